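"""Online least-mean-squares (LMS) adaptive decoding across sessions.

LMS is stochastic gradient descent on the squared prediction error of
an affine readout: at every sample the decoder predicts
x_hat = w' z + b, observes the error e = x - x_hat, and nudges each
weight by eta * e * z_i.  The rule is local — each synapse needs only
its input, the shared error signal and its own weight — which is what
makes it a biologically plausible candidate for compensating
representational drift.

Streaming is strictly causal: sessions are replayed in chronological
order, samples in recorded order, with raw (not per-trial-centered)
kinematics as the teaching signal, since centering would require
knowledge of the whole trial before it ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (DataIntegrityError, InvalidParameterError, MultiDayDataset)
from . import decoding

__all__ = [
    "LMSState", "DivergenceError", "lms_step", "run_session",
    "run_online", "weight_change_stats", "sweep_learning_rates",
]


class DivergenceError(RuntimeError):
    """LMS weights exceeded the divergence guard (learning rate too big)."""


@dataclass
class LMSState:
    """Adaptive affine decoder state.

    ``session_snapshots`` holds (session index, weight copy, bias) at
    every session boundary; ``sample_log`` optionally records the full
    per-sample weight trajectory norm.
    """

    weights: np.ndarray
    bias: float = 0.0
    learning_rate: float = 0.0
    session_snapshots: list = field(default_factory=list)
    sample_log: list | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float).ravel()
        if self.learning_rate < 0:
            raise InvalidParameterError("learning_rate must be >= 0")


def lms_step(state: LMSState, z_t: np.ndarray, x_t: float
             ) -> tuple[LMSState, float]:
    """One LMS update; returns (state, prediction made *before* update).

    x_hat = w'z + b;  e = x - x_hat;  w += eta e z;  b += eta e.
    The state is updated in place and also returned.
    """
    z_t = np.asarray(z_t, float).ravel()
    if len(z_t) != len(state.weights):
        raise DataIntegrityError(
            f"input length {len(z_t)} != weight length {len(state.weights)}")
    if not (np.all(np.isfinite(z_t)) and np.isfinite(x_t)):
        raise DataIntegrityError("non-finite input to LMS step")
    x_hat = float(state.weights @ z_t + state.bias)
    e = float(x_t) - x_hat
    eta = state.learning_rate
    if eta != 0.0 and e != 0.0:
        state.weights = state.weights + eta * e * z_t
        state.bias = state.bias + eta * e
    return state, x_hat


def run_session(state: LMSState, Z: np.ndarray, x: np.ndarray,
                guard: float | None = None, log_norms: bool = False
                ) -> np.ndarray:
    """Stream one session through LMS; returns per-sample predictions.

    Vectorized inner loop over samples; raises DivergenceError when the
    weight norm exceeds ``guard``.
    """
    w, b, eta = state.weights.copy(), state.bias, state.learning_rate
    T = Z.shape[0]
    preds = np.empty(T)
    norms = np.empty(T) if log_norms else None
    # overflow while diverging is expected; the guard turns it into a
    # loud DivergenceError instead of a numpy warning
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(T):
            z = Z[t]
            x_hat = w @ z + b
            preds[t] = x_hat
            e = x[t] - x_hat
            if eta != 0.0:
                w += eta * e * z
                b += eta * e
            if log_norms:
                norms[t] = np.sqrt(w @ w)
            if guard is not None and t % 64 == 0 and \
                    not w @ w <= guard * guard:
                raise DivergenceError(
                    f"weight norm exceeded guard at learning rate "
                    f"{eta:g}")
        if guard is not None and not w @ w <= guard * guard:
            raise DivergenceError(
                f"weight norm exceeded guard at learning rate {eta:g}")
    state.weights, state.bias = w, b
    if log_norms:
        state.sample_log = (list(state.sample_log or []) + norms.tolist())
    return preds


def _affine_ols(Z: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Batch OLS with a bias column (initialization of the stream)."""
    A = np.column_stack([Z, np.ones(Z.shape[0])])
    w, *_ = np.linalg.lstsq(A, x, rcond=None)
    return w[:-1], float(w[-1])


def run_online(multiday: MultiDayDataset, target: str, eta: float,
               init_sessions: int = 2, seed: int = 0,
               divergence_factor: float = 1e6, log_norms: bool = False
               ) -> dict:
    """Initialize by batch OLS, then track the remaining sessions online.

    The decoder is fit (with bias) to the first ``init_sessions``
    sessions, then streamed sample-by-sample through every subsequent
    session with learning rate ``eta``.  A frozen copy (eta = 0) is
    streamed in parallel as the no-plasticity baseline.  Returns
    per-session MAEs for both, end-of-session weight snapshots, and
    the day gaps needed for per-day weight-change rates.
    """
    if multiday.n_sessions < init_sessions + 1:
        raise InvalidParameterError(
            f"need >= {init_sessions + 1} sessions")
    train = multiday.sessions[:init_sessions]
    Z0 = np.vstack([s.activity for s in train])
    x0 = np.concatenate([s.target(target) for s in train])
    w0, b0 = _affine_ols(Z0, x0)
    guard = divergence_factor * max(np.linalg.norm(w0), 1e-12)

    state = LMSState(weights=w0.copy(), bias=b0, learning_rate=eta,
                     sample_log=[] if log_norms else None)
    frozen = LMSState(weights=w0.copy(), bias=b0, learning_rate=0.0)
    stream = multiday.sessions[init_sessions:]
    snapshots = [w0.copy()]
    mae_lms, mae_frozen = [], []
    for s in stream:
        Z, x = s.activity, s.target(target)
        preds = run_session(state, Z, x, guard=guard, log_norms=log_norms)
        mae_lms.append(float(np.mean(np.abs(x - preds))))
        preds_f = run_session(frozen, Z, x)
        mae_frozen.append(float(np.mean(np.abs(x - preds_f))))
        snapshots.append(state.weights.copy())
    state.session_snapshots = [(i, w.copy(), None)
                               for i, w in enumerate(snapshots)]
    day_idx = multiday.day_indices[init_sessions - 1:]
    return {"state": state, "eta": eta,
            "mae_per_session": np.array(mae_lms),
            "mae_frozen": np.array(mae_frozen),
            "snapshots": np.array(snapshots),
            "day_gaps": np.diff(day_idx),
            "session_lengths": np.array([s.n_samples for s in stream])}


def weight_change_stats(snapshots: np.ndarray, day_gaps: np.ndarray,
                        sample_log: np.ndarray | None = None,
                        mean_session_samples: int | None = None) -> dict:
    """Per-session percent weight change, optionally with a sliding trace.

    Percent change between consecutive end-of-session snapshots is
    ||w_{d+1} - w_d|| divided by the mean snapshot norm, divided by
    the days elapsed between those sessions, times 100 (% per day);
    the undivided % per session is also returned.  The sliding trace
    differences the per-sample weight trajectory over a window of the
    mean session sample count, normalized identically.
    """
    W = np.asarray(snapshots, float)
    if W.shape[0] < 2:
        raise InvalidParameterError("need >= 2 weight snapshots")
    gaps = np.asarray(day_gaps, float).ravel()
    if len(gaps) != W.shape[0] - 1:
        raise InvalidParameterError("need one day gap per snapshot interval")
    norms = np.linalg.norm(W, axis=1)
    ref = float(norms.mean())
    diffs = np.linalg.norm(np.diff(W, axis=0), axis=1)
    pct_per_session = diffs / ref * 100.0
    pct_per_day = pct_per_session / np.maximum(gaps, 1.0)
    out = {"pct_per_session": pct_per_session,
           "pct_per_day": pct_per_day,
           "mean_pct_per_session": float(pct_per_session.mean()),
           "mean_pct_per_day": float(pct_per_day.mean())}
    if sample_log is not None and mean_session_samples:
        log = np.asarray(sample_log, float)
        k = int(mean_session_samples)
        if len(log) > k:
            sliding = np.abs(log[k:] - log[:-k]) / ref * 100.0
            out["sliding_pct"] = sliding
    return out


def sweep_learning_rates(multiday: MultiDayDataset, target: str,
                         eta_grid, seed: int = 0, init_sessions: int = 2
                         ) -> dict:
    """Plasticity-accuracy trade-off: one online run per learning rate.

    Returns matched (mean % weight change per day, mean MAE) pairs per
    eta, plus the frozen-decoder and concatenated-decoder reference
    errors evaluated on the streamed sessions.  Runs that diverge are
    reported (NaN entries) and the sweep continues.
    """
    etas = np.asarray(eta_grid, float).ravel()
    if etas.size == 0:
        raise InvalidParameterError("eta grid must be non-empty")
    maes = np.full(len(etas), np.nan)
    pct_day = np.full(len(etas), np.nan)
    diverged = np.zeros(len(etas), bool)
    frozen_mae = np.nan
    for i, eta in enumerate(etas):
        try:
            res = run_online(multiday, target, float(eta), init_sessions,
                             seed)
        except DivergenceError:
            diverged[i] = True
            continue
        maes[i] = res["mae_per_session"].mean()
        frozen_mae = res["mae_frozen"].mean()
        stats = weight_change_stats(res["snapshots"], res["day_gaps"])
        pct_day[i] = stats["mean_pct_per_day"]
    # affine concatenated reference: raw kinematics are not centered in
    # the online setting, so the batch comparator needs a bias too
    Zc = np.vstack([s.activity for s in multiday.sessions])
    xc = np.concatenate([s.target(target) for s in multiday.sessions])
    wc, bc = _affine_ols(Zc, xc)
    stream = multiday.sessions[init_sessions:]
    concat_mae = float(np.mean([np.mean(np.abs(
        s.target(target) - (s.activity @ wc + bc))) for s in stream]))
    return {"eta": etas, "mae": maes, "pct_weight_change_per_day": pct_day,
            "diverged": diverged, "frozen_mae": float(frozen_mae),
            "concat_mae": concat_mae}
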