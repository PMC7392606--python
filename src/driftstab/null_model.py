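"""Statistically-matched random-drift null model for a linear readout.

The null model asks: if a population's readout weights performed an
unstructured random walk, how quickly would a fixed (concatenated)
decoder degrade?  A synthetic readout M_r is drifted from day to day
under two hard constraints,

* norm conservation, ||M_{r+1}|| = ||M_r||, and
* a target *between-day R^2*: the expected squared correlation of the
  new readout's output M_{r+1}' z with the old readout's prediction
  M_r' z, evaluated under the day's empirical activity covariance,
  matches the rate at which the data's own single-day decoders degrade,

and generates pseudo-observations x_r = M_r' z + eps_r whose
single-day decodability is matched to the data by calibrating the noise
scale of eps_r.  Optionally the day-to-day weight change is confined to
a fixed k-dimensional subspace, which turns each drift step into a
(non-convex) quadratically-constrained quadratic program solved from
random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .data import (InvalidParameterError, MultiDayDataset, SessionData)
from . import decoding

__all__ = [
    "NullReadout", "NullExperimentResult", "CalibrationInfeasibleError",
    "DriftStepInfeasibleError", "init_readout", "calibrate_noise_scale",
    "expected_between_day_r2", "drift_step", "random_orthonormal_basis",
    "run_null_experiment", "match_null_to_data",
]


class CalibrationInfeasibleError(RuntimeError):
    """Requested single-day accuracy is better than the noiseless limit."""


class DriftStepInfeasibleError(RuntimeError):
    """No constrained drift step found within the retry budget."""


@dataclass
class NullReadout:
    """State of the drifting synthetic readout on one day."""

    day_index: int
    weights: np.ndarray
    noise_scale: float = 0.0
    basis: np.ndarray | None = None
    pseudo_target: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float).ravel()
        if self.noise_scale < 0:
            raise InvalidParameterError("noise_scale must be >= 0")
        if self.basis is not None:
            B = np.asarray(self.basis, float)
            if np.max(np.abs(B.T @ B - np.eye(B.shape[1]))) > 1e-8:
                raise InvalidParameterError("basis columns must be "
                                            "orthonormal")
            self.basis = B


@dataclass
class NullExperimentResult:
    """Degradation statistics of a generated null experiment."""

    curves: np.ndarray          # (n_resamples, D) normalized R^2
    mean_curve: np.ndarray      # (D,)
    band: np.ndarray            # (2, D) inner-95% resampling band
    per_day_mae: np.ndarray     # (n_resamples, D) single-day CV error
    concat_mae: np.ndarray      # (n_resamples,)
    noise_scales: np.ndarray
    readout_norms: np.ndarray   # (n_resamples, D)


def init_readout(n_units: int, seed: int = 0) -> NullReadout:
    """Day-one readout with i.i.d. uniform [0, 1] weights."""
    if n_units < 1:
        raise InvalidParameterError("n_units must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return NullReadout(day_index=0, weights=rng.uniform(0.0, 1.0, n_units))


def _second_moment(Z: np.ndarray) -> np.ndarray:
    Zc = Z - Z.mean(axis=0, keepdims=True)
    return Zc.T @ Zc / Zc.shape[0]


def expected_between_day_r2(m_prev: np.ndarray, m_next: np.ndarray,
                            cov: np.ndarray) -> float:
    """Expected squared multiple correlation of the two readout outputs.

    For outputs driven by activity with covariance ``cov``, the R^2 of
    x_{r+1} = m_next' z regressed on the prediction m_prev' z is the
    squared correlation of the two projections, a ratio of quadratic
    forms evaluated in closed form.
    """
    a = float(m_prev @ cov @ m_next)
    b = float(m_prev @ cov @ m_prev)
    c = float(m_next @ cov @ m_next)
    return a * a / (b * c)


def calibrate_noise_scale(session: SessionData, m1: np.ndarray,
                          target_mae: float, seed: int = 0, folds: int = 5,
                          rel_tol: float = 0.01, max_iter: int = 60) -> float:
    """Noise scale sigma such that decoding x = Z m1 + sigma*eps attains
    the target single-day cross-validated MAE (within ``rel_tol``
    relative), found by monotone bisection on a fixed noise draw.
    """
    Z = session.activity
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eps = rng.standard_normal(Z.shape[0])
    x0 = Z @ np.asarray(m1, float)

    def mae(sigma):
        sess = SessionData(
            session.day_index, session.unit_ids, Z,
            decoding.with_target_channel(session.kinematics, "position",
                                         x0 + sigma * eps),
            session.sample_rate_hz)
        return decoding.evaluate_cv(sess, "position", folds)["mae"]

    base = mae(0.0)
    if target_mae < base * (1 - rel_tol):
        raise CalibrationInfeasibleError(
            f"target MAE {target_mae:.4g} below noiseless CV error "
            f"{base:.4g}")
    if abs(base - target_mae) <= rel_tol * target_mae:
        return 0.0
    lo, hi = 0.0, float(np.std(x0)) + 1e-12
    while mae(hi) < target_mae:
        hi *= 2.0
        if hi > 1e12:
            raise CalibrationInfeasibleError("noise calibration diverged")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = mae(mid)
        if abs(m - target_mae) <= rel_tol * target_mae:
            return mid
        if m < target_mae:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def random_orthonormal_basis(n_units: int, k: int, seed: int = 0
                             ) -> np.ndarray:
    """k random orthonormal directions in readout-weight space."""
    if not 1 <= k <= n_units:
        raise InvalidParameterError("need 1 <= k <= n_units")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    B, _ = np.linalg.qr(rng.standard_normal((n_units, k)))
    return B


def _unconstrained_step(m, cov, target_r2, rng, max_retries):
    """Closed-form scaling of a white-noise candidate.

    The candidate's components parallel and orthogonal to m are
    rescaled: M(theta) = cos(theta) m + ||m|| sin(theta) u with u a
    unit vector orthogonal to m, which conserves the norm for every
    theta; theta is then root-found so the expected between-day R^2
    hits the target.
    """
    nrm = np.linalg.norm(m)
    for _ in range(max_retries):
        xi = rng.standard_normal(len(m))
        u = xi - m * (m @ xi) / (nrm * nrm)
        un = np.linalg.norm(u)
        if un == 0:
            continue
        u /= un

        def r2_of(theta):
            cand = np.cos(theta) * m + nrm * np.sin(theta) * u
            return expected_between_day_r2(m, cand, cov)

        f = lambda th: r2_of(th) - target_r2
        if f(np.pi / 2) > 0:
            continue  # even a fully orthogonal step stays too correlated
        theta = scipy.optimize.brentq(f, 0.0, np.pi / 2, xtol=1e-12)
        return np.cos(theta) * m + nrm * np.sin(theta) * u
    raise DriftStepInfeasibleError(
        f"no candidate reached target R^2 {target_r2:.3f}")


def _constrained_step(m, cov, target_r2, basis, rng, max_retries,
                      clip=False):
    """Drift step confined to span(basis): a non-convex QCQP.

    With dM = B gamma, norm conservation restricts gamma to the sphere
    gamma = -B'm + r u (||u|| = 1, r = ||B'm||), which this solver
    parametrizes exactly, leaving the target between-day R^2 as a
    single scalar equation.  Random unit-Gaussian directions seed
    geodesics on that sphere starting from the zero-drift point
    (R^2 = 1); the first geodesic on which the R^2 profile crosses the
    target is root-found by bisection.  Norm conservation therefore
    holds to machine precision and failures occur only when the
    subspace genuinely cannot decorrelate the readout to the target.
    """
    B = basis
    k = B.shape[1]
    bm = B.T @ m
    r = float(np.linalg.norm(bm))
    if r == 0:
        raise DriftStepInfeasibleError(
            "readout is orthogonal to the drift subspace; no norm-"
            "conserving step exists")
    u0 = bm / r  # gamma(u0) = 0: the no-drift point

    def candidate(u):
        return m + B @ (r * u - bm)

    grid = np.linspace(0.0, np.pi, 65)[1:]
    best_val, best_u = np.inf, None
    for _ in range(max_retries):
        v = rng.standard_normal(k)
        w = v - u0 * (u0 @ v)
        wn = np.linalg.norm(w)
        if wn == 0:
            continue
        w /= wn

        def f(t):
            u = np.cos(t) * u0 + np.sin(t) * w
            return expected_between_day_r2(m, candidate(u), cov) - target_r2

        prev_t = 0.0
        for t in grid:
            ft = f(t)
            if ft <= 0.0:
                theta = scipy.optimize.brentq(f, prev_t, t, xtol=1e-13)
                u = np.cos(theta) * u0 + np.sin(theta) * w
                return candidate(u)
            if ft < best_val:
                best_val, best_u = ft, np.cos(t) * u0 + np.sin(t) * w
            prev_t = t
    if clip and best_u is not None:
        # the subspace cannot decorrelate this far: take the most
        # decorrelating reachable step (realized R^2 floors above target)
        return candidate(best_u)
    raise DriftStepInfeasibleError(
        f"constrained drift step failed after {max_retries} restarts "
        f"(target R^2 {target_r2:.3f}, rank {k}): the subspace cannot "
        "decorrelate the readout that far")


def drift_step(state: NullReadout, activity: np.ndarray,
               target_between_day_r2: float, seed: int = 0,
               basis: np.ndarray | None = None,
               max_retries: int = 20,
               on_infeasible: str = "raise") -> NullReadout:
    """One norm-preserving drift step of the synthetic readout.

    Draws a white-noise candidate direction and adjusts it so that the
    new weights conserve the norm exactly and realize the target
    between-day R^2 under the empirical activity covariance.  With a
    ``basis`` the change is additionally confined to its span.  A
    low-rank subspace has a floor on how far it can decorrelate the
    readout; ``on_infeasible='clip'`` returns the most decorrelating
    reachable step instead of raising when the target lies below that
    floor.
    """
    if on_infeasible not in ("raise", "clip"):
        raise InvalidParameterError("on_infeasible must be 'raise' or "
                                    "'clip'")
    if not 0.0 <= target_between_day_r2 <= 1.0:
        raise InvalidParameterError("target R^2 must be in [0, 1]")
    m = state.weights
    cov = _second_moment(np.atleast_2d(activity))
    if target_between_day_r2 == 1.0:
        return NullReadout(state.day_index + 1, m.copy(), state.noise_scale,
                           basis if basis is not None else state.basis)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    use_basis = basis if basis is not None else state.basis
    if use_basis is not None:
        new = _constrained_step(m, cov, target_between_day_r2,
                                np.asarray(use_basis, float), rng,
                                max_retries,
                                clip=(on_infeasible == "clip"))
    else:
        new = _unconstrained_step(m, cov, target_between_day_r2, rng,
                                  max_retries)
    return NullReadout(state.day_index + 1, new, state.noise_scale, use_basis)


def match_null_to_data(multiday: MultiDayDataset, target: str = "position",
                       folds: int = 10) -> dict:
    """Extract the matching statistics the null model needs from data.

    Returns the mean single-day cross-validated MAE and the mean
    day-adjacent generalization R^2 of the data's cross-day matrix,
    which operationalize 'matched to the rate at which single-day
    decoders degrade'.
    """
    maes = [decoding.evaluate_cv(s, target, folds)["mae"]
            for s in multiday.sessions]
    r2 = decoding.cross_day_r2_matrix(multiday, target, folds)
    D = r2.shape[0]
    adj = [r2[i, i + 1] for i in range(D - 1)] + \
          [r2[i + 1, i] for i in range(D - 1)]
    between = float(np.clip(np.mean(adj), 0.0, 1.0))
    sameday = float(np.clip(np.mean(np.diag(r2)), 1e-12, 1.0))
    # the adjacent-day R^2 confounds readout drift with observation
    # noise; dividing by the same-day (noise-limited) R^2 isolates the
    # decorrelation attributable to drift, which is what drift_step
    # targets for its noiseless readout
    drift_r2 = float(np.clip(between / sameday, 0.0, 1.0))
    return {"single_day_mae": float(np.mean(maes)),
            "between_day_r2": between, "single_day_r2": sameday,
            "drift_r2": drift_r2,
            "per_day_mae": np.array(maes), "cross_day_r2": r2}


def run_null_experiment(day1, n_days: int, between_day_r2, single_day_mae,
                        k: int | None = None, seed: int = 0,
                        n_resamples: int = 20, folds: int = 5,
                        on_infeasible: str = "clip"
                        ) -> NullExperimentResult:
    """Simulate the null readout and measure decoder degradation.

    ``day1`` is a prepared session (or multi-day dataset, in which case
    each day's own activity is used).  For each resample a fresh
    readout trajectory and noise realization generate pseudo-position
    targets; single-day and concatenated decoders are then fit to the
    pseudo-data exactly as they would be to real data, and the
    normalized-R^2 degradation curve recorded.  The band is the inner
    95% over resamples.
    """
    if isinstance(day1, MultiDayDataset):
        sessions_in = day1.sessions
        if len(sessions_in) < n_days:
            raise InvalidParameterError("not enough sessions for n_days")
        get_session = lambda r: sessions_in[r]
    else:
        get_session = lambda r: day1
    r2_targets = np.broadcast_to(np.asarray(between_day_r2, float),
                                 (n_days - 1,))
    ss = np.random.SeedSequence(seed)
    curves, maes, cmaes, scales, norms = [], [], [], [], []
    for child in ss.spawn(n_resamples):
        seeds = child.generate_state(2 * n_days + 12) % (2 ** 31)
        n = get_session(0).n_units
        state = init_readout(n, seed=int(seeds[0]))
        sigma = calibrate_noise_scale(get_session(0), state.weights,
                                      single_day_mae, seed=int(seeds[2]),
                                      folds=folds)
        rng = np.random.default_rng(child.spawn(1)[0])
        if k is not None:
            state.basis = random_orthonormal_basis(n, k, seed=int(seeds[1]))
        traj = [state]
        for r in range(1, n_days):
            traj.append(drift_step(traj[-1], get_session(r - 1).activity,
                                   float(r2_targets[r - 1]),
                                   seed=int(seeds[2 + r]),
                                   on_infeasible=on_infeasible))
        pseudo = []
        for r, st in enumerate(traj):
            s = get_session(r)
            x = s.activity @ st.weights + sigma * rng.standard_normal(
                s.n_samples)
            pseudo.append(SessionData(
                r, s.unit_ids, s.activity,
                decoding.with_target_channel(s.kinematics, "position", x),
                s.sample_rate_hz))
        md = MultiDayDataset(pseudo)
        curves.append(decoding.degradation_curve(md, "position"))
        maes.append([decoding.evaluate_cv(s, "position", folds)["mae"]
                     for s in pseudo])
        cat = decoding.fit_concatenated(md, "position")
        cmaes.append(np.mean([decoding.mean_abs_error(
            s.target("position"), decoding.predict(cat, s.activity))
            for s in pseudo]))
        scales.append(sigma)
        norms.append([np.linalg.norm(st.weights) for st in traj])
    curves = np.array(curves)
    band = np.percentile(curves, [2.5, 97.5], axis=0)
    return NullExperimentResult(curves=curves, mean_curve=curves.mean(axis=0),
                                band=band, per_day_mae=np.array(maes),
                                concat_mae=np.array(cmaes),
                                noise_scales=np.array(scales),
                                readout_norms=np.array(norms))
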