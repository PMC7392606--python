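"""Synthetic multi-day, drifting, place-tuned population activity.

The generator produces the kind of data the analysis modules assume:
populations of a few hundred units whose unimodal tuning curves tile a
linearized virtual maze, sampled at a calcium-imaging frame rate while a
simulated animal runs trials of a two-cue navigation task.  Tuning
parameters reconfigure ("drift") from day to day under one of three
controllable modes:

``random_walk``
    Isotropic drift of tuning parameters — every direction of parameter
    space is equally likely; this is the unstructured comparison case.
``low_rank``
    Drift confined to a fixed ``rank_k``-dimensional subspace of
    parameter space, emulating systematic reconfiguration in which only
    a few population-level components change.
``noise_aligned_mix``
    Drift of the per-unit coefficients of a shared location-modulation
    channel, with a controlled fraction of the drift power placed along
    the top eigenvectors of the ensemble's trial-to-trial noise
    covariance — giving the alignment statistics a known ground truth
    to recover.

All randomness flows from a single :class:`numpy.random.SeedSequence`
per entry point, so identical (config, seed) pairs give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.signal

from .data import (InvalidParameterError, KinematicsSeries, MultiDayDataset,
                   SessionData)

__all__ = [
    "DriftSpec", "TuningEnsemble", "TrialParams", "NoiseParams",
    "SimulateConfig", "generate_kinematics", "generate_ensemble",
    "apply_drift", "simulate_session", "generate_dataset",
    "InvalidParameterError",
]

DRIFT_MODES = ("random_walk", "low_rank", "noise_aligned_mix")


@dataclass
class DriftSpec:
    """Day-to-day reconfiguration of the tuning ensemble.

    ``step_size`` is the per-day root-mean-square *fractional* change of
    the drifting tuning parameters (unitless); ``noise_align_frac`` is
    the fraction of drift power placed along the ensemble's noise-
    covariance eigenvectors (``noise_aligned_mix`` mode only).
    """

    mode: str = "random_walk"
    rank_k: int = 5
    step_size: float = 0.05
    noise_align_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in DRIFT_MODES:
            raise InvalidParameterError(
                f"unknown drift mode {self.mode!r}; expected one of "
                f"{DRIFT_MODES}")
        if self.step_size < 0:
            raise InvalidParameterError("step_size must be >= 0")
        if not 0.0 <= self.noise_align_frac <= 1.0:
            raise InvalidParameterError("noise_align_frac must be in [0, 1]")
        if self.mode == "low_rank" and self.rank_k < 1:
            raise InvalidParameterError("rank_k must be >= 1")


@dataclass
class TuningEnsemble:
    """Parametric place-tuning of a population of units.

    Each unit has a Gaussian bump on the normalized maze coordinate
    [0, 1] with peak location ``peaks[i]``, width ``widths[i]`` and a
    flat baseline ``baselines[i]``; the curve is normalized so its
    maximum over the location-bin grid is exactly 1 before the per-unit
    ``gains`` scaling.  Trial-to-trial covariability is a low-rank plus
    diagonal factor model (``noise_loadings @ noise_loadings.T +
    diag(noise_diag)``).
    """

    peaks: np.ndarray
    widths: np.ndarray
    gains: np.ndarray
    baselines: np.ndarray
    mod_coefs: np.ndarray
    noise_loadings: np.ndarray
    noise_diag: np.ndarray
    cue_weights: np.ndarray
    n_bins: int = 50

    @property
    def n_units(self) -> int:
        return len(self.peaks)

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    def _raw(self, x: np.ndarray) -> np.ndarray:
        """Unnormalized bump + baseline evaluated at locations x."""
        x = np.asarray(x, float)[:, None]
        return self.baselines[None, :] + np.exp(
            -0.5 * ((x - self.peaks[None, :]) / self.widths[None, :]) ** 2)

    @property
    def _norm(self) -> np.ndarray:
        return self._raw(self.bin_centers).max(axis=0)

    @property
    def tuning(self) -> np.ndarray:
        """(n_units, n_bins) peak-normalized curves; max over bins == 1."""
        return (self._raw(self.bin_centers) / self._norm[None, :]).T

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Noise-free rates at normalized locations x: (T, n_units).

        Rate = gain * normalized tuning + mod_coef * sin(2 pi x); the
        second term is a shared location-modulation channel whose
        per-unit coefficients are the drifting quantity in
        ``noise_aligned_mix`` mode (a constant offset would be erased
        by the z-scoring the alignment analyses apply, so the drifting
        pattern must co-vary with location to be observable).
        """
        if self.n_units == 0:
            return np.zeros((len(np.atleast_1d(x)), 0))
        x = np.asarray(x, float)
        curves = self._raw(x) / self._norm[None, :]
        out = self.gains[None, :] * curves
        if np.any(self.mod_coefs):
            out = out + np.sin(2 * np.pi * x)[:, None] * \
                self.mod_coefs[None, :]
        return out

    def noise_cov(self) -> np.ndarray:
        """Implied trial-to-trial noise covariance (symmetric PSD)."""
        L = self.noise_loadings
        return L @ L.T + np.diag(self.noise_diag)


@dataclass
class TrialParams:
    """Trial-structure knobs for the simulated task."""

    mean_duration_s: float = 9.0
    duration_jitter_s: float = 2.0
    iti_duration_s: float = 2.0
    p_correct: float = 0.85
    turn_angle_deg: float = 30.0
    turn_fraction: float = 0.25
    view_angle_noise_deg: float = 3.0
    durations_s: Sequence[float] | None = None


@dataclass
class NoiseParams:
    """Observation-noise and calcium-dynamics knobs.

    ``sigma_shared`` / ``sigma_private`` multiply the ensemble's noise
    factor loadings and diagonal respectively (0 disables each source);
    ``smooth_tau_s`` is the decay constant of the causal exponential
    filter emulating slow calcium-indicator dynamics (0 disables).
    """

    sigma_shared: float = 1.0
    sigma_private: float = 1.0
    smooth_tau_s: float = 0.7


def generate_kinematics(maze_len_m: float = 4.5, n_trials: int = 200,
                        sample_rate_hz: float = 5.3,
                        trial_params: TrialParams | None = None,
                        seed: int = 0) -> KinematicsSeries:
    """Simulate maze-traversal kinematics for ``n_trials`` trials.

    Within each trial the position rises monotonically from 0 to
    ``maze_len_m`` with a smooth velocity profile; the view angle ramps
    toward +/- ``turn_angle_deg`` in the final ``turn_fraction`` of the
    maze according to the trial's binary cue.  Inter-trial-interval
    samples (position and velocity pinned to the maze end / zero) are
    flagged so preprocessing can drop them.
    """
    if maze_len_m <= 0:
        raise InvalidParameterError("maze_len_m must be > 0")
    if sample_rate_hz <= 0:
        raise InvalidParameterError("sample_rate_hz must be > 0")
    if n_trials < 0:
        raise InvalidParameterError("n_trials must be >= 0")
    tp = trial_params or TrialParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    pos, vel, ang, tid, cor, cue, iti = [], [], [], [], [], [], []
    for k in range(n_trials):
        if tp.durations_s is not None:
            dur = float(tp.durations_s[k % len(tp.durations_s)])
        else:
            dur = tp.mean_duration_s + tp.duration_jitter_s * (
                2.0 * rng.random() - 1.0)
        n = int(np.floor(dur * sample_rate_hz))
        n = max(n, 2)
        c = int(rng.random() < 0.5)
        ok = bool(rng.random() < tp.p_correct)
        # smooth strictly-positive velocity profile, rescaled so the
        # trial traverses exactly [0, maze_len]
        raw = 1.0 + 0.4 * rng.standard_normal(n)
        win = scipy.signal.windows.gaussian(min(9, n), 2.0)
        raw = np.convolve(raw, win / win.sum(), mode="same")
        raw = np.clip(raw, 0.1, None)
        cs = np.cumsum(raw)
        p = maze_len_m * (cs - cs[0]) / (cs[-1] - cs[0])
        v = np.gradient(p) * sample_rate_hz
        frac = p / maze_len_m
        ramp = np.clip((frac - (1 - tp.turn_fraction)) / tp.turn_fraction, 0, 1)
        sign = 1.0 if c == 1 else -1.0
        a = (sign * tp.turn_angle_deg * ramp
             + tp.view_angle_noise_deg * rng.standard_normal(n))

        pos.append(p); vel.append(v); ang.append(a)
        tid.append(np.full(n, k)); cor.append(np.full(n, ok))
        cue.append(np.full(n, c)); iti.append(np.zeros(n, bool))

        if k < n_trials - 1 and tp.iti_duration_s > 0:
            m = int(np.floor(tp.iti_duration_s * sample_rate_hz))
            if m > 0:
                pos.append(np.full(m, maze_len_m))
                vel.append(np.zeros(m)); ang.append(np.zeros(m))
                tid.append(np.full(m, k)); cor.append(np.full(m, ok))
                cue.append(np.full(m, c)); iti.append(np.ones(m, bool))

    if n_trials == 0:
        empty = np.array([])
        return KinematicsSeries(empty, empty, empty, empty,
                                np.array([], int), np.array([], bool),
                                np.array([], int), np.array([], bool),
                                maze_len_m)
    cat = np.concatenate
    T = len(cat(pos))
    return KinematicsSeries(
        time=np.arange(T) / sample_rate_hz, position=cat(pos),
        velocity=cat(vel), view_angle=cat(ang),
        trial_id=cat(tid).astype(int), correct=cat(cor).astype(bool),
        cue=cat(cue).astype(int), iti_flag=cat(iti).astype(bool),
        maze_len_m=maze_len_m)


def generate_ensemble(n_units: int,
                      field_width_params: tuple[float, float] = (0.05, 0.15),
                      gain_params: tuple[float, float] = (0.8, 1.2),
                      noise_params: dict | None = None,
                      seed: int = 0,
                      n_bins: int = 50,
                      baseline_range: tuple[float, float] = (0.0, 0.1),
                      cue_shift: float = 0.0,
                      noise_rank: int = 5,
                      noise_scale: float = 0.1) -> TuningEnsemble:
    """Draw a population whose tuning peaks tile the normalized maze.

    Peak locations are i.i.d. uniform on [0, 1]; widths, gains and
    baselines uniform over the given ranges.  The trial-to-trial noise
    covariance is a random ``noise_rank`` factor model plus a diagonal,
    both scaled by ``noise_scale`` (standard-deviation units of the
    normalized fluorescence).
    """
    if n_units < 0:
        raise InvalidParameterError("n_units must be >= 0")
    if noise_params:
        noise_rank = noise_params.get("rank", noise_rank)
        noise_scale = noise_params.get("scale", noise_scale)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    peaks = rng.uniform(0.0, 1.0, n_units)
    widths = rng.uniform(*field_width_params, n_units)
    gains = rng.uniform(*gain_params, n_units)
    baselines = rng.uniform(*baseline_range, n_units)
    mod_coefs = np.zeros(n_units)
    r = min(noise_rank, n_units)
    loadings = noise_scale * rng.standard_normal((n_units, r)) / max(np.sqrt(r), 1)
    diag = (noise_scale * rng.uniform(0.3, 1.0, n_units)) ** 2
    cue_w = np.zeros(n_units)
    if cue_shift:
        direction = rng.standard_normal(n_units)
        nrm = np.linalg.norm(direction)
        if nrm > 0:
            cue_w = cue_shift * direction / nrm * np.sqrt(n_units)
    return TuningEnsemble(peaks, widths, gains, baselines, mod_coefs,
                          loadings, diag, cue_w, n_bins)


def _drift_scales(ens: TuningEnsemble, mode: str) -> np.ndarray:
    """Per-parameter scale used to define *fractional* change."""
    if mode == "noise_aligned_mix":
        # modulation coefficients drift in absolute activity units
        return np.ones(ens.n_units)
    # peaks in maze-fraction units (scale 1), gains relative to initial gain
    return np.concatenate([np.ones(ens.n_units), np.abs(ens.gains)])


def _get_params(ens: TuningEnsemble, mode: str) -> np.ndarray:
    if mode == "noise_aligned_mix":
        return ens.mod_coefs.copy()
    return np.concatenate([ens.peaks, ens.gains])


def _set_params(ens: TuningEnsemble, theta: np.ndarray,
                mode: str) -> TuningEnsemble:
    n = ens.n_units
    if mode == "noise_aligned_mix":
        return replace(ens, mod_coefs=theta.copy())
    return replace(ens, peaks=theta[:n].copy(), gains=theta[n:].copy())


def apply_drift(ensemble: TuningEnsemble, drift_spec: DriftSpec,
                n_days: int) -> list[TuningEnsemble]:
    """Propagate the ensemble through ``n_days`` days of drift.

    Day 1 is the input ensemble unchanged.  Each subsequent day applies
    one drift step whose realized per-day RMS fractional parameter
    change equals ``step_size`` exactly (the random direction is drawn
    first and then rescaled), so drift-rate calibration holds by
    construction.
    """
    if n_days < 1:
        raise InvalidParameterError("n_days must be >= 1")
    mode = drift_spec.mode
    if mode == "low_rank" and drift_spec.rank_k > ensemble.n_units:
        raise InvalidParameterError(
            f"rank_k={drift_spec.rank_k} exceeds n_units={ensemble.n_units}")
    rng = np.random.default_rng(np.random.SeedSequence(drift_spec.seed))
    scales = _drift_scales(ensemble, mode)
    P = len(scales)
    days = [ensemble]
    if n_days == 1 or P == 0:
        return days + [ensemble] * (n_days - 1)

    basis = None
    if mode == "low_rank":
        G = rng.standard_normal((P, drift_spec.rank_k))
        basis, _ = np.linalg.qr(G)
    noise_basis = None
    if mode == "noise_aligned_mix":
        cov = ensemble.noise_cov()
        w, V = np.linalg.eigh(cov)
        k = max(1, ensemble.noise_loadings.shape[1])
        noise_basis = V[:, np.argsort(w)[::-1][:k]]  # top-k eigenvectors

    theta = _get_params(ensemble, mode)
    for _ in range(1, n_days):
        if drift_spec.step_size == 0:
            days.append(days[-1])
            continue
        if mode == "random_walk":
            u = rng.standard_normal(P)
        elif mode == "low_rank":
            u = basis @ rng.standard_normal(drift_spec.rank_k)
        else:  # noise_aligned_mix
            f = drift_spec.noise_align_frac
            c_al = noise_basis @ rng.standard_normal(noise_basis.shape[1])
            c_al /= max(np.linalg.norm(c_al), 1e-300)
            c_rnd = rng.standard_normal(P)
            c_rnd -= noise_basis @ (noise_basis.T @ c_rnd)  # orth. complement
            c_rnd /= max(np.linalg.norm(c_rnd), 1e-300)
            u = np.sqrt(f) * c_al + np.sqrt(1.0 - f) * c_rnd
        rms = np.sqrt(np.mean(u ** 2))
        u = u / rms if rms > 0 else u
        theta = theta + drift_spec.step_size * scales * u
        days.append(_set_params(days[0], theta, mode))
    return days


def _exp_smooth(rates: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    """Causal exponential smoothing emulating slow indicator dynamics."""
    if tau_s <= 0:
        return rates
    a = np.exp(-1.0 / (tau_s * fs))
    # y[t] = a y[t-1] + (1-a) x[t]
    return scipy.signal.lfilter([1.0 - a], [1.0, -a], rates, axis=0)


def simulate_session(ensemble: TuningEnsemble, kinematics: KinematicsSeries,
                     noise_params: NoiseParams | None = None, seed: int = 0,
                     day_index: int = 0,
                     sample_rate_hz: float | None = None) -> SessionData:
    """Render one session of activity from tuning plus noise.

    activity(t, i) = smooth(gain_i * tuning_i(x_t)
                            + mod_i * sin(2 pi x_t)
                            + cue_w_i * s(t)) + correlated noise,
    where x_t is the normalized maze position, s(t) = +/-1 encodes the
    trial cue, smoothing is the causal calcium-like filter, and the
    noise is drawn from the ensemble's factor model.  With all noise
    scales and the smoothing constant at zero the activity equals the
    tuning lookup exactly.
    """
    if ensemble.n_units == 0:
        raise InvalidParameterError("ensemble must contain at least one unit")
    if len(kinematics) == 0:
        raise InvalidParameterError("kinematics must be non-empty")
    np_ = noise_params or NoiseParams()
    if sample_rate_hz is None:
        dt = np.median(np.diff(kinematics.time)) if len(kinematics) > 1 else 1.0
        sample_rate_hz = 1.0 / dt
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = kinematics.position / kinematics.maze_len_m
    rates = ensemble.evaluate(x)
    if np.any(ensemble.cue_weights):
        s = 2.0 * kinematics.cue - 1.0
        rates = rates + s[:, None] * ensemble.cue_weights[None, :]
    rates = _exp_smooth(rates, np_.smooth_tau_s, sample_rate_hz)
    T, n = rates.shape
    noise = np.zeros_like(rates)
    if np_.sigma_shared != 0 and ensemble.noise_loadings.shape[1] > 0:
        g = rng.standard_normal((T, ensemble.noise_loadings.shape[1]))
        noise += np_.sigma_shared * g @ ensemble.noise_loadings.T
    if np_.sigma_private != 0:
        noise += (np_.sigma_private * np.sqrt(ensemble.noise_diag)[None, :]
                  * rng.standard_normal((T, n)))
    return SessionData(day_index=day_index, unit_ids=np.arange(n),
                       activity=rates + noise, kinematics=kinematics,
                       sample_rate_hz=sample_rate_hz)


@dataclass
class SimulateConfig:
    """Complete recipe for a multi-day synthetic dataset."""

    n_units: int = 150
    n_sessions: int = 10
    n_trials: int = 200
    maze_len_m: float = 4.5
    sample_rate_hz: float = 5.3
    max_gap_days: int = 2
    p_gap: float = 0.3
    drift: DriftSpec = field(default_factory=DriftSpec)
    trial_params: TrialParams = field(default_factory=TrialParams)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    cue_shift: float = 0.0
    seed: int = 0
    session_days: Sequence[int] | None = None


def generate_dataset(config: SimulateConfig) -> MultiDayDataset:
    """Generate a full multi-session dataset from one config + seed.

    Session days are either given explicitly or drawn with occasional
    2-day recording gaps (probability ``p_gap`` per interval).  Drift is
    applied per elapsed calendar day, so a 2-day gap accumulates two
    drift steps, as it would in a real recording.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_days, s_ens, s_kin, s_sess = ss.spawn(4)
    rng = np.random.default_rng(s_days)
    if cfg.session_days is not None:
        days = list(cfg.session_days)
    else:
        days, d = [0], 0
        for _ in range(cfg.n_sessions - 1):
            d += 2 if rng.random() < cfg.p_gap else 1
            days.append(d)
    n_days = days[-1] + 1

    ens = generate_ensemble(cfg.n_units, seed=s_ens.generate_state(1)[0] % (2**31),
                            cue_shift=cfg.cue_shift)
    drift = replace(cfg.drift, seed=int(
        (cfg.drift.seed + s_ens.generate_state(2)[1]) % (2**31)))
    daily = apply_drift(ens, drift, n_days)

    kin_seeds = s_kin.generate_state(len(days)) % (2**31)
    sess_seeds = s_sess.generate_state(len(days)) % (2**31)
    sessions = []
    for i, day in enumerate(days):
        kin = generate_kinematics(cfg.maze_len_m, cfg.n_trials,
                                  cfg.sample_rate_hz, cfg.trial_params,
                                  seed=int(kin_seeds[i]))
        sess = simulate_session(daily[day], kin, cfg.noise_params,
                                seed=int(sess_seeds[i]), day_index=day,
                                sample_rate_hz=cfg.sample_rate_hz)
        sessions.append(sess)
    return MultiDayDataset(sessions, max_gap_days=cfg.max_gap_days)
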