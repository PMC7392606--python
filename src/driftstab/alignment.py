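"""Alignment of representational drift with noise and coding directions.

Across days the trial-conditioned mean population activity at a given
maze location changes by a drift vector dmu.  This module quantifies
how that drift projects onto (a) the directions of trial-to-trial
variability ("noise correlations") and (b) the directions along which
activity varies with maze location ("behavior-coding directions").

For a reference matrix A (the trial-conditioned noise covariance Sigma,
or the second moment Sigma_grad + mu_grad mu_grad' of the location
gradient of activity), the mean squared dot product of a unit drift
vector with fluctuations drawn from A is the quadratic form
dmu' A dmu.  Normalizing by the largest eigenvalue gives

    phi^2   = dmu' A dmu / (|dmu|^2 lambda_max),

which is 1 when drift lies along the top eigenvector.  A randomly
oriented drift vector still picks up chance alignment
phi_0^2 = tr(A) / (D lambda_max), so the summary statistic

    rho = (phi - phi_0) / (1 - phi_0)

is 0 on average for random drift and 1 for drift perfectly aligned
with the dominant direction of variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (DataIntegrityError, InvalidParameterError, SessionData)

__all__ = [
    "ConditionedMoments", "AlignmentScores", "InsufficientDataError",
    "UndefinedAlignmentError", "conditioned_moments", "drift_vectors",
    "alignment_phi2", "alignment_rho", "chance_alignment_mc",
    "pooled_rho",
]


class InsufficientDataError(ValueError):
    """A conditioning cell has too few trials to form moments."""


class UndefinedAlignmentError(ValueError):
    """Alignment of a zero drift vector is undefined."""


@dataclass
class ConditionedMoments:
    """Per (location bin, cue condition) moments of processed activity.

    ``mean``/``cov`` are the trial-averaged mean and trial-to-trial
    covariance per cell; ``grad_mean``/``grad_cov`` are the same
    moments of the location-derivative of activity (finite differences
    across adjacent bins within each trial).  Keys of all dicts are
    (bin_index, condition_label) tuples.
    """

    mean: dict
    cov: dict
    grad_mean: dict
    grad_cov: dict
    n_bins: int
    conditions: tuple
    n_units: int

    def cells(self):
        return list(self.mean.keys())

    def reference_matrix(self, cell, mode: str) -> np.ndarray:
        """The matrix A whose spectrum defines alignment for ``mode``."""
        if mode == "noise":
            return self.cov[cell]
        if mode == "coding":
            g = self.grad_mean[cell]
            return self.grad_cov[cell] + np.outer(g, g)
        raise InvalidParameterError(
            f"mode must be 'noise' or 'coding', got {mode!r}")


@dataclass
class AlignmentScores:
    """Normalized alignment scores for one drift vector and reference."""

    phi_sq: float
    phi_chance_sq: float
    rho: float
    mode: str


def _trial_bin_tensor(session: SessionData, n_bins: int):
    """Per-trial, per-bin averaged activity: (n_trials, n_bins, n_units).

    Location is normalized to [0, 1] *within each trial* (trial
    pseudotime); bins with no samples in a trial are NaN.
    """
    kin = session.kinematics
    act = session.activity
    keep = ~kin.iti_flag
    trials = np.array(sorted(set(kin.trial_id[keep].tolist())))
    n_units = act.shape[1]
    out = np.full((len(trials), n_bins, n_units), np.nan)
    cues = np.zeros(len(trials), int)
    for ti, t in enumerate(trials):
        m = keep & (kin.trial_id == t)
        pos = kin.position[m]
        lo, hi = pos.min(), pos.max()
        x = (pos - lo) / (hi - lo) if hi > lo else np.zeros(len(pos))
        bins = np.clip((x * n_bins).astype(int), 0, n_bins - 1)
        a = act[m]
        for b in range(n_bins):
            bm = bins == b
            if np.any(bm):
                out[ti, b] = a[bm].mean(axis=0)
        cues[ti] = kin.cue[m][0]
    return trials, out, cues


def conditioned_moments(session: SessionData, n_location_bins: int = 50,
                        condition_on_cue: bool = True,
                        min_trials: int = 2) -> ConditionedMoments:
    """Location- (and cue-) conditioned activity moments of one session.

    Expects activity already passed through the band-pass / z-score
    normalization.  Per-trial activity is averaged within
    ``n_location_bins`` equal bins of trial pseudotime; means and
    covariances are then taken over trials within each (bin, cue)
    cell.  Gradient moments come from central finite differences of
    the per-trial bin-averaged activity across adjacent bins
    (forward/backward at the maze ends).
    """
    trials, tensor, cues = _trial_bin_tensor(session, n_location_bins)
    if condition_on_cue:
        conditions = tuple(sorted(set(cues.tolist())))
    else:
        conditions = (None,)
    # per-trial location gradient: d z / d x with dx = 1 / n_bins
    grad = np.gradient(tensor, axis=1) * n_location_bins

    mean, cov, gmean, gcov = {}, {}, {}, {}
    for b in range(n_location_bins):
        for c in conditions:
            rows = np.ones(len(trials), bool) if c is None else (cues == c)
            vals = tensor[rows, b]
            gvals = grad[rows, b]
            ok = ~np.isnan(vals).any(axis=1)
            vals, gvals = vals[ok], gvals[ok]
            if len(vals) < min_trials:
                raise InsufficientDataError(
                    f"cell (bin={b}, cue={c}) has {len(vals)} trials; "
                    f"need >= {min_trials}")
            key = (b, c)
            mean[key] = vals.mean(axis=0)
            cov[key] = np.cov(vals.T, bias=False) if len(vals) > 1 else \
                np.zeros((vals.shape[1],) * 2)
            gmean[key] = gvals.mean(axis=0)
            gcov[key] = np.cov(gvals.T, bias=False)
            cov[key] = np.atleast_2d(cov[key])
            gcov[key] = np.atleast_2d(gcov[key])
    return ConditionedMoments(mean, cov, gmean, gcov, n_location_bins,
                              conditions, session.n_units)


def drift_vectors(moments_day_a: ConditionedMoments,
                  moments_day_b: ConditionedMoments) -> dict:
    """Change in conditioned mean activity between two days, per cell."""
    if (moments_day_a.n_bins != moments_day_b.n_bins
            or moments_day_a.conditions != moments_day_b.conditions
            or moments_day_a.n_units != moments_day_b.n_units):
        raise DataIntegrityError("conditioning structures differ between "
                                 "the two days")
    return {cell: moments_day_b.mean[cell] - moments_day_a.mean[cell]
            for cell in moments_day_a.cells()}


def _regularized_eigmax(A: np.ndarray, ridge_frac: float = 1e-6):
    A = 0.5 * (A + A.T)
    lmax = float(np.linalg.eigvalsh(A)[-1])
    if lmax <= 0:
        raise UndefinedAlignmentError("reference matrix has no positive "
                                      "eigenvalue")
    A = A + ridge_frac * lmax * np.eye(A.shape[0])
    return A, float(np.linalg.eigvalsh(A)[-1])


def alignment_phi2(dmu: np.ndarray, A: np.ndarray) -> tuple[float, float]:
    """(phi^2, phi_0^2) for a drift vector against a reference matrix."""
    dmu = np.asarray(dmu, float).ravel()
    nrm2 = float(dmu @ dmu)
    if nrm2 == 0:
        raise UndefinedAlignmentError("zero drift vector")
    A, lmax = _regularized_eigmax(A)
    D = A.shape[0]
    phi2 = float(dmu @ A @ dmu) / (nrm2 * lmax)
    phi0_2 = float(np.trace(A)) / (D * lmax)
    return phi2, phi0_2


def alignment_rho(dmu: np.ndarray, reference_moments, mode: str,
                  cell=None) -> AlignmentScores:
    """Normalized drift-alignment statistic rho for one drift vector.

    ``reference_moments`` may be a :class:`ConditionedMoments` (with
    ``cell`` selecting the conditioning cell) or a reference matrix
    directly.  ``mode='noise'`` aligns against the trial-conditioned
    covariance; ``mode='coding'`` against the second moment of the
    location gradient.
    """
    if isinstance(reference_moments, ConditionedMoments):
        A = reference_moments.reference_matrix(cell, mode)
    else:
        if mode not in ("noise", "coding"):
            raise InvalidParameterError(
                f"mode must be 'noise' or 'coding', got {mode!r}")
        A = np.asarray(reference_moments, float)
    phi2, phi0_2 = alignment_phi2(dmu, A)
    phi, phi0 = np.sqrt(phi2), np.sqrt(phi0_2)
    rho = (phi - phi0) / (1.0 - phi0) if phi0 < 1.0 else 0.0
    return AlignmentScores(phi_sq=phi2, phi_chance_sq=phi0_2,
                           rho=float(rho), mode=mode)


def chance_alignment_mc(reference_moments, mode: str = "noise",
                        n_samples: int = 100, seed: int = 0,
                        cell=None) -> dict:
    """Monte-Carlo chance distribution of rho for random unit drift.

    Draws drift vectors uniformly on the unit sphere and computes rho
    for each; returns the sample, its mean, and the 95th percentile
    used as the chance line in summary figures.
    """
    if isinstance(reference_moments, ConditionedMoments):
        A = reference_moments.reference_matrix(cell, mode)
    else:
        A = np.asarray(reference_moments, float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    D = A.shape[0]
    vs = rng.standard_normal((n_samples, D))
    vs /= np.linalg.norm(vs, axis=1, keepdims=True)
    rhos = np.array([alignment_rho(v, A, mode).rho for v in vs])
    return {"rho_samples": rhos, "mean": float(rhos.mean()),
            "p95": float(np.percentile(rhos, 95))}


def pooled_rho(sessions_processed: list[SessionData],
               mode: str = "noise", n_location_bins: int = 50,
               condition_on_cue: bool = True,
               min_trials: int = 2) -> dict:
    """rho pooled over location bins and consecutive session pairs.

    The reference moments are taken from the earlier session of each
    pair (drift is measured against the variability present *before*
    the change).  Returns the tidy per-cell table and the pooled mean.
    """
    moments = [conditioned_moments(s, n_location_bins, condition_on_cue,
                                   min_trials)
               for s in sessions_processed]
    rows = []
    for p in range(len(moments) - 1):
        dmus = drift_vectors(moments[p], moments[p + 1])
        for cell, dmu in dmus.items():
            if np.linalg.norm(dmu) == 0:
                continue
            sc = alignment_rho(dmu, moments[p], mode, cell=cell)
            rows.append({"pair": p, "bin": cell[0], "condition": cell[1],
                         "phi_sq": sc.phi_sq,
                         "phi_chance_sq": sc.phi_chance_sq, "rho": sc.rho})
    rhos = np.array([r["rho"] for r in rows])
    return {"table": rows, "mean_rho": float(rhos.mean()),
            "rho_values": rhos}
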