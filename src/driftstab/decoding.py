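"""Linear readout machinery for drifting population codes.

A kinematic variable x(t) is decoded from population activity z(t) by a
fixed weight vector M, x_hat = M' z.  This module provides:

* single-day ordinary-least-squares decoders with trial-blocked
  cross-validation and chance / identity-permutation baselines,
* the *concatenated* decoder — a single M fit jointly to data stacked
  over several days,
* the *plasticity-constrained* path — per-day weights M_d minimizing

      (1 - lam) * sum_d ||x_d - M_d' z_d||^2
          + lam * sum_d ||M_{d+1} - M_d||^2,

  a single block-tridiagonal quadratic solved exactly for each lam,
  which interpolates between independent per-day decoders (lam = 0)
  and the concatenated decoder (lam -> 1),
* cross-day generalization matrices and degradation curves,
* greedy best-K-subset ranking from cached fold-wise sufficient
  statistics, and Gaussian-process extrapolation of performance versus
  population size.

All fits expect sessions that have been through
:func:`driftstab.dataio.prepare_decoding_series` (ITI-free, per-trial
zero-mean), so decoders are fit without a bias term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .data import (DataIntegrityError, InvalidParameterError, MultiDayDataset,
                   SessionData)

__all__ = [
    "DecoderWeights", "ConstrainedPathResult", "RankingResult",
    "IllConditionedError", "fit_ols", "predict", "evaluate_cv",
    "chance_level", "fit_concatenated", "fit_constrained_path",
    "permutation_identity_baseline", "cross_day_matrix", "greedy_rank",
    "extrapolate_performance", "fit_performance_gp", "degradation_curve",
    "trial_folds", "r2_score",
]


class IllConditionedError(np.linalg.LinAlgError):
    """Singular Gram matrix with zero ridge; add regularization."""


@dataclass
class DecoderWeights:
    """A linear readout for one kinematic variable."""

    weights: np.ndarray
    bias: float | None = None
    target: str = "position"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float).ravel()
        if not np.all(np.isfinite(self.weights)):
            raise DataIntegrityError("decoder weights must be finite")

    @property
    def n_units(self) -> int:
        return len(self.weights)


@dataclass
class ConstrainedPathResult:
    """Solution path of the plasticity-constrained decoder."""

    lambda_grid: np.ndarray
    per_day_weights: list[np.ndarray]   # one (D, n) array per lambda
    per_day_error: np.ndarray           # (n_lambda, D) training MAE
    pct_weight_change: np.ndarray       # (n_lambda,) mean % change / session
    target: str = "position"


@dataclass
class RankingResult:
    """Greedy best-K-subset ranking of units."""

    order: np.ndarray            # permutation of unit indices
    cv_error_by_k: np.ndarray    # 10-fold CV MSE for best-1..best-N
    ridge_strength: float


# ------------------------------------------------------------- fitting

def fit_ols(activity: np.ndarray, target_series: np.ndarray,
            ridge_strength: float = 0.0,
            target: str = "position") -> DecoderWeights:
    """Ordinary least squares readout, optionally ridge-regularized.

    ``ridge_strength`` adds a constant to the diagonal of the activity
    covariance (Gram matrix divided by the sample count), so its scale
    is comparable across dataset sizes.
    """
    Z = np.atleast_2d(np.asarray(activity, float))
    x = np.asarray(target_series, float).ravel()
    if Z.shape[0] != len(x):
        raise DataIntegrityError(
            f"{Z.shape[0]} activity rows vs {len(x)} target samples")
    if np.isnan(Z).any() or np.isnan(x).any():
        raise DataIntegrityError("missing values in regression inputs")
    T, n = Z.shape
    if ridge_strength == 0.0:
        w, _, rank, _ = np.linalg.lstsq(Z, x, rcond=None)
        if rank < n:
            raise IllConditionedError(
                f"Gram matrix is singular (rank {rank} < {n} units); "
                "pass ridge_strength > 0")
    else:
        A = Z.T @ Z / T + ridge_strength * np.eye(n)
        w = np.linalg.solve(A, Z.T @ x / T)
    return DecoderWeights(weights=w, bias=None, target=target)


def predict(decoder: DecoderWeights, activity: np.ndarray) -> np.ndarray:
    out = np.atleast_2d(activity) @ decoder.weights
    if decoder.bias is not None:
        out = out + decoder.bias
    return out


def mean_abs_error(x: np.ndarray, x_hat: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(x) - np.asarray(x_hat))))


def r2_score(x: np.ndarray, x_hat: np.ndarray) -> float:
    x = np.asarray(x, float)
    ss_res = np.sum((x - x_hat) ** 2)
    ss_tot = np.sum((x - x.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0


# ------------------------------------------------------ cross-validation

def trial_folds(trial_id: np.ndarray, folds: int) -> list[np.ndarray]:
    """Partition samples into contiguous blocks of whole trials.

    Returns boolean masks, one per fold; trials are never split across
    folds, which avoids leakage through slow calcium dynamics.
    """
    trial_id = np.asarray(trial_id)
    trials = np.array(sorted(set(trial_id.tolist())))
    if len(trials) < folds:
        raise InvalidParameterError(
            f"{len(trials)} trials cannot form {folds} folds")
    masks = []
    for chunk in np.array_split(trials, folds):
        masks.append(np.isin(trial_id, chunk))
    return masks


def evaluate_cv(session: SessionData, target: str, folds: int = 10,
                ridge_strength: float = 0.0) -> dict:
    """Trial-blocked K-fold cross-validated decoding error.

    Returns pooled mean absolute error over all held-out samples
    (``mae``), the pooled mean squared error (``mse``), and per-fold
    MAE values.
    """
    Z = session.activity
    x = session.target(target)
    masks = trial_folds(session.kinematics.trial_id, folds)
    abs_err, sq_err, per_fold = [], [], []
    for test in masks:
        train = ~test
        dec = fit_ols(Z[train], x[train], ridge_strength, target)
        err = x[test] - predict(dec, Z[test])
        abs_err.append(np.abs(err))
        sq_err.append(err ** 2)
        per_fold.append(float(np.mean(np.abs(err))))
    abs_err = np.concatenate(abs_err)
    return {"mae": float(abs_err.mean()),
            "mse": float(np.concatenate(sq_err).mean()),
            "per_fold": np.array(per_fold)}


def chance_level(session: SessionData, target: str, n_shuffles: int = 100,
                 seed: int = 0, folds: int = 5,
                 ridge_strength: float = 0.0) -> float:
    """Chance decoding error from circular time-shuffling.

    Each draw circularly shifts the kinematics trace by a random offset
    relative to the activity, destroying the correspondence while
    preserving both marginal structures, then re-estimates the
    cross-validated decoding error.  Returns the mean over draws.
    """
    trials = session.kinematics.trial_table()
    if len(trials) < 2:
        raise InvalidParameterError("need >= 2 trials for chance estimation")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    T = session.n_samples
    x = session.target(target)
    maes = []
    for _ in range(n_shuffles):
        shift = int(rng.integers(1, T))
        shifted = np.roll(x, shift)
        kin = session.kinematics
        # decode the shifted trace with the original trial segmentation
        sess = SessionData(session.day_index, session.unit_ids,
                           session.activity,
                           with_target_channel(kin, target, shifted),
                           session.sample_rate_hz)
        maes.append(evaluate_cv(sess, target, folds, ridge_strength)["mae"])
    return float(np.mean(maes))


def with_target_channel(kin, target, values):
    """Copy a kinematics series with one channel's values replaced."""
    from .data import KinematicsSeries
    ch = {"position": kin.position, "velocity": kin.velocity,
          "view_angle": kin.view_angle}
    ch[target] = values
    return KinematicsSeries(kin.time, ch["position"], ch["velocity"],
                            ch["view_angle"], kin.trial_id, kin.correct,
                            kin.cue, kin.iti_flag, kin.maze_len_m)


# ------------------------------------------------- multi-day decoders

def _stack(multiday: MultiDayDataset, target: str):
    Z = np.vstack([s.activity for s in multiday.sessions])
    x = np.concatenate([s.target(target) for s in multiday.sessions])
    return Z, x


def fit_concatenated(multiday: MultiDayDataset, target: str,
                     ridge_strength: float = 0.0) -> DecoderWeights:
    """Single decoder minimizing the summed per-day squared error.

    Equivalent to ordinary least squares on the row-stacked data from
    all sessions (which all share the common tracked unit set).
    """
    Z, x = _stack(multiday, target)
    return fit_ols(Z, x, ridge_strength, target)


def fit_constrained_path(multiday: MultiDayDataset, target: str,
                         lambda_grid) -> ConstrainedPathResult:
    """Solve the day-to-day plasticity-constrained decoder path.

    For each lam in ``lambda_grid`` the joint quadratic over per-day
    weights M_1..M_D is solved exactly as one sparse block-tridiagonal
    linear system.  Missing calendar days are ignored: sessions are
    treated as contiguous, so the weight-change penalty couples
    consecutive *sessions*.
    """
    lam_grid = np.sort(np.asarray(lambda_grid, float).ravel())
    if np.any(lam_grid < 0) or np.any(lam_grid >= 1):
        raise InvalidParameterError("lambda values must lie in [0, 1)")
    sessions = multiday.sessions
    D, n = len(sessions), multiday.n_units
    grams = [s.activity.T @ s.activity for s in sessions]
    rhs_blocks = [s.activity.T @ s.target(target) for s in sessions]
    eye = scipy.sparse.identity(n, format="csr")

    all_w, all_err, all_pct = [], [], []
    for lam in lam_grid:
        blocks = [[None] * D for _ in range(D)]
        for d in range(D):
            deg = (d > 0) + (d < D - 1)
            blocks[d][d] = scipy.sparse.csr_matrix(
                (1 - lam) * grams[d]) + lam * deg * eye
            if d < D - 1:
                blocks[d][d + 1] = -lam * eye
                blocks[d + 1][d] = -lam * eye
        H = scipy.sparse.bmat(blocks, format="csc")
        rhs = (1 - lam) * np.concatenate(rhs_blocks)
        M = scipy.sparse.linalg.spsolve(H, rhs).reshape(D, n)
        errs = [mean_abs_error(s.target(target), s.activity @ M[d])
                for d, s in enumerate(sessions)]
        norms = np.linalg.norm(M, axis=1)
        if D > 1:
            dchg = np.linalg.norm(np.diff(M, axis=0), axis=1)
            pct = float(np.mean(dchg) / np.mean(norms) * 100.0)
        else:
            pct = 0.0
        all_w.append(M)
        all_err.append(errs)
        all_pct.append(pct)
    return ConstrainedPathResult(lam_grid, all_w, np.array(all_err),
                                 np.array(all_pct), target)


def permutation_identity_baseline(multiday: MultiDayDataset, target: str,
                                  n_perms: int = 100, seed: int = 0,
                                  test_frac: float = 0.2,
                                  permutations=None) -> dict:
    """Concatenated-decoder error when each day uses a different 'code'.

    For each draw, unit identities are independently permuted within
    every session (destroying cross-day unit correspondence while
    preserving within-day structure), the concatenated decoder is refit
    on the training trials, and the error on held-out trials is
    recorded.  ``permutations`` may supply explicit per-session
    permutations for a single deterministic draw.
    """
    if multiday.n_sessions < 2:
        raise InvalidParameterError("need >= 2 sessions")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = multiday.n_units
    splits = []
    for s in multiday.sessions:
        trials = np.array(sorted(set(s.kinematics.trial_id.tolist())))
        n_test = max(1, int(round(test_frac * len(trials))))
        test_trials = trials[-n_test:]
        test = np.isin(s.kinematics.trial_id, test_trials)
        splits.append((s, test))

    def concat_error(perms):
        Ztr, xtr, Zte, xte = [], [], [], []
        for (s, test), p in zip(splits, perms):
            Z = s.activity[:, p]
            x = s.target(target)
            Ztr.append(Z[~test]); xtr.append(x[~test])
            Zte.append(Z[test]); xte.append(x[test])
        dec = fit_ols(np.vstack(Ztr), np.concatenate(xtr), 0.0, target)
        return mean_abs_error(np.concatenate(xte),
                              predict(dec, np.vstack(Zte)))

    identity = [np.arange(n)] * multiday.n_sessions
    unpermuted = concat_error(identity)
    if permutations is not None:
        return {"errors": np.array([concat_error(permutations)]),
                "unpermuted": unpermuted}
    errors = [concat_error([rng.permutation(n)
                            for _ in range(multiday.n_sessions)])
              for _ in range(n_perms)]
    return {"errors": np.array(errors), "unpermuted": unpermuted}


def cross_day_matrix(multiday: MultiDayDataset, target: str,
                     folds: int = 10, ridge_strength: float = 0.0
                     ) -> np.ndarray:
    """D x D matrix of train-day-i / test-day-j decoding errors.

    Off-diagonal entries train on all of day i and test on all of day
    j; the diagonal holds the same-day cross-validated error, so every
    entry is an error on data unseen by the decoder that produced it.
    """
    sessions = multiday.sessions
    D = len(sessions)
    out = np.zeros((D, D))
    for i, si in enumerate(sessions):
        dec = fit_ols(si.activity, si.target(target), ridge_strength, target)
        for j, sj in enumerate(sessions):
            if i == j:
                out[i, j] = evaluate_cv(si, target, folds,
                                        ridge_strength)["mae"]
            else:
                out[i, j] = mean_abs_error(sj.target(target),
                                           predict(dec, sj.activity))
    return out


def cross_day_r2_matrix(multiday: MultiDayDataset, target: str,
                        folds: int = 10) -> np.ndarray:
    """D x D generalization matrix in R^2 units (used for null matching)."""
    sessions = multiday.sessions
    D = len(sessions)
    out = np.zeros((D, D))
    for i, si in enumerate(sessions):
        dec = fit_ols(si.activity, si.target(target), 0.0, target)
        for j, sj in enumerate(sessions):
            if i == j:
                masks = trial_folds(si.kinematics.trial_id, folds)
                x_all, xh_all = [], []
                for test in masks:
                    d = fit_ols(si.activity[~test], si.target(target)[~test],
                                0.0, target)
                    x_all.append(si.target(target)[test])
                    xh_all.append(predict(d, si.activity[test]))
                out[i, j] = r2_score(np.concatenate(x_all),
                                     np.concatenate(xh_all))
            else:
                out[i, j] = r2_score(sj.target(target),
                                     predict(dec, sj.activity))
    return out


# --------------------------------------------------- subset selection

def _fold_stats(Z, x, masks):
    """Cached per-fold sufficient statistics for subset regression."""
    stats = []
    for test in masks:
        train = ~test
        stats.append({
            "A_tr": Z[train].T @ Z[train], "b_tr": Z[train].T @ x[train],
            "T_tr": int(train.sum()),
            "A_te": Z[test].T @ Z[test], "b_te": Z[test].T @ x[test],
            "ss_te": float(x[test] @ x[test]), "T_te": int(test.sum()),
        })
    return stats


def _subset_cv_mse(stats, S, ridge):
    S = np.asarray(S)
    sse_total, t_total = 0.0, 0
    for st in stats:
        A = st["A_tr"][np.ix_(S, S)] / st["T_tr"] + ridge * np.eye(len(S))
        w = np.linalg.solve(A, st["b_tr"][S] / st["T_tr"])
        sse_total += (st["ss_te"] - 2.0 * w @ st["b_te"][S]
                      + w @ st["A_te"][np.ix_(S, S)] @ w)
        t_total += st["T_te"]
    # pooled over held-out samples, matching evaluate_cv's convention
    return float(sse_total / t_total)


def greedy_rank(session: SessionData, target: str,
                ridge_strength: float = 1e-4, folds: int = 10,
                max_k: int | None = None) -> RankingResult:
    """Rank units by greedy forward selection on CV explained variance.

    Starting from the single most predictive unit, each step adds the
    unit that most reduces the trial-blocked 10-fold CV mean squared
    error.  All candidate fits are evaluated from cached fold-wise
    means/covariances, never re-touching the raw samples; ties break
    toward the lowest unit index.
    """
    Z = session.activity
    x = session.target(target)
    n = Z.shape[1]
    if n < 1:
        raise InvalidParameterError("need >= 1 unit")
    masks = trial_folds(session.kinematics.trial_id, folds)
    stats = _fold_stats(Z, x, masks)
    max_k = n if max_k is None else min(max_k, n)
    selected: list[int] = []
    errors = []
    remaining = list(range(n))
    for _ in range(max_k):
        cand_err = np.array([_subset_cv_mse(stats, selected + [j],
                                            ridge_strength)
                             for j in remaining])
        best = int(np.argmin(cand_err))  # first minimum -> lowest index
        selected.append(remaining.pop(best))
        errors.append(cand_err[best])
    return RankingResult(order=np.array(selected),
                         cv_error_by_k=np.array(errors),
                         ridge_strength=ridge_strength)


# ----------------------------------------------------- extrapolation

def fit_performance_gp(sizes: np.ndarray, errors: np.ndarray,
                       query_sizes: np.ndarray, seed: int = 0) -> dict:
    """Smooth error-vs-population-size with a Matern + white-noise GP.

    Kernel hyperparameters are set by maximum marginal likelihood; the
    returned band is mean +/- 1.96 * predictive sigma.
    """
    sizes = np.asarray(sizes, float)
    X = np.log(sizes[:, None])  # performance curves are smooth in log-size
    gp = GaussianProcessRegressor(
        kernel=ConstantKernel(1.0) * Matern(length_scale=1.0, nu=2.5)
        + WhiteKernel(1e-4, noise_level_bounds=(1e-12, 1e2)),
        normalize_y=True, n_restarts_optimizer=3, random_state=seed)
    gp.fit(X, np.asarray(errors, float))
    q = np.asarray(query_sizes, float)
    mean, sigma = gp.predict(np.log(q[:, None]), return_std=True)
    return {"query_sizes": q, "mean": mean, "sigma": sigma,
            "lower": mean - 1.96 * sigma, "upper": mean + 1.96 * sigma}


def extrapolate_performance(session: SessionData, target: str,
                            subset_sizes, n_draws: int = 20, seed: int = 0,
                            folds: int = 10, query_sizes=None) -> dict:
    """Decoding error versus random-subset size, with a GP extrapolation.

    For each size, ``n_draws`` random unit subsets are cross-validated
    and their errors averaged; the mean curve is then smoothed and
    extrapolated by :func:`fit_performance_gp`.
    """
    sizes = np.asarray(sorted(set(int(s) for s in subset_sizes)))
    if len(sizes) < 3:
        raise InvalidParameterError("need >= 3 distinct subset sizes")
    if sizes.max() > session.n_units:
        raise InvalidParameterError("subset size exceeds population size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mean_err, all_err = [], []
    for k in sizes:
        draws = []
        for _ in range(n_draws):
            cols = rng.choice(session.n_units, size=k, replace=False)
            sub = SessionData(session.day_index, session.unit_ids[cols],
                              session.activity[:, cols], session.kinematics,
                              session.sample_rate_hz)
            draws.append(evaluate_cv(sub, target, folds)["mae"])
        mean_err.append(float(np.mean(draws)))
        all_err.append(draws)
    if query_sizes is None:
        query_sizes = np.unique(np.round(np.geomspace(
            sizes.min(), 2 * sizes.max(), 40))).astype(int)
    gp = fit_performance_gp(sizes, mean_err, query_sizes, seed)
    gp.update({"sizes": sizes, "mean_error": np.array(mean_err),
               "draw_errors": all_err})
    return gp


# ------------------------------------------------- degradation curves

def degradation_curve(multiday: MultiDayDataset, target: str,
                      test_frac: float = 0.2) -> np.ndarray:
    """Normalized R^2 of the concatenated decoder versus span length.

    Entry d is the held-out R^2 of a concatenated decoder fit to
    sessions 1..d+1, divided by the mean held-out R^2 of the same-day
    decoders over that span, clipped to [0, 1].  A stationary code
    stays near 1; drift that a fixed readout cannot track pulls the
    curve down as the span grows.
    """
    sessions = multiday.sessions
    splits = []
    for s in sessions:
        trials = np.array(sorted(set(s.kinematics.trial_id.tolist())))
        n_test = max(1, int(round(test_frac * len(trials))))
        test = np.isin(s.kinematics.trial_id, trials[-n_test:])
        splits.append(test)
    sameday_r2 = []
    for s, test in zip(sessions, splits):
        dec = fit_ols(s.activity[~test], s.target(target)[~test], 0.0, target)
        sameday_r2.append(r2_score(s.target(target)[test],
                                   predict(dec, s.activity[test])))
    curve = []
    for d in range(1, len(sessions) + 1):
        Ztr = np.vstack([s.activity[~t] for s, t in zip(sessions[:d],
                                                        splits[:d])])
        xtr = np.concatenate([s.target(target)[~t]
                              for s, t in zip(sessions[:d], splits[:d])])
        dec = fit_ols(Ztr, xtr, 0.0, target)
        x_all, xh_all = [], []
        for s, t in zip(sessions[:d], splits[:d]):
            x_all.append(s.target(target)[t])
            xh_all.append(predict(dec, s.activity[t]))
        r2_cat = r2_score(np.concatenate(x_all), np.concatenate(xh_all))
        denom = float(np.mean(sameday_r2[:d]))
        curve.append(np.clip(r2_cat / denom if denom > 0 else 0.0, 0.0, 1.0))
    return np.array(curve)
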