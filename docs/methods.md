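# Methods

`driftstab` asks a single scientific question in several ways: when a
population code reconfigures ("drifts") from day to day while behavior
stays fixed, can a *fixed* linear readout still recover behavioral
variables, and if not, how much ongoing weight change does it take to
keep up?  This note documents the models, estimators, parameter
choices and numerical conventions behind each stage, and what the
synthetic data used by the tests do and do not establish.

## The decoding model

All decoders are linear readouts of normalized fluorescence:
`x̂(t) = Mᵀ z(t)`, where `z(t)` is the T×n activity matrix of one or
more sessions and `x(t)` is one kinematic channel (linearized maze
position in m, forward velocity in m/s, or view angle in degrees).
For offline decoding, inter-trial intervals are removed, only correct
trials are kept, and activity and kinematics are centered to zero mean
on each trial, so decoders carry no bias term.  `M` is the
ordinary-least-squares solution; an optional ridge adds a constant to
the diagonal of the activity covariance (default 1e-4 where
regularization is requested, e.g. greedy ranking).

Performance is reported as the mean absolute error over held-out
samples under 10-fold cross-validation.  Folds are contiguous blocks
of whole trials — a trial is never split across folds — because the
slow calcium dynamics would otherwise leak information between train
and test.  Chance level is measured by circularly shifting the
kinematics trace relative to the activity by a random offset and
re-running the cross-validation (mean over shuffles).

## Multi-day decoders

*Concatenated decoder*: one weight vector minimizing the summed
squared error over all sessions of a span, equivalent to OLS on the
row-stacked data restricted to the units tracked in every session.

*Plasticity-constrained path*: per-day weights `M_1..M_D` minimizing

    (1 − λ) Σ_d ‖x_d − M_dᵀ z_d‖² + λ Σ_d ‖M_{d+1} − M_d‖² ,

for λ ∈ [0, 1).  This is an unconstrained quadratic; we assemble the
block-tridiagonal normal equations and solve them exactly with a
sparse direct solver — no iteration, no tolerance beyond the linear
solve.  λ = 0 decouples into independent per-day OLS fits; λ → 1
forces all `M_d` equal and recovers the concatenated decoder (we use
λ = 1 − 1e-9 as the numerical limit; the system remains solvable
because the data term still breaks the translation degeneracy).
Sessions are treated as contiguous regardless of calendar gaps; true
day indices are kept in metadata.

Percent weight change along the path (and for LMS below) is
`‖M_{d+1} − M_d‖₂ / mean_d ‖M_d‖₂ × 100` per session interval, or
divided additionally by the days elapsed when a per-day rate is
needed.

*Degradation curves*: for span lengths d = 1..D we fit the
concatenated decoder to the training trials of the first d sessions
and evaluate R² on their held-out trials; dividing by the mean
same-day decoder R² over the same span and clipping to [0, 1] gives a
"normalized R²" that is 1 for a stationary code and decays when a
fixed readout cannot track drift.  The normalization by the same-day
ceiling is our convention; it removes the noise floor so that curves
from datasets with different SNR are comparable.

*Best-K-subset ranking*: greedy forward selection on cross-validated
MSE, computed entirely from cached fold-wise sufficient statistics
(per-fold train/test Gram matrices and cross-moments), so the several
thousand candidate fits never re-touch the raw samples.  CV MSE is
pooled over held-out samples (not a mean of fold means) to match the
plain cross-validation estimator exactly.  Ties break toward the
lowest unit index for determinism.

*Performance extrapolation*: mean CV error over random unit subsets
per size, smoothed by Gaussian-process regression (Matérn ν = 5/2 plus
a white-noise kernel, hyperparameters by maximum marginal likelihood)
on log population size; the uncertainty band is ±1.96 predictive σ.

## The matched random-drift null model

The null model generates a synthetic drifting readout over real (or
synthetic) activity: `x_r = M_rᵀ z + ε_r` with `M_1` i.i.d. uniform on
[0, 1] and `ε_r` i.i.d. Gaussian, regenerated each day.  Two
constraints define each drift step:

1. **Norm conservation**, `‖M_{r+1}‖₂ = ‖M_r‖₂`.
2. **Matched decorrelation**: the expected R² of `M_{r+1}ᵀz` against
   the prediction `M_rᵀz` equals a target.  We compute this R²
   analytically as the squared correlation of the two projections
   under the day's empirical activity covariance — a ratio of
   quadratic forms — rather than by regression on sampled noise, which
   makes the constraint deterministic and lets us solve the
   unconstrained step in closed form: a white-noise candidate is split
   into components parallel and orthogonal to `M_r`, the mixture angle
   parametrizes a norm-conserving family, and the angle achieving the
   target R² is found by bisection.

The drift target is matched to data as follows: the mean day-adjacent
entry of the cross-day generalization R² matrix measures decorrelation
*including* observation noise, so we divide it by the mean same-day
(noise-limited) R² to isolate the decorrelation attributable to drift.
The noise scale of `ε_r` is then calibrated by monotone bisection so a
decoder trained on `(z, x_1)` matches the data's mean single-day MAE.

*Low-rank variant*: confining `ΔM_r` to the span of k fixed random
orthonormal basis vectors turns each step into a non-convex
quadratically-constrained program.  We exploit its structure instead
of calling a general NLP solver: with `ΔM = Bγ`, norm conservation
restricts `γ` to a sphere through the origin, which we parametrize
exactly; the remaining R² equation is solved by bisection along
geodesics of that sphere seeded from unit-Gaussian random directions
(up to 20 restarts).  Norm conservation therefore holds to machine
precision, and a failure to find a root means the subspace genuinely
cannot decorrelate the readout that far.

That failure mode is real physics, not a solver artifact: a rank-k
subspace has a floor on achievable decorrelation that depends on how
much of the activity covariance it captures, and for small k the
matched target is often below that floor.  `drift_step` raises a
`DriftStepInfeasibleError` by default; `run_null_experiment` instead
clips to the most decorrelating reachable step, so that an
undersized-rank null *under-drifts* — which is precisely the
signature by which rank sweeps identify the true drift rank.

## Drift-alignment statistics

For alignment analyses, activity is log-transformed (floored at 1e-3
of each unit's maximum, since fluorescence can touch zero), band-pass
filtered between 0.03 and 0.3 Hz with a zero-phase forward-backward
4th-order Butterworth, and z-scored per unit.  Per trial, location is
normalized to [0, 1] (trial pseudotime) and activity averaged within
50 equal bins (bin count configurable; the analyses are insensitive
over 8–50 at the tested scales).  Means μ and covariances Σ are taken
over trials within each (bin, cue) cell; location-gradient moments use
central finite differences of the per-trial binned activity, one-sided
at the maze ends.

For a drift vector Δμ (change in conditioned mean between days) and a
reference matrix A — Σ for noise alignment, or the gradient second
moment Σ∇ + μ∇μ∇ᵀ for coding alignment — the statistics are

    φ²  = Δμᵀ A Δμ / (‖Δμ‖² λmax(A)),
    φ0² = tr(A) / (D λmax(A)),
    ρ   = (φ − φ0) / (1 − φ0),

so φ² = 1 when drift lies along the top eigenvector, φ0² is the
expected φ² of a randomly oriented drift vector, and ρ is 0 at chance
and 1 at perfect alignment.  λmax for the coding mode is taken from
the gradient second-moment matrix itself; the reference matrix is
symmetrized and its diagonal ridged by 1e-6 λmax before the eigen-
decomposition to guard against near-singular trial-limited covariance.
Chance levels come from Monte-Carlo sampling of drift vectors uniform
on the unit sphere (we report the mean and the 95th percentile).  Note
that E[ρ] under random drift is slightly below zero — ρ uses φ = √φ²
and the square root is concave — by an amount that grows with the
eigenvalue spread of A; it stays well within the Monte-Carlo tolerance
for reasonably conditioned references.

ρ values are pooled over location bins and consecutive session pairs,
with the reference moments taken from the earlier session of each
pair.  Cue conditioning uses the current trial's cue by default (two
cells); conditioning on the previous trial's cue as well would halve
the per-cell trial count, and the synthetic task carries no
history-dependent structure for it to expose, so it is left out here.

## Online LMS decoder

The least-mean-squares rule is stochastic gradient descent on the
affine prediction error: `x̂ = wᵀz + b`, `e = x − x̂`, `w ← w + η e z`,
`b ← b + η e`, one update per 5.3 Hz sample.  The decoder is
initialized by batch OLS (with bias) on the first two sessions and
then streamed through the remaining sessions strictly causally — raw,
uncentered kinematics serve as the teaching signal because per-trial
centering would require future samples.  A frozen copy (η = 0) is
streamed in parallel as the no-plasticity baseline, and batch
comparators are evaluated with the same affine convention for
fairness.  Weight divergence (norm exceeding 1e6 × initial) raises
immediately so unstable learning rates fail loudly inside sweeps; the
classical stability bound η < 2/E‖z‖² holds on standardized inputs.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of the multi-day virtual-maze
recordings: a 4.5 m linearized maze sampled at 5.3 Hz; trials of ~9 s
with smooth velocity profiles, a binary visual cue, a cue-dependent
view-angle turn in the final quarter of the maze, ~85% correct trials
and flagged inter-trial intervals; populations of tens to hundreds of
units whose Gaussian-bump tuning curves (widths 0.05–0.15 of the
maze, peak-normalized, baseline up to 0.1) tile the maze uniformly;
trial-to-trial covariability from a rank-5-plus-diagonal factor
model; and slow calcium-like dynamics from a causal exponential filter
(decay 0.7 s) applied to the noiseless rates.  Defaults are 200
trials per session and session spans with at most 2-day gaps.

Drift modes:

- `random_walk` — isotropic diffusion of tuning peaks and gains; the
  per-day RMS fractional parameter change equals `step_size` exactly
  (directions are drawn first and rescaled), so drift-rate calibration
  is by construction.
- `low_rank` — the same diffusion confined to a fixed rank-k subspace
  of parameter space.
- `noise_aligned_mix` — drift of the per-unit coefficients of a shared
  location-modulation channel (`sin 2πx`), with fraction `f` of the
  drift power along the top noise-covariance eigenvectors.  A constant
  per-unit offset would be erased by the z-scoring that precedes the
  alignment analyses, which is why the drifting pattern must co-vary
  with location; this mode gives the alignment statistics a ground
  truth to recover (measured ρ_noise increases monotonically in `f`).

One deliberate limitation matters for interpreting the tests: tuning-
parameter drift (peaks/gains) degrades *cross-day generalization*
strongly but leaves *concatenated* decoders nearly intact, because a
one-dimensional position variable read out from 100+ tiled units is
massively redundant and rank structure in parameter space does not map
onto low-rank structure in readout-weight space (tuning is nonlinear
in its parameters).  The systematic-versus-random comparisons are
therefore run where the paper's own logic places them: on readouts
drifting over a stationary population — rank-confined versus
unconstrained weight walks at matched decorrelation — generated with
the null-model machinery itself.  Passing those tests shows the
pipeline reproduces the ordering (low-rank systematic drift preserves
a fixed readout far longer, and costs LMS several-fold less plasticity,
than matched full-rank drift); it does not by itself certify any
biological claim about real recordings.

Other things the generator does not emulate: biophysical indicator
kinetics or spike inference, 2-D maze geometry, behavioral learning,
history-dependent (previous-cue) structure, and non-stationary noise
statistics.

## Problem sizes and determinism

The test suite runs the decisive comparisons at desk scale, chosen as
the smallest sizes at which the effects are unambiguous: 150 units ×
10 sessions × 30 trials for the constrained-path limits and the
systematic-versus-random comparisons (50 paired seeds for the
degradation ordering; 3 seeds × 5 learning rates for the LMS
plasticity contrast); 60 units for rank recovery (8 data replicates,
20 null resamples per rank); 100 seeds for the null-model step
contract.  All randomness flows from named `SeedSequence` roots, and
identical (config, seed) pairs reproduce outputs byte-for-byte,
including HDF5 archives (written without modification timestamps) and
full-precision CSV round-trips.
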