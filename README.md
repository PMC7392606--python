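# driftstab

**Does a drifting neural population code support a stable linear
readout?**

Over days to weeks, the tuning of individual cortical neurons to task
variables reconfigures even while behavior stays constant
("representational drift").  `driftstab` is a toolbox for asking, with
multi-day calcium-imaging population recordings or matched synthetic
data, whether that drift is random or systematic from the point of
view of a downstream linear readout — and how much ongoing synaptic
plasticity it would take to compensate.  It is aimed at systems and
computational neuroscientists analyzing chronic population recordings
aligned with continuous behavior (position, velocity, heading).

The package provides, as composable library modules with a thin CLI:

- **`synthetic`** — a generator of multi-day, drifting, place-tuned
  population activity: a 4.5 m linearized virtual maze sampled at
  5.3 Hz, trials with binary cues and inter-trial intervals, tuning
  curves tiling the maze, factor-model noise correlations, and drift
  with controllable rank, step size, and alignment to noise
  directions.
- **`dataio`** — HDF5/CSV session formats, a best-effort reader for
  the public deposition layout, and the preprocessing rules: ITI
  removal, correct-trials-only, per-trial centering for decoding;
  cross-day unit tracking with a ≤2-day gap rule; log + 0.03–0.3 Hz
  band-pass + z-score for the alignment analyses.
- **`decoding`** — the linear readout machinery.  Single-day OLS
  decoders `x̂ = Mᵀz` with trial-blocked 10-fold cross-validation,
  chance (circular-shuffle) and unit-identity-permutation baselines,
  D×D cross-day generalization matrices, the *concatenated* decoder
  (one M fit to all days, Σ_d ‖x_d − Mᵀz_d‖²), the
  *plasticity-constrained path*
  `(1−λ) Σ_d ‖x_d − M_dᵀ z_d‖² + λ Σ_d ‖M_{d+1} − M_d‖²`
  solved exactly as a block-tridiagonal system for each λ, greedy
  best-K-subset ranking from cached sufficient statistics, and
  Gaussian-process extrapolation of error versus population size.
- **`null_model`** — a statistically matched random-drift null: a
  synthetic readout `x_r = M_rᵀz + ε_r` whose day-to-day weight walk
  conserves ‖M_r‖ exactly and realizes a target between-day R²
  (matched to how fast the data's own single-day decoders degrade),
  with an optional rank-k confinement solved as a quadratically-
  constrained program.
- **`alignment`** — the normalized drift-alignment statistics
  φ² = ΔμᵀAΔμ/(‖Δμ‖²λmax), φ0² = tr(A)/(D·λmax),
  ρ = (φ−φ0)/(1−φ0) against noise-covariance or location-coding
  reference matrices, with Monte-Carlo chance calibration.
- **`lms`** — an online least-mean-squares affine decoder
  (`w ← w + η e z`, per sample) that tracks drift across sessions,
  with per-session weight-change accounting and learning-rate sweeps.
- **`pipeline` / `driftstab` CLI** — YAML-configured orchestration of
  all stages with seeded, hash-manifested, reproducible outputs.

## Worked example

```python
import numpy as np
from driftstab import synthetic as sy, dataio, decoding, lms

# 150 units, 8 sessions, random-walk tuning drift at 5%/day
cfg = sy.SimulateConfig(
    n_units=150, n_sessions=8, n_trials=40, seed=1,
    drift=sy.DriftSpec("random_walk", step_size=0.05, seed=2),
)
dataset = sy.generate_dataset(cfg)
prep = dataset.map_sessions(dataio.prepare_decoding_series)

cv = decoding.evaluate_cv(prep[0], "position", folds=10)
chance = decoding.chance_level(prep[0], "position", n_shuffles=20, seed=0)
print(f"same-day position MAE: {cv['mae']:.3f} m (chance {chance:.3f} m)")

cat = decoding.fit_concatenated(prep, "position")
cat_mae = np.mean([decoding.mean_abs_error(
    s.target("position"), decoding.predict(cat, s.activity))
    for s in prep.sessions])
print(f"concatenated decoder MAE over {prep.n_sessions} sessions: {cat_mae:.3f} m")

path = decoding.fit_constrained_path(prep, "position", [0.0, 0.5, 0.9, 0.999])
for lam, err, pct in zip(path.lambda_grid,
                         path.per_day_error.mean(axis=1),
                         path.pct_weight_change):
    print(f"  lambda={lam:<6g} mean MAE {err:.3f} m, "
          f"weight change {pct:5.1f} %/session")

raw = dataset.map_sessions(lambda s: dataio.prepare_decoding_series(s, center=False))
res = lms.run_online(raw, "position", eta=4e-4)
stats = lms.weight_change_stats(res["snapshots"], res["day_gaps"])
print(f"LMS (eta=4e-4): MAE {res['mae_per_session'].mean():.3f} m "
      f"vs frozen {res['mae_frozen'].mean():.3f} m, "
      f"weight change {stats['mean_pct_per_session']:.1f} %/session")
```

prints

```
same-day position MAE: 0.249 m (chance 1.167 m)
concatenated decoder MAE over 8 sessions: 0.228 m
  lambda=0      mean MAE 0.193 m, weight change 104.9 %/session
  lambda=0.5    mean MAE 0.191 m, weight change  74.1 %/session
  lambda=0.9    mean MAE 0.195 m, weight change  35.5 %/session
  lambda=0.999  mean MAE 0.221 m, weight change   1.8 %/session
LMS (eta=4e-4): MAE 0.329 m vs frozen 0.496 m, weight change 4.0 %/session
```

Reading these numbers: a single-day linear decoder recovers position
to ~0.25 m against a ~1.2 m chance level, and a *fixed* decoder fit
jointly across all eight drifting sessions is nearly as good on this
synthetic code (0.23 m, training error) — drift does not preclude a
stable readout here.  The constrained path interpolates between
independent per-day decoders (λ=0, best error, large day-to-day weight
changes) and the concatenated decoder (λ→1, ~0 weight change, modest
error cost).  Streaming the sessions through the local LMS rule tracks
the drift (0.33 m) where the same decoder frozen after two sessions
degrades (0.50 m), at a cost of ~4% weight change per session.

## CLI

```sh
driftstab run --config cfg.yaml          # all configured stages
driftstab decode --config cfg.yaml --target position
driftstab nullmodel --config cfg.yaml --rank 14
driftstab align --config cfg.yaml --mode noise
driftstab lms --config cfg.yaml --eta 4e-4
driftstab report --manifest out/manifest.json
```

A config names the input (a `simulate:` block or a dataset path), the
stages, per-stage parameters, an output directory and a global seed;
unknown keys are errors.  Outputs are CSV tables, HDF5 archives and a
`manifest.json` recording seeds and output hashes.  See
`docs/methods.md` for the models, conventions and parameter choices.

### Deposited-data field map

`load_dataset(path, format="deposited_mat")` reads a directory of
per-session MAT v7.3 files with variables `dFF` (T×n activity),
`position`, `velocity`, `viewAngle`, `trial`, `correct`, `cue`, `iti`,
`time`, `unit_ids`, and scalars `day_index`, `sample_rate_hz`,
`maze_len_m`, mapping them onto the in-memory session containers and
applying the cross-day unit tracking.

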