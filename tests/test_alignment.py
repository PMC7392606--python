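"""Drift-alignment statistics: moments, phi/rho, chance calibration."""

import numpy as np
import pytest

from driftstab import alignment as al, dataio, synthetic as sy
from driftstab.data import (DataIntegrityError, KinematicsSeries,
                            SessionData)


def _zscored_session(md_session):
    """Per-unit z-score without the log/band-pass (linear processing
    preserves the generator's injected drift direction exactly)."""
    sub = md_session.select_samples(~md_session.kinematics.iti_flag)
    a = sub.activity
    a = (a - a.mean(axis=0)) / np.maximum(a.std(axis=0), 1e-12)
    return SessionData(sub.day_index, sub.unit_ids, a, sub.kinematics,
                       sub.sample_rate_hz)


def _processed_session(md_session):
    sub = md_session.select_samples(~md_session.kinematics.iti_flag)
    act = dataio.bandpass_zscore(sub.activity + 1.0,
                                 sample_rate_hz=sub.sample_rate_hz)
    return SessionData(sub.day_index, sub.unit_ids, act, sub.kinematics,
                       sub.sample_rate_hz)


@pytest.fixture(scope="module")
def processed_pair(drifting_dataset):
    return (_processed_session(drifting_dataset[0]),
            _processed_session(drifting_dataset[1]))


def _toy_session(n_trials=3, n_bins_samples=10, n_units=4, seed=0,
                 cue=None):
    """Tiny session with one sample per (trial, pseudo-location)."""
    rng = np.random.default_rng(seed)
    T = n_trials * n_bins_samples
    pos = np.tile(np.linspace(0, 4.5, n_bins_samples), n_trials)
    trial = np.repeat(np.arange(n_trials), n_bins_samples)
    cues = np.zeros(T, int) if cue is None else np.repeat(cue,
                                                          n_bins_samples)
    kin = KinematicsSeries(np.arange(T) / 5.3, pos,
                           np.gradient(pos) * 5.3, np.zeros(T), trial,
                           np.ones(T, bool), cues, np.zeros(T, bool))
    act = rng.standard_normal((T, n_units))
    return SessionData(0, np.arange(n_units), act, kin)


class TestConditionedMoments:

    def test_constant_activity_gives_zero_covariance(self):
        s = _toy_session()
        s.activity[:] = 2.5
        mom = al.conditioned_moments(s, n_location_bins=5,
                                     condition_on_cue=False)
        for cell in mom.cells():
            assert np.allclose(mom.mean[cell], 2.5)
            assert np.allclose(mom.cov[cell], 0.0)

    def test_matches_naive_loop_oracle(self):
        s = _toy_session(n_trials=3, n_bins_samples=5, n_units=3, seed=1)
        n_bins = 5
        mom = al.conditioned_moments(s, n_location_bins=n_bins,
                                     condition_on_cue=False)
        # naive per-cell loop: with exactly one sample per bin per
        # trial, the bin average is the sample itself
        act = s.activity.reshape(3, 5, 3)  # trial, bin, unit
        for b in range(n_bins):
            vals = act[:, b, :]
            assert np.allclose(mom.mean[(b, None)], vals.mean(axis=0))
            assert np.allclose(mom.cov[(b, None)],
                               np.cov(vals.T, bias=False))

    def test_scaling_law(self):
        s = _toy_session(seed=2)
        mom1 = al.conditioned_moments(s, 5, condition_on_cue=False)
        s2 = SessionData(0, s.unit_ids, 2.0 * s.activity, s.kinematics)
        mom2 = al.conditioned_moments(s2, 5, condition_on_cue=False)
        cell = mom1.cells()[0]
        assert np.allclose(mom2.mean[cell], 2.0 * mom1.mean[cell])
        assert np.allclose(mom2.cov[cell], 4.0 * mom1.cov[cell])

    def test_insufficient_trials_raises_with_cell_name(self):
        s = _toy_session(n_trials=3, cue=np.array([0, 0, 1]))
        with pytest.raises(al.InsufficientDataError, match="cue=1"):
            al.conditioned_moments(s, 5, condition_on_cue=True,
                                   min_trials=2)

    def test_cue_conditioning_splits_cells(self):
        s = _toy_session(n_trials=4, cue=np.array([0, 1, 0, 1]), seed=3)
        mom = al.conditioned_moments(s, 5, condition_on_cue=True)
        assert mom.conditions == (0, 1)
        assert len(mom.cells()) == 10


class TestDriftVectors:

    def test_identical_days_give_zero_drift(self, processed_pair):
        a, _ = processed_pair
        mom = al.conditioned_moments(a, 10)
        d = al.drift_vectors(mom, mom)
        assert all(np.allclose(v, 0) for v in d.values())

    def test_antisymmetry(self, processed_pair):
        a, b = processed_pair
        ma = al.conditioned_moments(a, 10)
        mb = al.conditioned_moments(b, 10)
        fwd = al.drift_vectors(ma, mb)
        bwd = al.drift_vectors(mb, ma)
        for cell in fwd:
            assert np.allclose(fwd[cell], -bwd[cell])

    def test_structure_mismatch_rejected(self, processed_pair):
        a, b = processed_pair
        ma = al.conditioned_moments(a, 10)
        mb = al.conditioned_moments(b, 12)
        with pytest.raises(DataIntegrityError):
            al.drift_vectors(ma, mb)


class TestAlignmentRho:

    def test_principal_eigenvector_gives_rho_one(self):
        rng = np.random.default_rng(4)
        G = rng.standard_normal((10, 10))
        A = G @ G.T
        w, V = np.linalg.eigh(A)
        top = V[:, -1]
        sc = al.alignment_rho(top, A, "noise")
        assert sc.phi_sq == pytest.approx(1.0, abs=1e-6)
        assert sc.rho == pytest.approx(1.0, abs=1e-5)

    def test_isotropic_matrix_gives_unit_chance(self):
        A = 3.0 * np.eye(8)
        sc = al.alignment_rho(np.random.default_rng(5).standard_normal(8),
                              A, "noise")
        assert sc.phi_chance_sq == pytest.approx(1.0, abs=1e-5)

    def test_quadratic_form_matches_sampling_oracle(self):
        # Monte-Carlo for the mean squared dot product of the drift
        # with fluctuations drawn from N(0, A)
        rng = np.random.default_rng(6)
        G = rng.standard_normal((12, 12))
        A = G @ G.T / 12
        dmu = rng.standard_normal(12)
        dmu /= np.linalg.norm(dmu)
        L = np.linalg.cholesky(A + 1e-12 * np.eye(12))
        dz = (L @ rng.standard_normal((12, 100_000))).T
        mc = np.mean((dz @ dmu) ** 2)
        quad = dmu @ A @ dmu
        assert abs(mc - quad) / quad < 0.02

    def test_rho_invariant_to_scales(self):
        rng = np.random.default_rng(7)
        G = rng.standard_normal((9, 9))
        A = G @ G.T
        dmu = rng.standard_normal(9)
        a = al.alignment_rho(dmu, A, "noise").rho
        b = al.alignment_rho(5.0 * dmu, 0.1 * A, "noise").rho
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_drift_rejected(self):
        with pytest.raises(al.UndefinedAlignmentError):
            al.alignment_rho(np.zeros(5), np.eye(5), "noise")

    def test_coding_mode_uses_gradient_second_moment(self, processed_pair):
        a, _ = processed_pair
        mom = al.conditioned_moments(a, 10)
        cell = mom.cells()[3]
        ref = mom.reference_matrix(cell, "coding")
        g = mom.grad_mean[cell]
        assert np.allclose(ref, mom.grad_cov[cell] + np.outer(g, g))


class TestChanceAlignment:

    def test_mean_rho_near_zero(self):
        rng = np.random.default_rng(8)
        G = rng.standard_normal((12, 12))
        A = G @ G.T / 12
        res = al.chance_alignment_mc(A, "noise", n_samples=2000, seed=9)
        assert abs(res["mean"]) < 3 / np.sqrt(2000) + 0.03
        assert np.all(res["rho_samples"] <= 1.0)

    def test_p95_positive_and_below_one(self, processed_pair):
        a, _ = processed_pair
        mom = al.conditioned_moments(a, 10)
        res = al.chance_alignment_mc(mom, "noise", n_samples=300,
                                     seed=10, cell=mom.cells()[0])
        assert 0 < res["p95"] < 1


class TestGroundTruthRecovery:

    def test_injected_drift_direction_recovered(self):
        # drift injected along a known unit vector: the measured change
        # in conditioned means should point the same way at low noise
        rng = np.random.default_rng(11)
        n = 12
        ens = sy.generate_ensemble(n, seed=12, noise_scale=0.02)
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        from dataclasses import replace
        ens2 = replace(ens, mod_coefs=ens.mod_coefs + 0.5 * v)
        kin = sy.generate_kinematics(4.5, 30, 5.3, seed=13)
        np_ = sy.NoiseParams(0.2, 0.2, 0.0)
        s1 = sy.simulate_session(ens, kin, np_, seed=14)
        s2 = sy.simulate_session(ens2, kin, np_, seed=15)
        m1 = al.conditioned_moments(s1, 8, condition_on_cue=False)
        m2 = al.conditioned_moments(s2, 8, condition_on_cue=False)
        d = al.drift_vectors(m1, m2)
        # the injected pattern flips sign with sin(2 pi x), so check
        # each cell's drift direction up to sign
        overlaps = []
        for c in m1.cells():
            dmu = d[c]
            if np.linalg.norm(dmu) > 0.05:
                overlaps.append(abs(dmu @ v) / np.linalg.norm(dmu))
        assert np.median(overlaps) > 0.9

    def test_rho_noise_increases_with_alignment_fraction(self):
        # ground-truth recovery: drift placed along noise-covariance
        # eigenvectors at fraction f should yield monotonically
        # increasing rho_noise
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        n_seeds = 10
        means = []
        for f in fractions:
            vals = []
            for seed in range(n_seeds):
                cfg = sy.SimulateConfig(
                    n_units=25, n_sessions=2, n_trials=40, seed=seed,
                    drift=sy.DriftSpec("noise_aligned_mix",
                                       step_size=0.5,
                                       noise_align_frac=f,
                                       seed=seed + 100),
                    noise_params=sy.NoiseParams(1.0, 0.2, 0.0))
                md = sy.generate_dataset(cfg)
                p0, p1 = (_zscored_session(md[0]),
                          _zscored_session(md[1]))
                res = al.pooled_rho([p0, p1], "noise",
                                    n_location_bins=8,
                                    condition_on_cue=False)
                vals.append(res["mean_rho"])
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_separation_noise_vs_coding_directions(self, processed_pair):
        a, _ = processed_pair
        mom = al.conditioned_moments(a, 10)
        cell = mom.cells()[4]
        noise_ref = mom.reference_matrix(cell, "noise")
        code_ref = mom.reference_matrix(cell, "coding")
        top_noise = np.linalg.eigh(noise_ref)[1][:, -1]
        top_code = np.linalg.eigh(code_ref)[1][:, -1]
        # drift confined to each matrix's principal direction must align
        # better with its own reference than with the other
        rho_nn = al.alignment_rho(top_noise, noise_ref, "noise").rho
        rho_nc = al.alignment_rho(top_noise, code_ref, "coding").rho
        rho_cc = al.alignment_rho(top_code, code_ref, "coding").rho
        rho_cn = al.alignment_rho(top_code, noise_ref, "noise").rho
        assert rho_nn > rho_nc
        assert rho_cc > rho_cn
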