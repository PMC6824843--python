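import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilat.core import canonical_load_set
from bilat.preprocess import EpochMeans
from bilat.tuning import (
    PlanarFit,
    fit_plane,
    fit_planes,
    load_sensitivity_anova,
    magnitude_contrast,
    rayleigh_bootstrap_p,
    rayleigh_stats,
    tuning_difference,
)

TAUS = np.array([ld.torque_vector for ld in canonical_load_set()])


def _means_from_rates(baseline, perturbation):
    """EpochMeans for one neuron from (8, n_trials) rate arrays per context."""
    per = {}
    for ctx in ("contra", "ipsi"):
        per[ctx] = {
            "baseline": baseline[ctx][None],
            "perturbation": perturbation[ctx][None],
            "steady_state": perturbation[ctx][None],
        }
    return EpochMeans(neuron_ids=[0], per_trial=per)


class TestSensitivityAnova:
    def test_no_epoch_effect_is_not_sensitive(self):
        rng = np.random.default_rng(0)
        rates = {ctx: rng.normal(10, 1, (8, 6)) for ctx in ("contra", "ipsi")}
        res = load_sensitivity_anova(_means_from_rates(rates, rates))[0]
        assert not res.load_sensitive
        assert res.p_epoch == pytest.approx(1.0)

    def test_single_load_response_found_by_interaction(self):
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            base = {ctx: rng.normal(10, 2, (8, 6)) for ctx in ("contra", "ipsi")}
            pert = {ctx: rng.normal(10, 2, (8, 6)) for ctx in ("contra", "ipsi")}
            pert["contra"][3] += 20.0  # respond on one load only
            res = load_sensitivity_anova(_means_from_rates(base, pert))[0]
            hits += res.load_sensitive
        assert hits >= 95

    def test_study_scale_fraction_sensitive(self, default_sensitivity):
        frac = np.mean([s.load_sensitive for s in default_sensitivity])
        assert frac > 0.5


class TestPlanarFit:
    def test_exact_on_noiseless_plane(self):
        rates = 10.0 + TAUS @ np.array([5.0, 3.0])
        fit = fit_plane(np.repeat(rates, 3), np.repeat(TAUS, 3, axis=0))
        assert fit.b_shoulder == pytest.approx(5.0, abs=1e-9)
        assert fit.b_elbow == pytest.approx(3.0, abs=1e-9)
        assert fit.preferred_angle_deg == pytest.approx(np.degrees(np.arctan2(3, 5)), abs=1e-9)
        assert fit.magnitude_hz_per_nm == pytest.approx(np.sqrt(34.0), abs=1e-9)
        assert fit.p_value < 1e-12

    def test_null_rates_give_near_zero_magnitude_and_uniform_p(self):
        ps, mags = [], []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            fit = fit_plane(rng.normal(10, 1, 40), np.repeat(TAUS, 5, axis=0))
            ps.append(fit.p_value)
            mags.append(fit.magnitude_hz_per_nm)
        assert np.median(mags) < 3.0
        # p approximately uniform: quartiles spread out
        assert np.percentile(ps, 25) > 0.05 and np.percentile(ps, 75) < 0.99

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_plane(np.ones(8), np.tile([[0.2, 0.0]], (8, 1)))

    def test_recovers_ground_truth_angles(self, default_bundle):
        truth = default_bundle["truth"]
        fits = fit_planes(default_bundle["means"], "contra")
        strong = [
            f for f in fits
            if f.significant and truth.gain_hz_per_nm["contra"][f.neuron_id] > 20
        ]
        errs = [
            abs((f.preferred_angle_deg - truth.preferred_angle_deg["contra"][f.neuron_id] + 180) % 360 - 180)
            for f in strong
        ]
        assert np.median(errs) < 10.0


class TestRayleigh:
    def test_degenerate_and_axial_examples(self):
        assert rayleigh_stats([135.0] * 5, "unimodal").R == pytest.approx(1.0)
        pair = [0.0, 180.0]
        assert rayleigh_stats(pair, "unimodal").R == pytest.approx(0.0, abs=1e-12)
        assert rayleigh_stats(pair, "bimodal").R == pytest.approx(1.0)
        quad = [0.0, 90.0, 180.0, 270.0]
        assert rayleigh_stats(quad, "unimodal").R == pytest.approx(0.0, abs=1e-12)
        assert rayleigh_stats(quad, "bimodal").R == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        shift=st.floats(0.0, 360.0),
        seed=st.integers(0, 1000),
        mode=st.sampled_from(["unimodal", "bimodal"]),
    )
    def test_rotation_invariance(self, shift, seed, mode):
        angles = np.random.default_rng(seed).uniform(0, 360, 25)
        r0 = rayleigh_stats(angles, mode)
        r1 = rayleigh_stats(angles + shift, mode)
        assert r1.R == pytest.approx(r0.R, abs=1e-9)

    def test_bootstrap_p_degenerate_and_reproducible(self):
        angles = [135.0] * 50
        assert rayleigh_bootstrap_p(angles, "unimodal", 500, seed=1) == 0.0
        rng_angles = np.random.default_rng(2).uniform(0, 360, 40)
        p1 = rayleigh_bootstrap_p(rng_angles, "bimodal", 500, seed=3)
        p2 = rayleigh_bootstrap_p(rng_angles, "bimodal", 500, seed=3)
        p3 = rayleigh_bootstrap_p(rng_angles[::-1], "bimodal", 500, seed=3)
        assert p1 == p2 == p3

    def test_default_session_bimodal_in_both_contexts(self, default_bundle, default_sensitivity):
        sens = {s.neuron_id for s in default_sensitivity if s.load_sensitive}
        for ctx in ("contra", "ipsi"):
            fits = [f for f in fit_planes(default_bundle["means"], ctx) if f.neuron_id in sens]
            angles = np.array([f.preferred_angle_deg for f in fits])
            assert rayleigh_bootstrap_p(angles, "bimodal", 1000, seed=4) < 0.01


def _fits_from_angles(angles, mags=None, p=1e-6):
    mags = np.ones(len(angles)) if mags is None else mags
    return [
        PlanarFit(
            neuron_id=i, context="contra", epoch="perturbation", offset_hz=0.0,
            b_shoulder=m * np.cos(np.radians(a)), b_elbow=m * np.sin(np.radians(a)),
            p_value=p,
        )
        for i, (a, m) in enumerate(zip(angles, mags))
    ]


class TestTuningDifference:
    def test_identity_gives_unit_R_at_zero_axis(self):
        fits = _fits_from_angles(np.linspace(0, 330, 12))
        td = tuning_difference(fits, fits, n_boot=200, seed=0)
        assert np.allclose(td.differences_deg, 0.0)
        assert td.R == pytest.approx(1.0)
        assert td.axis_deg == pytest.approx(0.0, abs=1e-9)

    def test_independent_angles_rarely_significant(self):
        low = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = _fits_from_angles(rng.uniform(0, 360, 90))
            b = _fits_from_angles(rng.uniform(0, 360, 90))
            td = tuning_difference(a, b, n_boot=200, seed=seed)
            low += td.p <= 0.05
        assert n_seeds - low >= 44  # >= ~90% of seeds not significant

    def test_stable_tuning_across_epochs_on_synthetic_data(self, default_bundle):
        means = default_bundle["means"]
        pert = [f for f in fit_planes(means, "contra", "perturbation") if f.significant]
        ss = [f for f in fit_planes(means, "contra", "steady_state") if f.significant]
        td = tuning_difference(pert, ss, n_boot=500, seed=5)
        axis = (td.axis_deg + 180) % 360 - 180
        assert abs(axis) < 10.0
        assert td.p < 0.01

    def test_disjoint_neuron_sets_rejected(self):
        a = _fits_from_angles([0.0, 90.0])
        b = _fits_from_angles([0.0, 90.0])
        for f in b:
            f.neuron_id += 100
        with pytest.raises(ValueError, match="common"):
            tuning_difference(a, b)


class TestMagnitudeContrast:
    def test_identical_magnitudes_are_null(self):
        fits = _fits_from_angles(np.linspace(0, 300, 10), mags=np.full(10, 5.0))
        mc = magnitude_contrast(fits, fits)
        assert mc.wilcoxon_z == pytest.approx(0.0)
        assert mc.fraction_contra_larger == pytest.approx(0.5)

    def test_too_few_neurons_rejected(self):
        fits = _fits_from_angles([0.0, 45.0, 90.0])
        with pytest.raises(ValueError, match="5"):
            magnitude_contrast(fits, fits)

    def test_gain_ratio_recovery_at_study_scale(self, default_bundle):
        means = default_bundle["means"]
        fc = fit_planes(means, "contra")
        fi = fit_planes(means, "ipsi")
        sig = {f.neuron_id for f in fc if f.significant} | {
            f.neuron_id for f in fi if f.significant
        }
        mc = magnitude_contrast(
            [f for f in fc if f.neuron_id in sig],
            [f for f in fi if f.neuron_id in sig],
        )
        ratio = mc.median_contra / mc.median_ipsi
        assert 1.6 < ratio < 2.4
        assert mc.wilcoxon_p < 0.01
        assert mc.fraction_contra_larger > 0.7
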