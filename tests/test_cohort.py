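"""Synthetic ovine cohort: protocol arithmetic, noise model, mismatch."""

import numpy as np
import pytest

from bvkinetics import (
    CohortConfig,
    InputProtocol,
    generate_cohort,
    inject_model_mismatch,
    ovine_hemorrhage_protocol,
    sample_infusion_schedule,
    simulate,
)
from bvkinetics.cohort import HEMORRHAGE_ML_PER_KG, STUDY_DURATION_MIN


class TestHemorrhageProtocol:
    def test_weight_normalized_rates(self):
        segs = ovine_hemorrhage_protocol(30.0)
        assert segs == [(0.0, 15.0, 50.0), (50.0, 55.0, 30.0), (70.0, 75.0, 30.0)]
        total = sum(r * (b - a) for a, b, r in segs)
        assert total == pytest.approx(1050.0)

    @pytest.mark.parametrize("w", [20.0, 33.5, 45.0])
    def test_cumulative_is_35_ml_per_kg(self, w):
        proto = InputProtocol.from_schedules([], ovine_hemorrhage_protocol(w), 180.0)
        _, cv = proto.cumulative(np.array([180.0]))
        assert cv[0] == pytest.approx(HEMORRHAGE_ML_PER_KG * w)

    def test_rates_scale_linearly_with_weight(self):
        one = ovine_hemorrhage_protocol(25.0)
        two = ovine_hemorrhage_protocol(50.0)
        for (a1, b1, r1), (a2, b2, r2) in zip(one, two):
            assert (a1, b1) == (a2, b2)
            assert r2 == pytest.approx(2.0 * r1)

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            ovine_hemorrhage_protocol(0.0)


class TestInfusionSchedules:
    def test_constant_family_single_segment(self):
        cfg = CohortConfig(infusion_family="constant", infusion_total_ratio_range=(1.0, 1.0))
        segs = sample_infusion_schedule(cfg, 30.0, np.random.default_rng(0))
        assert len(segs) == 1
        (t0, t1, rate) = segs[0]
        assert (t0, t1) == (30.0, 180.0)
        assert rate == pytest.approx(35.0 * 30.0 / 150.0)

    def test_stepped_family_changes_on_sampling_grid(self):
        cfg = CohortConfig(infusion_family="stepped", sampling_interval_min=5.0)
        rng = np.random.default_rng(3)
        for _ in range(5):
            segs = sample_infusion_schedule(cfg, 32.0, rng)
            for t0, t1, _ in segs:
                assert (t0 - 30.0) % 5.0 == pytest.approx(0.0)
                assert (t1 - 30.0) % 5.0 == pytest.approx(0.0)

    def test_infusion_never_starts_before_30_min(self):
        rng = np.random.default_rng(11)
        for family in ("constant", "stepped", "proportional-to-deficit"):
            cfg = CohortConfig(infusion_family=family)
            segs = sample_infusion_schedule(cfg, 28.0, rng)
            assert all(t0 >= 30.0 for t0, _, _ in segs)

    def test_proportional_family_never_over_resuscitates(self):
        cfg = CohortConfig(infusion_family="proportional-to-deficit")
        rng = np.random.default_rng(5)
        for _ in range(5):
            w = float(rng.uniform(25, 45))
            segs = sample_infusion_schedule(cfg, w, rng)
            total = sum(r * (b - a) for a, b, r in segs)
            assert 0 < total <= HEMORRHAGE_ML_PER_KG * w + 1e-9


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_subjects=3, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.measured_delta_vb, rb.measured_delta_vb)
            assert ra.protocol.segments == rb.protocol.segments
            assert ra.true_params == rb.true_params

    def test_noise_free_measurements_equal_simulation(self, noise_free_cohort):
        for rec in noise_free_cohort:
            truth = simulate(rec.true_params, rec.protocol, rec.measurement_times)
            expected = truth.delta_vb.copy()
            expected[0] = 0.0
            assert np.allclose(rec.measured_delta_vb, expected)

    def test_baseline_measurement_is_zero(self, noisy_cohort):
        for rec in noisy_cohort:
            assert rec.measurement_times[0] == 0.0
            assert rec.measured_delta_vb[0] == 0.0

    def test_parameters_within_configured_ranges(self, noisy_cohort):
        for rec in noisy_cohort:
            tp = rec.true_params
            assert 0.35 <= tp.alpha_v <= 3.20
            assert 0.07 <= tp.k_p <= 0.27

    def test_proportional_noise_level_recovered(self):
        # pool >=1000 measurements; empirical sd of (measured-true)/true
        cfg = CohortConfig(n_subjects=40, noise_sd=0.10, seed=13)
        ratios = []
        for rec in generate_cohort(cfg):
            truth = simulate(rec.true_params, rec.protocol, rec.measurement_times).delta_vb
            sel = np.abs(truth) > 1e-9
            ratios.append((rec.measured_delta_vb[sel] - truth[sel]) / truth[sel])
        pooled = np.concatenate(ratios)
        assert pooled.size >= 1000
        assert 0.09 <= pooled.std() <= 0.11

    def test_sampling_jitter_respects_interval_bounds(self):
        cfg = CohortConfig(n_subjects=3, sampling_jitter=True, seed=2)
        for rec in generate_cohort(cfg):
            gaps = np.diff(rec.measurement_times)
            assert np.all(gaps[:-1] >= 5.0 - 1e-9)
            assert np.all(gaps[:-1] <= 10.0 + 1e-9)


class TestModelMismatch:
    def test_none_returns_record_unchanged(self, noisy_cohort):
        rec = noisy_cohort[0]
        assert inject_model_mismatch(rec, "none", np.random.default_rng(0)) is rec

    def test_unknown_kind_rejected(self, noisy_cohort):
        with pytest.raises(ValueError, match="unknown mismatch kind"):
            inject_model_mismatch(noisy_cohort[0], "lymphatic", np.random.default_rng(0))

    def test_asymmetric_with_equal_rates_matches_model(self, noise_free_cohort):
        # degenerate perturbation: refill rate factor 1 reproduces the model
        rec = noise_free_cohort[0]
        out = inject_model_mismatch(
            rec, "asymmetric-kp", np.random.default_rng(0), noise_sd=0.0, kp_refill_factor=1.0
        )
        assert np.allclose(out.measured_delta_vb, rec.measured_delta_vb, rtol=1e-5, atol=1e-3)
        assert out.mismatch_tag == "asymmetric-kp"

    def test_compensatory_gain_restores_baseline_despite_small_infusion(self):
        # the unmodelled recruitment refills most of the deficit by 50 min
        cfg = CohortConfig(
            n_subjects=1, noise_sd=0.0, seed=55, infusion_total_ratio_range=(0.3, 0.3)
        )
        rec = generate_cohort(cfg)[0]
        out = inject_model_mismatch(
            rec, "compensatory-gain", np.random.default_rng(1), noise_sd=0.0
        )
        i50 = int(np.argmin(np.abs(out.measurement_times - 50.0)))
        # restored to within 10% of the deficit the model alone would show
        peak_deficit = float(np.min(rec.measured_delta_vb))
        assert out.measured_delta_vb[i50] >= 0.10 * peak_deficit
        # while the well-specified subject is still far below baseline
        assert rec.measured_delta_vb[i50] < 0.5 * peak_deficit
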