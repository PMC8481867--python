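"""Regressor construction, SVD data-quality profiles, window selection."""

import numpy as np
import pytest

from bvkinetics import (
    CohortConfig,
    InputProtocol,
    SubjectRecord,
    build_regressor,
    estimate_derivatives,
    generate_cohort,
    select_window,
    simulate,
    svd_profile,
    to_transfer_coeffs,
)
from bvkinetics.precalibration import assign_axes


def make_record(times, values, protocol=None, weight=30.0):
    protocol = protocol or InputProtocol([(0.0, float(times[-1]), 0.0, 0.0)])
    return SubjectRecord(
        subject_id="T001",
        weight_kg=weight,
        protocol=protocol,
        measurement_times=np.asarray(times, float),
        measured_delta_vb=np.asarray(values, float),
    )


class TestEstimateDerivatives:
    def test_exact_for_linear_series(self):
        t = np.arange(0.0, 60.0, 5.0)
        rec = make_record(t, 3.0 * t)
        d1, d2 = estimate_derivatives(rec)
        assert np.allclose(d1, 3.0, atol=1e-9)
        assert np.allclose(d2, 0.0, atol=1e-9)

    def test_exact_for_quadratic_series(self):
        t = np.arange(0.0, 60.0, 5.0)
        rec = make_record(t, 0.5 * t**2)
        d1, d2 = estimate_derivatives(rec)
        assert np.allclose(d1, t, atol=1e-8)
        assert np.allclose(d2, 1.0, atol=1e-8)

    def test_accuracy_on_noise_free_subject(self, noise_free_cohort):
        # interior first-derivative error below 5% of the peak rate
        for rec in noise_free_cohort:
            d1, _ = estimate_derivatives(rec)
            truth = simulate(rec.true_params, rec.protocol, rec.measurement_times)
            bp = rec.protocol.breakpoints
            interior = np.min(np.abs(rec.measurement_times[:, None] - bp[None, :]), axis=1) > 1e-9
            err = np.max(np.abs(d1[interior] - truth.d_delta_vb[interior]))
            assert err < 0.05 * np.max(np.abs(truth.d_delta_vb))

    def test_requires_enough_samples(self):
        rec = make_record([0.0, 5.0, 10.0, 15.0], [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 5"):
            estimate_derivatives(rec)

    def test_finite_difference_alternative(self):
        t = np.arange(0.0, 60.0, 5.0)
        rec = make_record(t, 2.0 * t)
        d1, d2 = estimate_derivatives(rec, method="finite_difference")
        assert np.allclose(d1, 2.0)
        assert np.allclose(d2, 0.0, atol=1e-12)


class TestBuildRegressor:
    def test_no_infusion_zeroes_first_column(self, noise_free_cohort):
        rec = noise_free_cohort[0]
        sys = build_regressor(rec, 30.0)  # infusion starts at 30 min
        assert np.allclose(sys.design[:, 0], 0.0)
        assert np.linalg.matrix_rank(sys.design) <= 2

    def test_breakpoint_samples_excluded(self, noise_free_cohort):
        rec = noise_free_cohort[0]
        sys = build_regressor(rec, 180.0)
        bp = rec.protocol.breakpoints
        assert np.min(np.abs(sys.times[:, None] - bp[None, :])) > 1e-9

    def test_noise_free_solution_recovers_transfer_coefficients(self, noise_free_cohort):
        # the linear-regression form targets theta = (zero_u, zero_v, pole);
        # 5-min sampling bounds the derivative reconstruction at a few percent
        for rec in noise_free_cohort:
            theta = build_regressor(rec, 180.0).solve()
            c = to_transfer_coeffs(rec.true_params)
            true = np.array([c.zero_u, c.zero_v, c.pole])
            assert np.all(np.abs(theta - true) / true < 0.03)

    def test_empty_window_rejected(self, noise_free_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            build_regressor(noise_free_cohort[0], 500.0)


class TestSVDProfile:
    def test_axis_assignment_orthogonal_case(self):
        # right singular vectors exactly on the axes: perfect assignment
        vt = np.eye(3)[[1, 0, 2]]  # directions ordered zero_v, zero_u, pole
        axes, alignment, mixed = assign_axes(vt)
        assert list(axes) == ["zero_v", "zero_u", "pole"]
        assert np.allclose(alignment, 1.0)
        assert not mixed.any()

    def test_mixed_direction_flagged(self):
        vt = np.array([[0.72, 0.69, 0.08], [0.69, -0.72, 0.0], [0.0, 0.08, 0.99]])
        axes, alignment, mixed = assign_axes(vt, alignment_threshold=0.8)
        assert mixed[0] and mixed[1]
        assert sorted(axes) == ["pole", "zero_u", "zero_v"]  # all axes still covered

    def test_singular_values_monotone_in_window(self, noisy_cohort):
        grid = np.arange(20.0, 181.0, 20.0)
        for rec in noisy_cohort:
            prof = svd_profile(rec, grid)
            assert np.all(np.diff(prof.sigmas, axis=0) >= -1e-9)

    def test_loss_axis_better_identified_than_gain_axis(self, noise_free_cohort):
        # hemorrhage-first protocol: the loss channel dominates early data
        for rec in noise_free_cohort:
            prof = svd_profile(rec, np.array([180.0]))
            sv = prof.sigma_for_axis("zero_v")[-1]
            su = prof.sigma_for_axis("zero_u")[-1]
            assert sv >= su


class TestSelectWindow:
    @staticmethod
    def profiles_for(n, noise, seed, grid):
        recs = generate_cohort(CohortConfig(n_subjects=n, noise_sd=noise, seed=seed))
        return [svd_profile(r, grid) for r in recs], recs[0].protocol

    def test_threshold_disabled_gives_smallest_event_window(self):
        grid = np.arange(10.0, 181.0, 10.0)
        profiles, protocol = self.profiles_for(4, 0.0, 1, grid)
        sel = select_window(profiles, protocol, threshold_fraction=0.0)
        # smallest grid window overlapping both the initial bleed and the
        # infusion (starting at 30 min) while leaving a bleed for validation
        assert sel.t_c == 40.0
        assert sel.contains_hemorrhage and sel.contains_infusion
        assert sel.validation_contains_hemorrhage

    def test_no_infusion_is_an_error(self):
        grid = np.arange(10.0, 181.0, 10.0)
        cfg = CohortConfig(n_subjects=2, noise_sd=0.0, seed=1,
                           infusion_total_ratio_range=(1.0, 1.0))
        recs = generate_cohort(cfg)
        # rebuild subjects with hemorrhage only
        from bvkinetics.cohort import ovine_hemorrhage_protocol
        from bvkinetics import InputProtocol, simulate as sim
        from dataclasses import replace

        bare = []
        for r in recs:
            proto = InputProtocol.from_schedules([], ovine_hemorrhage_protocol(r.weight_kg), 180.0)
            vals = sim(r.true_params, proto, r.measurement_times).delta_vb
            vals[0] = 0.0
            bare.append(replace(r, protocol=proto, measured_delta_vb=vals))
        profiles = [svd_profile(r, grid) for r in bare]
        with pytest.raises(ValueError, match="hemorrhage and an infusion"):
            select_window(profiles, bare[0].protocol)

    def test_strict_threshold_falls_back_with_warning(self):
        grid = np.arange(10.0, 181.0, 10.0)
        profiles, protocol = self.profiles_for(4, 0.0, 1, grid)
        with pytest.warns(UserWarning, match="singular-value threshold"):
            sel = select_window(profiles, protocol, threshold_fraction=0.5)
        assert sel.warnings

    def test_mismatched_grids_rejected(self):
        grid_a = np.arange(10.0, 181.0, 10.0)
        grid_b = np.arange(20.0, 181.0, 20.0)
        pa, protocol = self.profiles_for(1, 0.0, 1, grid_a)
        pb, _ = self.profiles_for(1, 0.0, 2, grid_b)
        with pytest.raises(ValueError, match="common T_c grid"):
            select_window(pa + pb, protocol)
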