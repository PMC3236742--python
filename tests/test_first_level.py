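"""HRF, design construction, smoothing, GLM fitting, contrasts, fixed effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropcr import (
    CohortSpec,
    build_design,
    canonical_hrf,
    contrast_map,
    fit_glm,
    fixed_effects_combine,
    gaussian_smooth,
    make_ground_truth,
    render_bold_run,
    run_first_level,
    sample_cohort_traits,
)
from neuropcr.first_level import fwhm_to_sigma
from neuropcr.synthetic_cohort import Event, EventSchedule
from neuropcr.volumes_io import Volume, ravel3


class TestCanonicalHrf:
    def test_peak_normalized_to_one(self):
        assert canonical_hrf(2.0).max() == 1.0

    def test_argmax_near_five_seconds(self):
        h = canonical_hrf(0.1)
        assert 4.5 <= np.argmax(h) * 0.1 <= 5.5

    def test_tail_is_negligible_at_support_end(self):
        h = canonical_hrf(0.1, duration=32.0)
        assert abs(h[-1]) < 0.01

    def test_length_is_ceil_duration_over_dt(self):
        assert canonical_hrf(2.0, 32.0).size == 16
        assert canonical_hrf(3.0, 32.0).size == 11

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestBuildDesign:
    def test_empty_schedule_gives_single_intercept(self):
        d = build_design([], n_frames=20, tr=2.0)
        assert d.names == ["M", "F", "S", "intercept"]
        assert not d.columns[:, :3].any()
        np.testing.assert_array_equal(d.columns[:, 3], 1.0)

    def test_confound_columns_appended_unchanged(self, rng):
        conf = rng.normal(size=(30, 6))
        d = build_design([("M", 0.0, 2.0)], n_frames=30, tr=2.0, confounds=conf)
        assert d.columns.shape[1] == 3 + 6 + 1  # task + confounds + intercept
        np.testing.assert_array_equal(d.columns[:, 3:9], conf)

    def test_confound_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="frames"):
            build_design([], n_frames=30, tr=2.0, confounds=rng.normal(size=(29, 2)))

    def test_convolution_matches_direct_sum_oracle(self, rng):
        # column value at frame t must equal sum_k indicator[k] * hrf[t-k]
        tr, n = 2.0, 60
        events = [("M", float(4 * k), tr) for k in range(10)]
        d = build_design(events, n_frames=n, tr=tr)
        hrf = canonical_hrf(tr)
        ind = np.zeros(n)
        for _, onset, _ in events:
            ind[int(round(onset / tr))] += 1
        oracle = np.array([sum(ind[k] * (hrf[t - k] if 0 <= t - k < hrf.size else 0.0) for k in range(n)) for t in range(n)])
        np.testing.assert_allclose(d.columns[:, 0], oracle, atol=1e-10)


class TestGaussianSmooth:
    def test_sigma_from_fwhm(self):
        assert fwhm_to_sigma(9.0, 2.0) == pytest.approx(1.9110, abs=1e-3)

    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((8, 8, 6), 3.25), voxel_dims=(2, 2, 3))
        out = gaussian_smooth(vol, 9.0)
        np.testing.assert_allclose(out.data, 3.25, atol=1e-10)

    def test_fwhm_zero_is_identity(self, rng):
        vol = Volume(rng.normal(size=(6, 6, 4)))
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0).data, vol.data)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(offset=st.floats(-50, 50), fwhm=st.floats(0.1, 12.0))
    def test_commutes_with_adding_a_constant(self, offset, fwhm):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(6, 6, 4))
        a = gaussian_smooth(Volume(data + offset), fwhm).data
        b = gaussian_smooth(Volume(data), fwhm).data + offset
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(Volume(np.zeros((3, 3, 3))), -1.0)

    def test_4d_smoothing_never_mixes_frames(self, rng):
        data = np.zeros((6, 6, 4, 3))
        data[..., 1] = rng.normal(size=(6, 6, 4))
        out = gaussian_smooth(Volume(data), 6.0)
        assert not out.data[..., 0].any() and not out.data[..., 2].any()


def _random_run(rng, n_frames=40, dims=(4, 4, 2)):
    events = [("M", 4.0, 2.0), ("F", 20.0, 2.0), ("S", 40.0, 2.0), ("M", 56.0, 2.0)]
    design = build_design(events, n_frames, tr=2.0)
    data = rng.normal(size=dims + (n_frames,))
    return Volume(data), design


class TestFitGlm:
    def test_betas_match_normal_equations_oracle(self, rng):
        run, design = _random_run(rng)
        fit = fit_glm(run, design)
        X = design.columns
        Y = run.data.reshape((-1, X.shape[0]), order="F").T
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y
        np.testing.assert_allclose(fit.betas, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        run, design = _random_run(rng)
        fit = fit_glm(run, design)
        X = design.columns
        Y = run.data.reshape((-1, X.shape[0]), order="F").T
        resid = Y - X @ fit.betas
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_dof_is_frames_minus_rank(self, rng):
        run, design = _random_run(rng)
        assert fit_glm(run, design).dof == 40 - 4

    def test_rank_deficient_design_names_columns(self, rng):
        run, _ = _random_run(rng)
        events = [("M", 4.0, 2.0)]
        design = build_design(events, 40, tr=2.0, confounds=np.ones((40, 1)))
        # confound0 duplicates the intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(run, design)

    def test_noiseless_run_recovers_planted_amplitudes(self):
        spec = CohortSpec(
            grid_dims=(5, 5, 3), cluster_voxels=6, run_minutes=2.0, n_runs=1,
            events_per_condition=6, noise_sd=0.0, seed=17,
        )
        truth = make_ground_truth(spec)
        subject = sample_cohort_traits(spec)[20]
        events = [
            Event("M", 10.0, 2.0), Event("F", 30.0, 2.0), Event("S", 50.0, 2.0),
            Event("M", 70.0, 2.0), Event("F", 90.0, 2.0), Event("S", 110.0, 2.0),
        ]
        run = render_bold_run(subject, EventSchedule(runs=[list(events)]), truth, spec)
        fit = fit_glm(run, build_design(events, spec.n_frames, spec.tr))
        for ci, cond in enumerate(("M", "F", "S")):
            planted = truth.amplitude(cond, subject.bdi, subject.aai)
            got = fit.betas[ci, truth.cluster_indices]
            np.testing.assert_allclose(got, planted, atol=1e-8)


class TestContrastMap:
    def test_identity_and_symmetry_contrasts(self, rng):
        run, design = _random_run(rng)
        fit = fit_glm(run, design)
        eff_m, _ = contrast_map(fit, [1, 0, 0])
        np.testing.assert_allclose(ravel3(eff_m.data), fit.betas[0], atol=1e-12)
        # equal M and F betas -> M-F contrast identically zero
        fit2 = fit_glm(run, design)
        fit2.betas[1] = fit2.betas[0]
        eff, _ = contrast_map(fit2, [1, -1, 0])
        np.testing.assert_allclose(eff.data, 0.0, atol=1e-12)

    def test_variance_matches_monte_carlo(self, rng):
        # one voxel, 10^4 simulated noise realizations: the sampling variance
        # of c'beta must match the analytic sigma2 * c'(X'X)^-1 c within 10%
        n, tr = 40, 2.0
        events = [("M", 8.0, tr), ("F", 24.0, tr), ("S", 48.0, tr)]
        design = build_design(events, n, tr)
        X = design.columns
        c = np.array([1.0, -1.0, 0.0, 0.0])
        pinv = np.linalg.pinv(X)
        draws = c @ pinv @ rng.normal(size=(n, 10_000))
        analytic = float(c @ np.linalg.inv(X.T @ X) @ c)  # sigma2 = 1
        assert abs(draws.var(ddof=1) / analytic - 1.0) < 0.10
        # and the per-voxel variance the package reports uses that same form
        run = Volume(rng.normal(size=(2, 2, 1, n)))
        fit = fit_glm(run, design)
        _, var = contrast_map(fit, [1, -1, 0])
        np.testing.assert_allclose(ravel3(var.data), fit.sigma2 * analytic, rtol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        run, design = _random_run(rng)
        with pytest.raises(ValueError, match="length"):
            contrast_map(fit_glm(run, design), [1, -1, 0, 0, 0, 0])


class TestFixedEffects:
    def _vols(self, arrays):
        return [Volume(np.asarray(a, dtype=float)) for a in arrays]

    def test_single_run_is_identity(self, rng):
        e = Volume(rng.normal(size=(3, 3, 2)))
        v = Volume(rng.uniform(0.5, 2.0, size=(3, 3, 2)))
        eff, var = fixed_effects_combine([e], [v])
        np.testing.assert_allclose(eff.data, e.data)
        np.testing.assert_allclose(var.data, v.data)

    def test_equal_variances_give_arithmetic_mean(self, rng):
        es = [Volume(rng.normal(size=(3, 3, 2))) for _ in range(3)]
        vs = [Volume(np.full((3, 3, 2), 2.0)) for _ in range(3)]
        eff, var = fixed_effects_combine(es, vs)
        np.testing.assert_allclose(eff.data, np.mean([e.data for e in es], axis=0))
        np.testing.assert_allclose(var.data, 2.0 / 3.0)

    def test_hand_computed_weighted_mean(self):
        eff, var = fixed_effects_combine(
            self._vols([np.full((2, 2, 1), 1.0), np.full((2, 2, 1), 5.0)]),
            self._vols([np.full((2, 2, 1), 1.0), np.full((2, 2, 1), 3.0)]),
        )
        # weights 0.75 / 0.25 -> effect 2.0, variance 1/(1 + 1/3) = 0.75
        np.testing.assert_allclose(eff.data, 0.75 * 1.0 + 0.25 * 5.0)
        np.testing.assert_allclose(var.data, 0.75)

    def test_combined_variance_never_exceeds_min_input(self, rng):
        vs = [Volume(rng.uniform(0.2, 4.0, size=(4, 4, 2))) for _ in range(3)]
        es = [Volume(rng.normal(size=(4, 4, 2))) for _ in range(3)]
        _, var = fixed_effects_combine(es, vs)
        assert np.all(var.data <= np.min([v.data for v in vs], axis=0) + 1e-12)

    def test_zero_variance_falls_back_to_unweighted_mean(self, caplog):
        import logging

        es = self._vols([np.full((2, 2, 1), 2.0), np.full((2, 2, 1), 4.0)])
        vs = self._vols([np.zeros((2, 2, 1)), np.ones((2, 2, 1))])
        with caplog.at_level(logging.WARNING):
            eff, _ = fixed_effects_combine(es, vs)
        np.testing.assert_allclose(eff.data, 3.0)
        assert any("zero variance" in r.message for r in caplog.records)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_combine([], [])


class TestEndToEnd:
    def test_noiseless_pipeline_recovers_planted_contrasts_within_1pct(self):
        spec = CohortSpec(
            grid_dims=(6, 6, 4), cluster_voxels=10, run_minutes=2.0, n_runs=2,
            events_per_condition=6, noise_sd=0.0, seed=23,
        )
        truth = make_ground_truth(spec)
        subject = sample_cohort_traits(spec)[22]
        from neuropcr import make_event_schedule

        sched = make_event_schedule(spec)
        runs = [render_bold_run(subject, sched, truth, spec, k) for k in range(2)]
        cset = run_first_level(runs, sched.runs, tr=spec.tr, fwhm_mm=0.0)
        for contrast in ("M-F", "M-S", "F-S"):
            planted = truth.contrast_amplitude(contrast, subject.bdi, subject.aai)
            got = ravel3(cset.maps[contrast].data)[truth.cluster_indices]
            if abs(planted) > 1e-12:
                assert np.abs(got / planted - 1.0).max() < 0.01
            else:
                np.testing.assert_allclose(got, 0.0, atol=1e-8)
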