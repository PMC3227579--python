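"""Per-run preprocessing stages: QC, despiking, detrending, band-pass,
smoothing, intensity normalization and nuisance regression."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import make_run
from traitconn.datatypes import NuisanceSet
from traitconn.preprocess import (RunPreprocessor, bandpass, despike, detrend,
                                  extract_nuisance, normalize_intensity,
                                  nuisance_regress, qc_motion, smooth_spatial)


class TestMotionQC:
    def test_zero_motion_retained(self):
        run = make_run(np.random.default_rng(0).random((4, 4, 4, 10)) + 1)
        dec = qc_motion(run)
        assert dec.retained and dec.max_displacement_mm == 0.0

    def test_translation_beyond_threshold_excluded(self):
        motion = np.zeros((10, 6))
        motion[5, 0] = 3.5
        run = make_run(np.ones((4, 4, 4, 10)), motion=motion)
        assert not qc_motion(run, threshold_mm=3.0).retained

    def test_boundary_displacement_is_excluded_strictly(self):
        motion = np.zeros((10, 6))
        motion[3, :3] = [3.0, 0.0, 0.0]
        run = make_run(np.ones((4, 4, 4, 10)), motion=motion)
        dec = qc_motion(run, threshold_mm=3.0)
        assert dec.max_displacement_mm == 3.0 and not dec.retained

    def test_displacement_relative_to_first_volume(self):
        motion = np.full((10, 6), 2.0)  # constant offset: no displacement
        run = make_run(np.ones((4, 4, 4, 10)), motion=motion)
        assert qc_motion(run).max_displacement_mm == 0.0


class TestDespike:
    def test_spike_free_series_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 100)  # bounded: no sample beyond the knee
        assert np.allclose(despike(x), x, atol=1e-10)

    def test_large_spike_bounded_by_c2(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, 100)
        resid_sd = 1.4826 * np.median(np.abs(x - np.median(x)))
        x2 = x.copy()
        x2[50] += 20 * resid_sd
        out = despike(x2, clip_c1=2.5, clip_c2=4.0)
        # the spike is compressed below c2 robust-SDs above the running fit
        assert out[50] < x2[50]
        assert out[50] - x[50] <= 4.0 * 2 * resid_sd  # generous robust-SD bound

    def test_monotone_map_preserves_order(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.normal(0, 1, 50))
        out = despike(x)
        # despiking is applied through a monotone residual map around one fit
        basis_resid_order = np.argsort(x - np.polyval(np.polyfit(np.arange(50), x, 2),
                                                      np.arange(50)))
        out_resid_order = np.argsort(out - np.polyval(np.polyfit(np.arange(50), x, 2),
                                                      np.arange(50)))
        assert np.array_equal(basis_resid_order, out_resid_order)

    def test_invalid_knees_rejected(self):
        with pytest.raises(ValueError, match="clip_c2"):
            despike(np.zeros(10), clip_c1=4.0, clip_c2=2.0)


class TestDetrend:
    def test_pure_quadratic_trend_removed(self):
        t = np.arange(100, dtype=float)
        x = 3 + 0.1 * t + 0.01 * t ** 2
        assert np.max(np.abs(detrend(x, order=2))) < 1e-8

    def test_sinusoid_nearly_preserved(self):
        n = 800
        t = np.arange(n, dtype=float)
        x = np.sin(2 * np.pi * 100 * t / n)  # many full cycles
        out = detrend(x, order=2)
        # oracle: explicit projection onto the polynomial basis
        basis = np.column_stack([np.ones(n), t, t ** 2])
        proj = basis @ np.linalg.lstsq(basis, x, rcond=None)[0]
        assert np.allclose(out, x - proj, atol=1e-9)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 0.01

    def test_output_orthogonal_to_polynomial_basis(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=150)
        out = detrend(x, order=2)
        t = np.arange(150, dtype=float)
        basis = np.column_stack([np.ones_like(t), t, t ** 2])
        coef, *_ = np.linalg.lstsq(basis, out, rcond=None)
        assert np.all(np.abs(coef) < 1e-10)
        assert abs(out.mean()) < 1e-10


class TestBandpass:
    def test_constant_series_zeroed(self):
        assert np.allclose(bandpass(np.full(197, 5.0), 2.0), 0.0, atol=1e-10)

    def test_inband_tone_preserved(self):
        t = np.arange(197) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(x, 2.0)
        assert abs(out.std() - x.std()) / x.std() < 0.05

    def test_stopband_tone_attenuated(self):
        t = np.arange(197) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(x, 2.0)
        assert np.sqrt((out ** 2).mean()) < 0.05 * np.sqrt((x ** 2).mean())

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=197)
        once = bandpass(x, 2.0)
        assert np.allclose(bandpass(once, 2.0), once, atol=1e-10)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(100), tr_seconds=2.0, f_hi=0.3)


class TestSmoothing:
    def test_constant_volume_unchanged(self):
        vol = np.full((10, 10, 10), 7.0)
        assert np.allclose(smooth_spatial(vol, 6.0, (4.0,) * 3), 7.0, atol=1e-10)

    def test_impulse_response_matches_gaussian_ratio(self):
        vol = np.zeros((11, 11, 11))
        vol[5, 5, 5] = 1.0
        out = smooth_spatial(vol, 6.0, (4.0,) * 3)
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2)))
        expected = np.exp(-(4.0 ** 2) / (2 * sigma ** 2))
        assert np.isclose(out[6, 5, 5] / out[5, 5, 5], expected, rtol=1e-6)

    def test_mass_preserved_for_interior_impulse(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = smooth_spatial(vol, 6.0, (4.0,) * 3)
        assert abs(out.sum() - 1.0) < 1e-3


class TestNormalize:
    def test_grand_mean_hits_target(self):
        rng = np.random.default_rng(6)
        run = make_run(rng.uniform(500, 1500, size=(6, 6, 6, 20)))
        out = normalize_intensity(run, target=10000.0)
        assert np.isclose(out.data[out.brain_mask].mean(), 10000.0, atol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(500, 1500, size=(6, 6, 6, 20))
        a = normalize_intensity(make_run(data)).data
        b = normalize_intensity(make_run(2 * data)).data
        assert np.allclose(a, b, rtol=1e-12)


class TestNuisance:
    def test_global_series_of_constant_volumes(self):
        data = np.ones((6, 6, 6, 10)) * np.arange(1, 11)
        run = make_run(data)
        ns = extract_nuisance(run)
        assert np.allclose(ns.global_signal, np.arange(1, 11))

    def test_empty_tissue_mask_rejected(self):
        run = make_run(np.ones((6, 6, 6, 10)))
        run.wm_prob[:] = 0.5
        with pytest.raises(ValueError, match="wm"):
            extract_nuisance(run, wm_prob_threshold=0.8)

    def test_wm_series_is_mean_over_thresholded_voxels(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(6, 6, 6, 10))
        run = make_run(data)
        run.wm_prob[:] = 0.0
        run.wm_prob[:3] = 0.9
        ns = extract_nuisance(run, wm_prob_threshold=0.8)
        brute = data[:3].reshape(-1, 10).mean(axis=0)
        assert np.allclose(ns.wm, brute)

    def test_regress_removes_series_in_design_span(self):
        rng = np.random.default_rng(9)
        t = 60
        g = rng.normal(size=t)
        data = np.broadcast_to(g, (4, 4, 4, t)).copy()
        run = make_run(data, motion=rng.normal(0, 0.1, (t, 6)))
        ns = NuisanceSet(global_signal=g, wm=rng.normal(size=t),
                         csf=rng.normal(size=t), motion=run.motion)
        out = nuisance_regress(run, ns)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_orthogonal_series_only_demeaned(self):
        rng = np.random.default_rng(10)
        t = 400
        X = rng.normal(size=(t, 9))
        y = rng.normal(size=t)
        # project y off the design to construct exact orthogonality
        full = np.column_stack([np.ones(t), X])
        y_orth = y - full @ np.linalg.lstsq(full, y, rcond=None)[0]
        data = np.zeros((2, 2, 2, t))
        data[0, 0, 0] = y_orth + 5.0
        run = make_run(data, motion=X[:, 3:])
        ns = NuisanceSet(global_signal=X[:, 0], wm=X[:, 1], csf=X[:, 2],
                         motion=X[:, 3:])
        out = nuisance_regress(run, ns)
        assert np.allclose(out.data[0, 0, 0], y_orth, atol=1e-8)

    def test_residuals_orthogonal_to_regressors_and_variance_contracts(self):
        rng = np.random.default_rng(11)
        t = 80
        data = rng.normal(size=(4, 4, 4, t))
        run = make_run(data, motion=rng.normal(0, 0.2, (t, 6)))
        ns = extract_nuisance(run)
        out = nuisance_regress(run, ns)
        resid = out.data.reshape(-1, t)
        X = ns.design()
        for j in range(9):
            corrs = resid @ (X[:, j] - X[:, j].mean())
            assert np.max(np.abs(corrs)) < 1e-8
        var_in = data.reshape(-1, t).var(axis=1)
        var_out = resid.var(axis=1)
        assert np.all(var_out <= var_in + 1e-12)

    def test_collinear_design_rejected(self):
        t = 50
        run = make_run(np.ones((4, 4, 4, t)))
        g = np.arange(t, dtype=float)
        ns = NuisanceSet(global_signal=g, wm=g, csf=np.ones(t),
                         motion=np.zeros((t, 6)))
        with pytest.raises(ValueError, match="rank deficient"):
            nuisance_regress(run, ns)


class TestChain:
    def test_preprocessing_recovers_planted_coupling_under_artifacts(self):
        """A planted in-band coupling plus large motion-locked artifact: the
        seed-target correlation after preprocessing must be closer to the
        noiseless coupling correlation than before."""
        from tests.test_synth import _mini_config, _seed_target_corr, MEANS, SDS, EYE
        from traitconn.synth import generate_bold_run, generate_trait_scores

        cfg = _mini_config()
        cfg.noise.motion_artifact_amplitude = 3.0
        cfg.noise.drift_amplitude = 3.0
        cfg.effects[0].trait_slope = {}
        cfg.effects[0].baseline_coupling = 0.0  # true coupling: r = 0
        p = generate_trait_scores(1, MEANS, SDS, EYE, rng_seed=12)[0]
        run = generate_bold_run(p, cfg.seeds, cfg.effects, cfg, 0)
        pre = RunPreprocessor.from_params(cfg.preproc)
        pre.set_params(smooth_fwhm_mm=0.0)
        clean = pre.transform(run)
        r_before = abs(_seed_target_corr(cfg, run))
        r_after = abs(_seed_target_corr(cfg, clean))
        assert r_after < r_before
        assert r_after < 0.25

    def test_chain_is_deterministic(self):
        from tests.test_synth import _mini_config, MEANS, SDS, EYE
        from traitconn.synth import generate_bold_run, generate_trait_scores

        cfg = _mini_config()
        p = generate_trait_scores(1, MEANS, SDS, EYE, rng_seed=13)[0]
        run = generate_bold_run(p, cfg.seeds, cfg.effects, cfg, 0)
        pre = RunPreprocessor.from_params(cfg.preproc)
        a = pre.transform(run).data
        b = pre.transform(run).data
        assert np.array_equal(a, b)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_bandpass_output_is_real_and_inband(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=120)
    out = bandpass(x, 2.0)
    spec = np.abs(np.fft.rfft(out))
    freqs = np.fft.rfftfreq(120, 2.0)
    outband = (freqs < 0.009) | (freqs > 0.1)
    assert np.all(spec[outband] < 1e-8 * max(1.0, spec.max()))
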