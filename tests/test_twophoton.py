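import math

import numpy as np
import pytest
from scipy import ndimage

from cohmap.io import FrameStack
from cohmap.synthetic import _von_mises_tuning
from cohmap.twophoton import (activity_map, dff_cell,
                              direction_coherence_tuning,
                              elevation_binned_tuning, hodges_ajne,
                              hodges_ajne_m, hodges_ajne_pvalue,
                              map_receptive_field, neuropil_alpha_grid,
                              neuropil_correct, register_frames,
                              run_cell_pipeline, segment_rois, session_qc)


def _match_rois(true_masks, found, min_iou=0.5):
    tp, used = 0, set()
    for i in range(true_masks.max()):
        tm = true_masks == i + 1
        best_iou, best_j = 0.0, None
        for j in range(1, found.max() + 1):
            if j in used:
                continue
            inter = (tm & (found == j)).sum()
            if inter == 0:
                continue
            iou = inter / (tm | (found == j)).sum()
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_iou >= min_iou:
            tp += 1
            used.add(best_j)
    return tp


class TestRegistration:
    def test_planted_shifts_recovered(self, rng):
        base = ndimage.gaussian_filter(
            np.abs(rng.standard_normal((64, 64))) * 10, 2)
        shifts = rng.integers(-3, 4, (30, 2))
        shifts[0] = 0
        frames = np.stack([np.roll(base, tuple(s), axis=(0, 1)) for s in shifts])
        reg, rec, flagged = register_frames(FrameStack(frames, 10.0))
        assert not flagged.any()
        np.testing.assert_array_equal(rec, -shifts)
        expected = np.broadcast_to(base.astype(np.float32), reg.data.shape)
        np.testing.assert_array_equal(reg.data, expected)

    def test_aligned_stack_untouched(self, rng):
        base = ndimage.gaussian_filter(rng.standard_normal((32, 32)), 2)
        frames = np.repeat(base[None], 5, axis=0)
        _, rec, flagged = register_frames(FrameStack(frames, 10.0))
        assert np.all(rec == 0) and not flagged.any()

    def test_excessive_shift_flagged_and_clamped(self, rng):
        base = ndimage.gaussian_filter(
            np.abs(rng.standard_normal((64, 64))) * 10, 2)
        frames = np.stack([base] * 4 + [np.roll(base, (20, 0), axis=(0, 1))])
        _, rec, flagged = register_frames(FrameStack(frames, 10.0),
                                          max_shift_frac=0.1)
        assert flagged[4]
        assert np.all(rec[4] == 0)


class TestActivityAndSegmentation:
    def test_gaussian_noise_scores_near_zero(self, rng):
        score = activity_map(rng.standard_normal((2000, 4, 4)))
        assert np.abs(score).max() < 0.5

    def test_sparse_transients_score_high(self, rng):
        trace = rng.normal(0, 0.1, (1000, 1, 1))
        trace[rng.integers(0, 1000, 30)] += 3.0
        moments_about_median = trace - np.median(trace)
        oracle = (moments_about_median ** 4).mean() / \
            (moments_about_median ** 2).mean() ** 2 - 3
        score = activity_map(trace)
        assert score[0, 0] == pytest.approx(oracle, rel=1e-9)
        assert score[0, 0] > 5.0

    def test_constant_pixel_scores_zero(self):
        assert activity_map(np.ones((200, 1, 1)))[0, 0] == 0.0

    def test_synthetic_field_recall_and_precision(self, twophoton_session_still):
        truth, sess = twophoton_session_still
        rois = segment_rois(activity_map(sess.stack))
        tp = _match_rois(truth.masks, rois)
        assert tp / truth.n_cells >= 0.9
        assert tp / max(rois.max(), 1) >= 0.9

    def test_blank_map_yields_no_rois(self):
        with pytest.warns(UserWarning):
            rois = segment_rois(np.zeros((50, 50)))
        assert rois.max() == 0

    def test_touching_disks_split_in_two(self):
        rr, cc = np.mgrid[0:40, 0:40]
        act = np.exp(-((rr - 20) ** 2 + (cc - 16) ** 2) / 8.0) \
            + np.exp(-((rr - 20) ** 2 + (cc - 24) ** 2) / 8.0)
        rois = segment_rois(act, cell_diameter_px=6)
        assert rois.max() == 2


class TestNeuropilCorrection:
    def test_identical_traces_fully_subtracted(self, rng):
        t = rng.standard_normal(500) + 10
        corrected, alpha = neuropil_correct(t, t)
        assert alpha == 1.0
        assert np.ptp(corrected) < 1e-9

    def test_independent_traces_need_no_correction(self, rng):
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000)
        _, alpha = neuropil_correct(a, b)
        assert alpha < 0.05

    @pytest.mark.parametrize("alpha_true", [0.0, 0.3, 0.7, 1.0])
    def test_planted_mixing_recovered(self, alpha_true, rng):
        npil = rng.standard_normal(3000)
        signal = np.zeros(3000)
        signal[rng.integers(0, 3000, 60)] = 3.0
        signal = ndimage.gaussian_filter1d(signal, 5) * 5
        soma = 100 + signal + alpha_true * npil
        corrected, alpha = neuropil_correct(soma, npil)
        assert alpha == pytest.approx(alpha_true, abs=0.02)
        if 0 < alpha_true < 1:
            r = np.corrcoef(corrected, npil)[0, 1]
            assert abs(r) < 0.05

    def test_grid_search_agrees_with_closed_form(self, rng):
        for _ in range(5):
            soma = rng.standard_normal(400) + 0.5 * rng.standard_normal(400)
            npil = rng.standard_normal(400)
            soma = soma + 0.4 * npil
            _, a_closed = neuropil_correct(soma, npil)
            a_grid = neuropil_alpha_grid(soma, npil)
            assert abs(a_closed - a_grid) <= 1e-3

    def test_constant_neuropil_leaves_soma_unchanged(self, rng):
        soma = rng.standard_normal(100)
        corrected, alpha = neuropil_correct(soma, np.full(100, 3.0))
        assert alpha == 0.0
        np.testing.assert_array_equal(corrected, soma)


class TestDffCell:
    def test_baseline_is_dominant_mode(self, rng):
        trace = np.concatenate([rng.normal(100, 2, 900), rng.normal(300, 5, 100)])
        _, f0 = dff_cell(trace)
        assert f0 == pytest.approx(100, abs=3)

    def test_constant_trace_gives_zero_dff(self):
        dff, f0 = dff_cell(np.full(200, 50.0))
        assert f0 == 50.0
        assert np.all(dff == 0)

    def test_planted_bimodal_mode_recovered(self, rng):
        trace = np.concatenate([rng.normal(80, 3, 700), rng.normal(120, 3, 300)])
        _, f0 = dff_cell(trace)
        assert f0 == pytest.approx(80, abs=5)

    def test_nonpositive_baseline_flagged(self, rng):
        with pytest.raises(ValueError):
            dff_cell(rng.normal(-10, 0.5, 200))


class TestReceptiveField:
    def test_single_location_response_centres_there(self):
        centers = np.linspace(-50, 50, 30)
        resp = np.zeros((30, 4))
        resp[12] = 1.0
        fit = map_receptive_field(resp, centers)
        assert fit.responsive
        assert fit.center_deg == pytest.approx(centers[12], abs=1.0)

    def test_planted_gaussian_recovered_within_two_degrees(self, rng):
        centers = np.linspace(-50, 50, 30)
        profile = 1.0 * np.exp(-(centers + 20) ** 2 / (2 * 10 ** 2))
        resp = profile[:, None] + rng.normal(0, profile.max() / 5, (30, 6))
        fit = map_receptive_field(resp, centers)
        assert fit.responsive
        assert fit.center_deg == pytest.approx(-20, abs=2)

    def test_flat_responses_not_responsive(self, rng):
        resp = rng.normal(0, 1, (30, 4))
        fit = map_receptive_field(resp, np.linspace(-50, 50, 30))
        assert fit.anova_p >= 0.0  # screened, typically not significant
        if fit.anova_p >= 0.05:
            assert not fit.responsive

    def test_minimum_design_enforced(self):
        with pytest.raises(ValueError):
            map_receptive_field(np.ones((3, 4)), np.arange(3))


class TestSessionQC:
    def test_perfect_gradient_always_passes(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            pos = r.uniform(0, 100, 30)
            prefs = -25 + 0.5 * pos + r.normal(0, 1, 30)
            qc = session_qc(pos, prefs, n_shuffle=2000, seed=seed)
            assert qc.passed

    def test_threshold_is_shuffle_percentile_by_construction(self, rng):
        pos = rng.uniform(0, 100, 20)
        prefs = rng.uniform(-25, 25, 20)
        qc = session_qc(pos, prefs, n_shuffle=1000, pct=99, seed=0)
        assert qc.threshold == pytest.approx(np.percentile(qc.shuffled, 99))

    def test_shuffled_preferences_rarely_pass(self):
        passes = sum(
            session_qc(np.random.default_rng(100 + s).uniform(0, 96, 30),
                       np.random.default_rng(200 + s).uniform(-25, 25, 30),
                       n_shuffle=2000, seed=s).passed
            for s in range(100))
        assert passes / 100 <= 0.04  # nominal 1% plus Monte-Carlo slack

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            session_qc(rng.uniform(0, 1, 5), rng.uniform(0, 1, 5))


class TestDirectionTuning:
    def _harness(self, mu, kappa, snr, rng, gain=1.0):
        dirs = list(range(0, 360, 45))
        m = np.interp(np.arange(200), np.arange(0, 200, 25),
                      rng.choice([0, .03, .06, .12, .24, .48, .96], 8))
        segments = {d: (k * 200, (k + 1) * 200) for k, d in enumerate(dirs)}
        traces = {d: m for d in dirs}
        resp = np.concatenate([gain * m * _von_mises_tuning(d, mu, kappa)
                               for d in dirs])
        resp = resp + rng.normal(0, resp.max() / snr, resp.size)
        return direction_coherence_tuning(resp, segments, traces, lag_s=0)

    def test_single_positive_direction_preferred(self):
        segments = {d: (k * 10, (k + 1) * 10) for k, d in
                    enumerate(range(0, 360, 45))}
        m = np.linspace(0, 1, 10)
        traces = {d: m for d in segments}
        resp = np.zeros(80)
        resp[20:30] = m  # direction 90 only
        corrs, pref, best = direction_coherence_tuning(resp, segments, traces,
                                                       lag_s=0)
        assert pref == pytest.approx(90.0)
        assert best == pytest.approx(corrs[90])

    def test_equal_weights_bisect(self):
        segments = {0: (0, 10), 90: (10, 20)}
        m = np.linspace(0, 1, 10)
        traces = {0: m, 90: m}
        resp = np.concatenate([m, m])
        _, pref, _ = direction_coherence_tuning(resp, segments, traces, lag_s=0)
        assert pref == pytest.approx(45.0)

    def test_planted_von_mises_mu_recovered(self, rng):
        for _ in range(25):
            mu = rng.uniform(0, 360)
            _, pref, _ = self._harness(mu, kappa=2.0, snr=5.0, rng=rng)
            err = abs((pref - mu + 180) % 360 - 180)
            assert err <= 22.5

    def test_all_negative_correlations_give_nan_preference(self, rng):
        segments = {0: (0, 50), 180: (50, 100)}
        m = np.linspace(0, 1, 50)
        traces = {0: m, 180: m}
        resp = np.concatenate([-m, -m])
        _, pref, _ = direction_coherence_tuning(resp, segments, traces, lag_s=0)
        assert math.isnan(pref)


class TestHodgesAjne:
    def test_published_exact_tail_values(self):
        assert hodges_ajne_pvalue(10, 2) == pytest.approx(270 / 512)
        assert hodges_ajne_pvalue(10, 0) == pytest.approx(10 / 512)

    def test_statistic_on_constructed_samples(self, rng):
        tight = rng.uniform(0, 0.01, 10)  # all in one tiny arc: m = 0
        assert hodges_ajne_m(tight) == 0
        assert hodges_ajne(tight) == pytest.approx(10 / 512)
        uniformish = np.linspace(0, 2 * np.pi, 10, endpoint=False) + 0.01
        assert hodges_ajne(uniformish) == 1.0  # perfectly balanced: m = n/2

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hodges_ajne(np.array([0.0, 1.0, 2.0]))

    def test_null_calibration_matches_exact_tail(self):
        # at n = 100 the discrete statistic's attainable level is ~0.03
        # (reject iff m <= 34; exact tail 0.029), not the nominal 0.05
        rng = np.random.default_rng(77)
        rej = sum(hodges_ajne(rng.uniform(0, 2 * np.pi, 100)) <= 0.05
                  for _ in range(2000)) / 2000
        expected = hodges_ajne_pvalue(100, 34)
        assert abs(rej - expected) < 3 * math.sqrt(expected * (1 - expected) / 2000)


class TestElevationBinnedTuning:
    def test_noiseless_linear_dependence_recovered_exactly(self, rng):
        el = rng.uniform(-40, 40, 200)
        y = 0.5 - 0.01 * el
        fit = elevation_binned_tuning(el, y, z_score=False, n_boot=200)
        assert fit["slope"] == pytest.approx(-0.01, abs=1e-12)
        assert fit["slope_ci"][1] - fit["slope_ci"][0] < 1e-9

    def test_null_slope_ci_covers_zero(self):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            el = r.uniform(-40, 40, 200)
            y = r.normal(0, 1, 200)
            fit = elevation_binned_tuning(el, y, n_boot=500, seed=s)
            lo, hi = fit["slope_ci"]
            hits += lo <= 0 <= hi
        assert hits >= 93

    def test_planted_negative_slope_sign_recovered(self):
        neg = 0
        for s in range(40):
            r = np.random.default_rng(1000 + s)
            el = r.uniform(-40, 40, 150)
            y = 0.3 - 0.01 * el + r.normal(0, 0.15, 150)
            neg += elevation_binned_tuning(el, y, seed=s, n_boot=100)["slope"] < 0
        assert neg >= 38

    def test_single_bin_rejected(self, rng):
        with pytest.raises(ValueError):
            elevation_binned_tuning(np.full(20, 5.0), rng.normal(0, 1, 20))


class TestCellPipeline:
    def test_end_to_end_recovery_of_planted_cells(self, twophoton_session):
        truth, sess = twophoton_session
        result = run_cell_pipeline(sess, truth.um_per_px)
        tab = result.table
        recovered = 0
        for i in range(truth.n_cells):
            d = np.hypot(tab["row"] - truth.centers[i, 0],
                         tab["col"] - truth.centers[i, 1])
            if d.min() > 4:
                continue
            j = d.idxmin()
            dir_err = abs((tab.loc[j, "preferred_direction"]
                           - truth.preferred_direction[i] + 180) % 360 - 180)
            rf_err = abs(tab.loc[j, "rf_center_deg"] - truth.rf_elevation[i])
            if dir_err <= 45 and rf_err <= 5:
                recovered += 1
        assert recovered / truth.n_cells >= 0.85
        assert result.qc is not None and result.qc.passed

    def test_registration_equivariance_of_cell_outputs(
            self, twophoton_session, twophoton_session_still):
        truth, moving = twophoton_session
        _, still = twophoton_session_still
        a = run_cell_pipeline(moving, truth.um_per_px).table
        b = run_cell_pipeline(still, truth.um_per_px).table
        assert len(a) == len(b)
        a = a.sort_values(["row", "col"]).reset_index(drop=True)
        b = b.sort_values(["row", "col"]).reset_index(drop=True)
        np.testing.assert_allclose(a["row"], b["row"], atol=1.5)
        np.testing.assert_allclose(a["alpha"], b["alpha"], atol=0.1)
        dir_err = np.abs((a["preferred_direction"] - b["preferred_direction"]
                          + 180) % 360 - 180)
        assert np.nanmedian(dir_err) <= 10
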