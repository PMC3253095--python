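import numpy as np
import pandas as pd
import pytest

from tests.conftest import series_from_volumes
from trialprep import glm_eval, qc_select
from trialprep.core_io import ConcatIndex, Event, Trial, TrialTable, VolumeSeries
from trialprep.glm_eval import (
    build_design,
    build_regressors,
    canonical_hrf,
    count_suprathreshold,
    fit_glm,
    select_regressor_rows,
    smooth_spatial,
)
from trialprep.synthetic import SimConfig, simulate_session


class TestCanonicalHrf:
    def test_peak_near_five_seconds(self):
        dt = 0.1
        h = canonical_hrf(dt)
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=dt)

    def test_zero_at_onset_and_undershoot_negative(self):
        h = canonical_hrf(0.5)
        assert h[0] == 0.0
        t = np.arange(len(h)) * 0.5
        assert h[(t > 10) & (t < 25)].min() < 0
        assert h.sum() > 0
        assert h.max() == pytest.approx(1.0)


class TestBuildRegressors:
    def test_empty_table_gives_zeros(self):
        reg = build_regressors(TrialTable([]), [20], 1.0, ["stimulation"])
        assert (reg["stimulation"] == 0).all()
        assert len(reg) == 20

    def test_unknown_condition_errors(self):
        trials = TrialTable([Trial(0, 0, 0, 9, [Event("fixation", 0, 2)])])
        with pytest.raises(KeyError, match="reward"):
            build_regressors(trials, [20], 1.0, ["reward"])

    def test_single_event_peaks_at_onset_plus_six(self):
        trials = TrialTable([Trial(0, 0, 5, 25, [Event("stim", 10.0, 2.0)])])
        reg = build_regressors(trials, [40], 1.0, ["stim"])
        peak_t = float(np.argmax(reg["stim"].to_numpy()))
        assert abs(peak_t - 16.0) <= 1.0
        assert reg["stim"].max() == pytest.approx(1.0)

    def test_convolution_is_additive_over_events(self):
        one = TrialTable([Trial(0, 0, 0, 59, [Event("s", 5.0, 2.0)])])
        other = TrialTable([Trial(0, 0, 0, 59, [Event("s", 40.0, 2.0)])])
        both = TrialTable([Trial(0, 0, 0, 59, [Event("s", 5.0, 2.0),
                                               Event("s", 40.0, 2.0)])])
        r1 = build_regressors(one, [60], 1.0, ["s"]).to_numpy()
        r2 = build_regressors(other, [60], 1.0, ["s"]).to_numpy()
        rb = build_regressors(both, [60], 1.0, ["s"]).to_numpy()
        # same normalization: events are far apart, so peaks match
        np.testing.assert_allclose(rb, r1 + r2, atol=1e-6)

    def test_row_selection_matches_concatenation(self):
        cfg = SimConfig.small(seed=0)
        series, trials, _, _ = simulate_session(cfg)
        _, index = qc_select.concatenate(series, trials)
        reg = build_regressors(trials, {0: 100, 1: 100}, cfg.intervolume_time,
                               ["stimulation", "fixation"])
        sel = select_regressor_rows(reg, index)
        assert len(sel) == index.n_kept
        rows = [r * 100 + i for r, i in index.kept]
        np.testing.assert_array_equal(sel.to_numpy(), reg.to_numpy()[rows])

    def test_row_selection_commutes_with_sum(self):
        cfg = SimConfig.small(seed=0)
        series, trials, _, _ = simulate_session(cfg)
        _, index = qc_select.concatenate(series, trials)
        reg = build_regressors(trials, {0: 100, 1: 100}, cfg.intervolume_time,
                               ["stimulation", "fixation"])
        summed = pd.DataFrame({"s": reg.sum(axis=1)})
        a = select_regressor_rows(summed, index)["s"].to_numpy()
        b = select_regressor_rows(reg, index).sum(axis=1).to_numpy()
        np.testing.assert_allclose(a, b)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, phantom):
        series = series_from_volumes([phantom[0]] * 2, voxel_size=(2, 2, 2))
        out = smooth_spatial(series, (0, 0, 0))
        np.testing.assert_array_equal(out.data, series.data)

    def test_interior_mass_conserved(self, phantom):
        img = np.zeros((32, 32, 8))
        img[10:22, 10:22, 2:6] = 50.0
        series = series_from_volumes([img], voxel_size=(2, 2, 2))
        out = smooth_spatial(series, (2, 2, 2))
        assert out.data.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_delta_profile_width_matches_fwhm(self):
        img = np.zeros((33, 33, 9))
        img[16, 16, 4] = 1.0
        series = series_from_volumes([img], voxel_size=(1.0, 1.0, 1.0))
        out = smooth_spatial(series, (4.0, 4.0, 4.0))
        prof = out.data[:, 16, 4, 0]
        half = prof.max() / 2
        above = np.flatnonzero(prof >= half)
        width = above[-1] - above[0] + 1
        assert width == pytest.approx(4.0, abs=1.0)


def _toy_design(n=40, seed=0):
    rng = np.random.default_rng(seed)
    reg = pd.DataFrame({"stim": rng.uniform(0, 1, n), "fix": rng.uniform(0, 1, n)})
    run_id = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    return build_design(reg, run_id), run_id


class TestFitGlm:
    def test_exact_recovery_on_noise_free_data(self):
        design, run_id = _toy_design()
        beta0 = np.array([2.0, -1.0, 5.0, 7.0])
        y = design.X @ beta0
        data = np.tile(y, (4, 4, 2, 1))
        series = VolumeSeries.from_runs(data, (1, 1, 1), 1.0, "y",
                                        [20, 20])
        c = design.contrast({"stim": 1.0, "fix": -1.0})
        res = fit_glm(series, design, c, grand_mean_scale=False)
        np.testing.assert_allclose(res.beta[0, 0, 0], beta0, atol=1e-9)
        assert res.degenerate.all()
        assert (res.t == 0).all()

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        design, _ = _toy_design()
        n = design.X.shape[0]
        data = rng.standard_normal((3, 3, 2, n)) + 100.0
        series = VolumeSeries.from_runs(data, (1, 1, 1), 1.0, "y", [20, 20])
        c = design.contrast({"stim": 1.0})
        res = fit_glm(series, design, c, grand_mean_scale=False)
        beta = res.beta.reshape(-1, design.X.shape[1])
        resid = data.reshape(-1, n) - beta @ design.X.T
        dots = resid @ design.X
        assert np.abs(dots).max() < 1e-8 * np.abs(data).max() * n

    def test_grand_mean_scaling_leaves_t_unchanged(self):
        rng = np.random.default_rng(2)
        design, _ = _toy_design()
        n = design.X.shape[0]
        data = rng.standard_normal((3, 3, 2, n)) + 100.0
        series = VolumeSeries.from_runs(data, (1, 1, 1), 1.0, "y", [20, 20])
        c = design.contrast({"stim": 1.0, "fix": -1.0})
        t_raw = fit_glm(series, design, c, grand_mean_scale=False).t
        t_gms = fit_glm(series, design, c, grand_mean_scale=True).t
        np.testing.assert_allclose(t_gms, t_raw, atol=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        design, run_id = _toy_design()
        n = design.X.shape[0]
        data = rng.standard_normal((2, 2, 2, n)) + 50.0
        perm = rng.permutation(n)
        series = VolumeSeries.from_runs(data, (1, 1, 1), 1.0, "y", [n])
        X_perm = glm_eval.DesignMatrix(design.X[perm], design.names)
        series_perm = VolumeSeries.from_runs(data[..., perm], (1, 1, 1),
                                             1.0, "y", [n])
        c = design.contrast({"stim": 1.0, "fix": -1.0})
        t_a = fit_glm(series, design, c, grand_mean_scale=False).t
        t_b = fit_glm(series_perm, X_perm, c, grand_mean_scale=False).t
        np.testing.assert_allclose(t_a, t_b, atol=1e-9)

    def test_artefact_regressor_zeroes_residual_at_volume(self):
        rng = np.random.default_rng(4)
        n = 30
        reg = pd.DataFrame({"stim": rng.uniform(0, 1, n)})
        run_id = np.zeros(n, int)
        design = build_design(reg, run_id, artefact_rows=[7])
        data = rng.standard_normal((2, 2, 1, n)) + 10.0
        series = VolumeSeries.from_runs(data, (1, 1, 1), 1.0, "y", [n])
        res = fit_glm(series, design, design.contrast({"stim": 1.0}),
                      grand_mean_scale=False)
        beta = res.beta.reshape(-1, design.X.shape[1])
        resid = data.reshape(-1, n) - beta @ design.X.T
        assert np.abs(resid[:, 7]).max() < 1e-10

    def test_design_row_mismatch_errors(self):
        design, _ = _toy_design()
        series = VolumeSeries.from_runs(np.zeros((2, 2, 1, 10)), (1, 1, 1),
                                        1.0, "y", [10])
        with pytest.raises(ValueError, match="design rows"):
            fit_glm(series, design, design.contrast({"stim": 1.0}))


class TestSuprathreshold:
    def test_counts_and_monotonicity(self):
        t_map = np.zeros((4, 4, 2))
        t_map[:2] = 5.0
        res = glm_eval.GLMResult(np.zeros((4, 4, 2, 1)), np.ones((4, 4, 2)),
                                 t_map, 10, ["c"], np.zeros((4, 4, 2), bool))
        mask = np.ones((4, 4, 2), bool)
        count, prop = count_suprathreshold(res, mask, 3.11)
        assert (count, prop) == (16, 0.5)
        c4, _ = count_suprathreshold(res, mask, 4.0)
        c3, _ = count_suprathreshold(res, mask, 3.0)
        assert c4 <= c3

    def test_empty_mask_errors(self):
        res = glm_eval.GLMResult(np.zeros((2, 2, 1, 1)), np.ones((2, 2, 1)),
                                 np.zeros((2, 2, 1)), 5, ["c"],
                                 np.zeros((2, 2, 1), bool))
        with pytest.raises(ValueError, match="empty"):
            count_suprathreshold(res, np.zeros((2, 2, 1), bool), 3.11)


class TestGlmOnSimulation:
    def test_activation_detected_with_low_false_positives(self, clean_session):
        series, trials, _, truth = clean_session
        conds = ["stimulation", "fixation"]
        reg = build_regressors(trials, {r: series.run_length(r)
                                        for r in series.runs()},
                               series.intervolume_time, conds)
        design = build_design(reg, series.run_id)
        c = design.contrast({"stimulation": 1.0, "fixation": -1.0})
        smoothed = smooth_spatial(series, (2, 2, 2))
        res = fit_glm(smoothed, design, c, mask=truth.brain_mask)
        t_in = res.t[truth.activation_map]
        assert t_in.mean() > 3.11
        outside = truth.brain_mask & ~truth.activation_map
        fp = np.mean(res.t[outside] > 3.11)
        assert fp < 0.02

    def test_method2_adds_one_column_per_artefact_volume(self, corrupted_session):
        _, (series, trials, _, truth) = corrupted_session
        analysis = glm_eval._SessionAnalysis(series, trials,
                                             glm_eval.EvalConfig(),
                                             brain_roi=truth.brain_mask)
        reg = analysis.regressors_full()
        d1 = build_design(reg, series.run_id)
        rows = analysis._artefact_rows_full()
        d2 = build_design(reg, series.run_id, rows)
        assert d2.X.shape[1] == d1.X.shape[1] + len(rows)
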