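"""Design-matrix construction, OLS estimation and contrast inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emfl import design as d
from emfl import glm
from tests.conftest import estimable_truth


def _toy_events(n_runs=1):
    """Two-condition mini block design: 50 volumes per run."""
    rows = []
    for r in range(1, n_runs + 1):
        rows += [
            (4.0, 12.0, "faces", r),
            (24.0, 12.0, "objects", r),
            (60.0, 12.0, "faces", r),
            (80.0, 12.0, "objects", r),
        ]
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run"])


def _toy_design(n_runs=1, seed=0):
    rng = np.random.default_rng(seed)
    n_vol = 50
    nuisance = {r: rng.standard_normal((n_vol, 6)) for r in range(1, n_runs + 1)}
    return glm.build_design_matrix(
        _toy_events(n_runs), nuisance, {r: n_vol for r in range(1, n_runs + 1)},
        condition_labels=["faces", "objects"],
    )


class TestDesignMatrix:
    def test_canonical_session_dimensions(self, schedule, emfl_session):
        design = glm.design_matrix_from_schedule(
            schedule, {r.run_index: r.nuisance for r in emfl_session.runs})
        assert design.n_rows == 5 * 137 == 685
        assert len(design.columns) == 10 + 6 + 2 * 5
        # crossed design: exactly one rank lost, to the modality-mean split
        assert design.rank == len(design.columns) - 1
        v = design.null_space[:, 0]
        cond = v[:10]
        vis = cond[:5] / np.abs(cond[:5]).max()
        aud = cond[5:] / np.abs(cond[:5]).max()
        assert np.allclose(vis, vis[0]) and np.allclose(aud, -vis[0])
        assert np.allclose(v[10:], 0)

    def test_condition_column_zero_before_first_block(self, schedule, emfl_session):
        design = glm.design_matrix_from_schedule(
            schedule, {r.run_index: r.nuisance for r in emfl_session.runs})
        frame = design.to_frame()
        # first 18 s of each run are fixation: regressor still zero at t=0..16
        col = frame["faces"].to_numpy()
        for r in range(5):
            assert np.allclose(col[r * 137: r * 137 + 9][:int(18 / 2)], 0.0)

    def test_sustained_block_plateaus_at_one(self):
        reg = glm.condition_regressor([10.0], [120.0], 100, tr=2.0)
        assert abs(reg[40] - 1.0) < 1e-6  # 70 s into a 120 s block

    def test_rank_deficiency_names_collinear_columns(self):
        events = _toy_events()
        rng = np.random.default_rng(0)
        nuis = rng.standard_normal((50, 6))
        nuis[:, 5] = nuis[:, 4]  # duplicate nuisance column
        with pytest.raises(glm.RankDeficientDesignError, match="nuisance"):
            glm.build_design_matrix(events, {1: nuis}, {1: 50},
                                    condition_labels=["faces", "objects"])

    def test_nuisance_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="nuisance"):
            glm.build_design_matrix(_toy_events(), {1: np.zeros((40, 6))}, {1: 50},
                                    condition_labels=["faces", "objects"])

    def test_regressor_shape_matches_nilearn_reference(self):
        from nilearn.glm.first_level import compute_regressor

        frame_times = np.arange(50) * 2.0
        ours = glm.condition_regressor([10.0], [20.0], 50, tr=2.0)
        theirs, _ = compute_regressor(
            np.array([[10.0, 20.0, 1.0]]).T, "spm", frame_times)
        r = np.corrcoef(ours, theirs[:, 0])[0, 1]
        assert r > 0.999


class TestOlsOracle:
    def test_betas_and_t_match_normal_equations(self):
        """20-timepoint, 3-voxel toy against the explicit (X'X)^-1 X'y oracle."""
        design = _toy_design()
        x = design.matrix[:20, [0, 1, -2]]  # faces, objects, intercept
        rng = np.random.default_rng(5)
        y = rng.standard_normal((20, 3)) + 100.0
        # oracle: closed-form normal equations per voxel
        xtx_inv = np.linalg.inv(x.T @ x)
        beta_oracle = xtx_inv @ x.T @ y
        resid = y - x @ beta_oracle
        dof = 20 - 3
        sig2 = (resid ** 2).sum(axis=0) / dof
        c = np.array([1.0, -1.0, 0.0])
        t_oracle = (c @ beta_oracle) / np.sqrt(sig2 * (c @ xtx_inv @ c))
        # implementation path on the same matrix
        dm = glm.DesignMatrix(matrix=x, columns=["faces", "objects", "run1_intercept"],
                              run_indices=[1] * 20, condition_labels=["faces", "objects"],
                              rank=3)
        fit = glm.fit_glm([y.T.reshape(3, 1, 1, 20)], dm)
        assert np.allclose(fit.beta, beta_oracle, atol=1e-10)
        result = glm.compute_contrast(fit, glm.ContrastSpec("F>O", {"faces": 1, "objects": -1}))
        assert np.allclose(result.t_map, t_oracle, atol=1e-10)
        assert np.allclose(result.p_map, 2 * stats.t.sf(np.abs(t_oracle), dof), atol=1e-12)

    def test_noiseless_session_recovery(self, noiseless_phantom, noiseless_fit):
        """Noiseless simulation recovers the identifiable part of the ground
        truth exactly: estimable projection of betas and all within-modality
        contrasts."""
        expected = estimable_truth(noiseless_phantom, noiseless_fit)
        got = np.stack([noiseless_fit.percent_signal(c) for c in d.ALL_CONDITIONS])
        assert np.abs(got - expected).max() < 1e-6
        amp = noiseless_phantom.amplitude_matrix()[:, noiseless_fit.voxel_indices]
        res = glm.compute_contrast(noiseless_fit, "Faces>Objects")
        assert np.abs(res.effect - (amp[0] - amp[2])).max() < 1e-6

    def test_white_noise_betas_unbiased(self, schedule):
        """Mean beta over many pure-noise voxels sits inside its sampling band."""
        rng = np.random.default_rng(17)
        n_vox = 1000
        nuis = {r.index: rng.standard_normal((137, 6)) for r in schedule.runs}
        design = glm.design_matrix_from_schedule(schedule, nuis)
        y = 100.0 + rng.standard_normal((685, n_vox))
        fit = glm.fit_glm([y.T.reshape(n_vox, 1, 1, 685)], design)
        res = glm.compute_contrast(fit, "Faces>Objects")
        raw = res.effect / 100.0  # percent of baseline 100 -> raw beta units
        se_mean = raw.std() / np.sqrt(n_vox)
        assert abs(raw.mean()) < 4 * se_mean

    def test_concatenated_fit_equals_run_average_noiseless(self, noiseless_session,
                                                           noiseless_phantom):
        mask = noiseless_phantom.parcels > 0
        joint = glm.fit_session(noiseless_session, mask=mask)
        per_run = [glm.fit_session(noiseless_session, [r], mask=mask)
                   for r in noiseless_session.run_indices]
        res_joint = glm.compute_contrast(joint, "Scenes>Objects").effect
        res_avg = np.mean(
            [glm.compute_contrast(f, "Scenes>Objects").effect for f in per_run], axis=0)
        assert np.abs(res_joint - res_avg).max() < 1e-6


class TestContrasts:
    def test_english_average_expansion(self, emfl_fit):
        auto = glm.compute_contrast(emfl_fit, "English>Nonwords")
        manual = glm.compute_contrast(emfl_fit, glm.ContrastSpec(
            "manual", {"false_belief": 0.5, "false_photo": 0.5, "nonwords": -1.0}))
        assert np.allclose(auto.t_map, manual.t_map)
        assert np.allclose(auto.effect, manual.effect)

    def test_all_registry_contrasts_are_estimable_and_zero_sum(self, emfl_fit):
        for name, spec in glm.CONTRASTS.items():
            weights = spec.expanded_weights()
            assert abs(sum(weights.values())) < 1e-12, name
            glm.compute_contrast(emfl_fit, name)  # estimable: must not raise

    def test_zero_and_unknown_weight_errors(self, emfl_fit):
        with pytest.raises(ValueError):
            glm.compute_contrast(emfl_fit, glm.ContrastSpec("null", {"faces": 0.0}))
        with pytest.raises(KeyError):
            glm.compute_contrast(emfl_fit, glm.ContrastSpec("bad", {"nope": 1.0}))

    def test_single_condition_contrast_inestimable_in_crossed_design(self, emfl_fit):
        with pytest.raises(ValueError, match="estimable"):
            glm.compute_contrast(emfl_fit, glm.ContrastSpec("faces-only", {"faces": 1.0}))


class TestSignedLogP:
    def test_threshold_three_is_p_001(self, emfl_fit):
        """A voxel exactly at two-sided p = 0.001 maps to signed log-p 3.0."""
        t_crit = stats.t.isf(0.0005, emfl_fit.dof)
        res = glm.compute_contrast(emfl_fit, "Faces>Objects")
        res.t_map = np.array([t_crit, -t_crit, 0.0])
        res.p_map = 2 * stats.t.sf(np.abs(res.t_map), emfl_fit.dof)
        slp = -np.log10(res.p_map) * np.sign(res.t_map)
        assert np.allclose(slp[:2], [3.0, -3.0], atol=1e-9)

    def test_map_properties(self, emfl_fit):
        res = glm.compute_contrast(emfl_fit, "Faces>Objects")
        assert np.all(res.signed_log_p[res.t_map == 0] == 0)
        # |signed log p| monotone in |t|
        order = np.argsort(np.abs(res.t_map))
        assert np.all(np.diff(np.abs(res.signed_log_p[order])) >= -1e-12)
        thresholded = glm.signed_log_p_map(res, 3.0)
        kept = thresholded != 0
        assert np.all(np.abs(thresholded[kept]) >= 3.0)
        assert np.all(thresholded[~kept] == 0)

    def test_antisymmetry_under_t_negation(self, emfl_fit):
        res = glm.compute_contrast(emfl_fit, "Faces>Objects")
        neg = glm.compute_contrast(emfl_fit, glm.ContrastSpec(
            "O>F", {"objects": 1, "faces": -1}))
        assert np.allclose(neg.signed_log_p, -res.signed_log_p, atol=1e-9)
        assert np.allclose(glm.signed_log_p_map(neg, 3.0),
                           -glm.signed_log_p_map(res, 3.0), atol=1e-9)

    def test_threshold_must_be_nonnegative(self, emfl_fit):
        res = glm.compute_contrast(emfl_fit, "Faces>Objects")
        with pytest.raises(ValueError):
            glm.signed_log_p_map(res, -1.0)
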