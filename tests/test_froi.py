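"""fROI selection rules, cross-validated profiles and growing-window curves."""

import numpy as np
import pytest
from scipy import stats

from emfl import froi
from emfl import glm
from emfl import simulate as sim
from emfl.froi import (
    FIRST_LAST,
    ODD_EVEN,
    Parcel,
    Split,
    crossval_profile,
    define_froi_topk,
    detect_fixed_threshold,
    growing_window_curve,
    parcels_from_phantom,
    rank_parcel_voxels,
)


def _synthetic_result(values, t=None, grid=None):
    """ContrastResult with prescribed signed log-p values on a 1D grid."""
    values = np.asarray(values, dtype=float)
    grid = grid or (values.size, 1, 1)
    t = np.sign(values) if t is None else np.asarray(t, dtype=float)
    p = 10.0 ** (-np.abs(values))
    return glm.ContrastResult(name="synthetic", effect=values.copy(), t_map=t,
                              p_map=p, signed_log_p=values, dof=100,
                              grid_shape=grid,
                              voxel_indices=np.arange(values.size))


class TestTopK:
    @pytest.mark.parametrize("n,fraction,expected", [
        (200, 0.10, 20), (60, 0.10, 6), (10, 0.10, 1), (15, 0.10, 2),  # 1.5 rounds up
        (500, 0.10, 50), (60, 1.0, 60), (25, 0.10, 3),                 # 2.5 away from zero
    ])
    def test_selection_size(self, n, fraction, expected):
        rng = np.random.default_rng(n)
        res = _synthetic_result(rng.standard_normal(n))
        parcel = Parcel("P", np.ones((n, 1, 1), bool), "Faces>Objects")
        sel = define_froi_topk(res, parcel, fraction)
        assert len(sel.voxels) == expected
        # voxels are the top values, ranked
        top = np.sort(np.argsort(-res.signed_log_p, kind="stable")[:expected])
        assert np.array_equal(np.sort(sel.voxels), top)

    def test_all_ties_resolved_by_voxel_index(self):
        res = _synthetic_result(np.full(60, 2.5))
        parcel = Parcel("P", np.ones((60, 1, 1), bool), "Faces>Objects")
        sel = define_froi_topk(res, parcel, 0.10)
        assert np.array_equal(sel.voxels, np.arange(6))  # deterministic tie order

    def test_selection_is_idempotent(self, emfl_fit, phantom):
        parcel = parcels_from_phantom(phantom)[0]
        res = glm.compute_contrast(emfl_fit, parcel.defining_contrast)
        a = define_froi_topk(res, parcel)
        b = define_froi_topk(res, parcel)
        assert np.array_equal(a.voxels, b.voxels)

    def test_invalid_fraction_and_empty_parcel(self):
        res = _synthetic_result(np.arange(10.0))
        parcel = Parcel("P", np.ones((10, 1, 1), bool), "Faces>Objects")
        with pytest.raises(ValueError):
            define_froi_topk(res, parcel, 0.0)
        with pytest.raises(ValueError):
            Parcel("empty", np.zeros((10, 1, 1), bool), "Faces>Objects")

    def test_negative_voxels_never_outrank_positive(self):
        values = np.array([-5.0, -4.0, 0.5, 0.2, 1.0, -6.0])
        parcel = Parcel("P", np.ones((6, 1, 1), bool), "Faces>Objects")
        ranked = rank_parcel_voxels(_synthetic_result(values), parcel)
        assert list(ranked[:3]) == [4, 2, 3]


class TestDetection:
    def test_min_voxel_boundary(self):
        for n_sig, expect in ((9, False), (10, True)):
            values = np.concatenate([np.full(n_sig, 4.0), np.full(60 - n_sig, 1.0)])
            res = _synthetic_result(values)  # 4.0 -> p=1e-4 < 0.001; 1.0 -> p=0.1
            parcel = Parcel("P", np.ones((60, 1, 1), bool), "Faces>Objects")
            det = detect_fixed_threshold(res, parcel)
            assert det.n_significant == n_sig
            assert det.detected is expect

    def test_negative_direction_not_counted(self):
        res = _synthetic_result(np.full(60, -8.0))  # hugely significant, wrong sign
        parcel = Parcel("P", np.ones((60, 1, 1), bool), "Faces>Objects")
        assert detect_fixed_threshold(res, parcel).n_significant == 0

    def test_null_parcel_detection_rate_matches_binomial_oracle(self):
        """Independent uniform p-values: detection of >= 10/60 voxels at
        p<0.001 is essentially impossible (Binomial oracle ~ 4e-18)."""
        oracle = stats.binom.sf(9, 60, 0.001)
        assert oracle < 1e-15
        rng = np.random.default_rng(0)
        parcel = Parcel("P", np.ones((60, 1, 1), bool), "Faces>Objects")
        detections = 0
        for _ in range(1000):
            p = rng.uniform(size=60)
            res = _synthetic_result(-np.log10(p))
            detections += detect_fixed_threshold(res, parcel).detected
        assert detections == 0

    def test_invalid_thresholds(self):
        res = _synthetic_result(np.arange(5.0))
        parcel = Parcel("P", np.ones((5, 1, 1), bool), "Faces>Objects")
        with pytest.raises(ValueError):
            detect_fixed_threshold(res, parcel, p_threshold=0.0)


class TestSplits:
    def test_canonical_odd_even(self):
        assert ODD_EVEN.directions([1, 2, 3, 4, 5]) == [((1, 3, 5), (2, 4)),
                                                        ((2, 4), (1, 3, 5))]

    def test_first_last(self):
        assert FIRST_LAST.directions([1, 2, 3, 4, 5]) == [((1, 2, 3), (4, 5)),
                                                          ((4, 5), (1, 2, 3))]

    def test_degenerate_splits_rejected(self):
        with pytest.raises(ValueError):
            ODD_EVEN.directions([1])
        with pytest.raises(ValueError):
            ODD_EVEN.directions([1, 3])  # no even runs
        with pytest.raises(ValueError):
            Split("bogus").directions([1, 2])


class TestCrossvalProfile:
    def test_noiseless_profile_identities(self, noiseless_phantom, noiseless_session):
        """Exact ground-truth identities of the held-out profile:
        preferred - nonpreferred = (ratio - 1) * amplitude of the selected
        voxels, and the same-modality baseline equals the response to every
        opposite-modality condition (the crossed-design folding)."""
        mask = noiseless_phantom.parcels > 0
        parcel = parcels_from_phantom(noiseless_phantom)[0]  # FFA, ratio 3
        prof = crossval_profile(noiseless_session, parcel, mask=mask)
        voxels = next(iter(prof.froi_voxels.values()))
        amp_non = noiseless_phantom.amplitude["objects"].reshape(-1)[voxels].mean()
        same = [c for c in prof.same_modality_conditions()]
        for c in same:
            if c == "faces":
                continue
            assert abs(prof.response["faces"] - prof.response[c] - 2 * amp_non) < 1e-9
        other = [c for c in prof.response if c not in same]
        for c in other:
            assert abs(prof.response[c] - prof.baseline) < 1e-9

    def test_baseline_is_mean_of_same_modality_conditions(self, emfl_session,
                                                          phantom, parcel_mask):
        parcel = parcels_from_phantom(phantom)[9]  # rTPJ: auditory
        prof = crossval_profile(emfl_session, parcel, mask=parcel_mask)
        same = prof.same_modality_conditions()
        assert prof.modality == "auditory"
        assert abs(prof.baseline - np.mean([prof.response[c] for c in same])) < 1e-12

    def test_preferred_condition_dominates_at_default_cnr(self, emfl_session,
                                                          phantom, parcel_mask):
        fits = {}
        for parcel in parcels_from_phantom(phantom)[:4]:
            prof = crossval_profile(emfl_session, parcel, mask=parcel_mask, fits=fits)
            pref = parcel.preferred_pair[0]
            pref_conds = ("false_belief", "false_photo") if pref == "english" else (pref,)
            best = max(prof.response, key=prof.response.get)
            assert best in pref_conds, parcel.label

    def test_double_dipping_inflates_training_selectivity(self, phantom, schedule,
                                                          parcel_mask):
        """Measuring on the runs that defined the fROI overstates selectivity
        relative to held-out measurement, on average across simulations."""
        parcel = parcels_from_phantom(phantom)[0]
        train_gain, test_gain = [], []
        for seed in range(6):
            sess = sim.simulate_session(phantom, schedule, seed=200 + seed,
                                        mask=parcel_mask)
            train, test = ODD_EVEN.directions(sess.run_indices)[0]
            fit_train = glm.fit_session(sess, train, mask=parcel_mask)
            fit_test = glm.fit_session(sess, test, mask=parcel_mask)
            res = glm.compute_contrast(fit_train, parcel.defining_contrast)
            voxels = define_froi_topk(res, parcel).voxels
            for fit, out in ((fit_train, train_gain), (fit_test, test_gain)):
                pref = froi.condition_response(fit, "faces", voxels)
                non = froi.condition_response(fit, "objects", voxels)
                out.append(pref - non)
        assert np.mean(train_gain) > np.mean(test_gain)


class TestGrowingWindow:
    def test_curve_equals_from_scratch_means_for_all_k(self, emfl_session,
                                                       phantom, parcel_mask):
        parcel = parcels_from_phantom(phantom)[3]  # PPA
        train, test = ODD_EVEN.directions(emfl_session.run_indices)[0]
        fit_train = glm.fit_session(emfl_session, train, mask=parcel_mask)
        fit_test = glm.fit_session(emfl_session, test, mask=parcel_mask)
        res = glm.compute_contrast(fit_train, parcel.defining_contrast)
        curve = growing_window_curve(res, fit_test, parcel)
        ranked = rank_parcel_voxels(res, parcel)
        assert np.array_equal(curve.sizes, np.arange(1, 61))
        for cond in ("scenes", "objects", "arithmetic"):
            direct = np.array([
                froi.condition_response(fit_test, cond, ranked[:k]) for k in curve.sizes
            ])
            assert np.abs(curve.responses[cond] - direct).max() < 1e-12
        # k = N equals the plain parcel mean; k = 1 the single best voxel
        full = froi.condition_response(fit_test, "scenes", parcel.flat_indices)
        assert abs(curve.responses["scenes"][-1] - full) < 1e-12
        single = froi.condition_response(fit_test, "scenes", ranked[:1])
        assert abs(curve.responses["scenes"][0] - single) < 1e-12

    def test_selectivity_declines_with_size(self, emfl_session, phantom, parcel_mask):
        """Top-10% selectivity exceeds whole-parcel selectivity in held-out
        data (the rationale for intersecting parcels with activation)."""
        parcel = parcels_from_phantom(phantom)[0]
        train, test = ODD_EVEN.directions(emfl_session.run_indices)[0]
        fit_train = glm.fit_session(emfl_session, train, mask=parcel_mask)
        fit_test = glm.fit_session(emfl_session, test, mask=parcel_mask)
        res = glm.compute_contrast(fit_train, parcel.defining_contrast)
        curve = growing_window_curve(res, fit_test, parcel)
        diff = curve.responses["faces"] - curve.responses["objects"]
        assert diff[5] > diff[-1]
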