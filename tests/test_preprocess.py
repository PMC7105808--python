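"""Volume discard, realignment, displacement/exclusion, masking,
smoothing and grand-mean normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonguepipe.core import MotionTrace, Volume4D
from tonguepipe.fixturegen import Scenario, head_mask, simulate_subject
from tonguepipe.preprocess import (brain_mask, discard_initial,
                                   displacement_and_exclusion,
                                   realign_translational, smooth_and_normalize)


class TestDiscard:
    def test_discard_rule(self, subject42):
        raw, _, _ = subject42
        assert discard_initial(raw, 4).n_volumes == 304

    def test_zero_discard_identity(self, subject42):
        raw, _, _ = subject42
        assert np.array_equal(discard_initial(raw, 0).data, raw.data)

    def test_discard_with_onset_shift(self, paradigm):
        vol = Volume4D(np.random.default_rng(0).random((4, 4, 4, 5)),
                       (3, 3, 3), 1.8)
        assert discard_initial(vol, 4).n_volumes == 1
        shifted = paradigm.shifted(-4 * 1.8)
        assert shifted.events[0].onset_s == pytest.approx(
            paradigm.events[0].onset_s - 7.2)

    def test_discard_too_many(self, subject42):
        raw, _, _ = subject42
        with pytest.raises(ValueError):
            discard_initial(raw, raw.n_volumes)


class TestRealign:
    def test_motion_free_null_estimates(self, protocol, paradigm, library):
        sc = Scenario(motion="none", motion_component=False)
        raw, _, _ = simulate_subject(protocol, paradigm, sc, 9, library)
        _, trace = realign_translational(discard_initial(raw, 4))
        assert np.abs(trace.translations_mm).max() / 3.0 < 0.1

    def test_injected_shift_recovered(self, protocol, paradigm, library):
        mot = np.zeros((308, 3))
        mot[54:85, 0] = 3.0  # +1 voxel on recorded volumes 54..84
        sc = Scenario(motion=mot, motion_component=False)
        raw, _, gt = simulate_subject(protocol, paradigm, sc, 3, library)
        _, trace = realign_translational(discard_initial(raw, 4))
        truth = gt.motion_truth[4:]
        truth = truth - truth[trace.reference_index]
        err_vox = np.abs(trace.translations_mm - truth) / 3.0
        assert err_vox.max() < 0.25

    def test_reference_estimate_exactly_zero(self, subject42):
        raw, _, _ = subject42
        _, trace = realign_translational(discard_initial(raw, 4))
        assert np.all(trace.params[trace.reference_index] == 0.0)

    def test_idempotent(self, protocol, paradigm, library):
        sc = Scenario(motion="mild")
        raw, _, _ = simulate_subject(protocol, paradigm, sc, 6, library)
        vol, _ = realign_translational(discard_initial(raw, 4))
        _, trace2 = realign_translational(vol)
        assert np.abs(trace2.translations_mm).max() / 3.0 < 0.05

    def test_zero_reference_error(self):
        vol = Volume4D(np.zeros((6, 6, 6, 4)), (3, 3, 3), 1.8)
        with pytest.raises(ValueError):
            realign_translational(vol)


class TestDisplacement:
    def test_zero_motion(self):
        trace = MotionTrace(np.zeros((10, 6)), 5)
        trace, rep = displacement_and_exclusion(trace)
        assert rep.abs_mean == 0 and rep.rel_mean == 0 and not rep.exclude
        assert trace.abs_disp[trace.reference_index] == 0
        assert len(trace.rel_disp) == 9

    def test_alternating_translations_rel_disp(self):
        params = np.zeros((20, 6))
        params[1::2, 3] = 0.3
        params[1::2, 5] = 0.4
        _, rep = displacement_and_exclusion(MotionTrace(params, 0))
        assert np.allclose(rep.rel_disp, 0.5)

    def test_exclusion_at_rel_limit(self):
        params = np.zeros((20, 6))
        params[1::2, 3] = 1.2  # rel steps of 1.2 mm -> rel_mean 1.14
        _, rep = displacement_and_exclusion(MotionTrace(params, 0))
        assert rep.rel_mean >= 1.0 and rep.exclude

    def test_rotation_arc_contribution(self):
        params = np.zeros((2, 6))
        params[1, 0] = 0.01  # rad -> 0.8 mm on the 80 mm sphere
        _, rep = displacement_and_exclusion(MotionTrace(params, 0))
        assert rep.rel_disp[0] == pytest.approx(0.8)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10**6), st.floats(1.0, 5.0))
    def test_exclusion_monotone_in_scale(self, seed, c):
        rng = np.random.default_rng(seed)
        params = np.zeros((30, 6))
        params[:, 3:6] = rng.normal(0, 0.5, (30, 3))
        _, rep1 = displacement_and_exclusion(MotionTrace(params, 0))
        scaled = params.copy()
        scaled[:, 3:6] *= c
        _, rep2 = displacement_and_exclusion(MotionTrace(scaled, 0))
        assert not (rep1.exclude and not rep2.exclude)

    def test_empty_trace_error(self):
        with pytest.raises(ValueError):
            MotionTrace(np.zeros((0, 6)), 0)


class TestBrainMask:
    def test_dice_against_true_head(self, subject42):
        raw, _, _ = subject42
        m = brain_mask(discard_initial(raw, 4))
        truth = head_mask((24, 24, 14))
        dice = 2 * (m & truth).sum() / (m.sum() + truth.sum())
        assert dice > 0.95
        assert m.dtype == bool

    def test_zero_volume_error(self):
        vol = Volume4D(np.zeros((8, 8, 8, 5)), (3, 3, 3), 1.8)
        with pytest.raises(ValueError):
            brain_mask(vol)


class TestSmoothNormalize:
    def test_impulse_fwhm(self):
        data = np.zeros((41, 41, 41, 1))
        data[20, 20, 20, 0] = 1.0
        vol = Volume4D(data, (1, 1, 1), 1.8, mask=np.ones((41, 41, 41), bool))
        out = smooth_and_normalize(vol, fwhm_mm=5.0, target_grand_mean=1.0)
        prof = out.data[:, 20, 20, 0]
        half = prof.max() / 2
        above = np.where(prof >= half)[0]
        # linear-interpolated width at half maximum
        lo = above[0] - (half - prof[above[0]]) / (prof[above[0] - 1] - prof[above[0]])
        hi = above[-1] + (half - prof[above[-1]]) / (prof[above[-1] + 1] - prof[above[-1]])
        assert hi - lo == pytest.approx(5.0, rel=0.05)

    def test_zero_fwhm_and_grand_mean(self, subject42):
        raw, _, _ = subject42
        vol = discard_initial(raw, 4)
        vol.mask = brain_mask(vol)
        out = smooth_and_normalize(vol, fwhm_mm=0.0)
        # zero smoothing: output is a pure rescale of the input
        factor = out.data[vol.mask][0, 0] / vol.data[vol.mask][0, 0]
        assert np.allclose(out.data, vol.data * factor)
        assert out.data[out.mask].mean() == pytest.approx(10000.0, rel=1e-6)

    def test_interior_sum_preserved(self):
        data = np.zeros((30, 30, 30, 1))
        data[12:18, 12:18, 12:18, 0] = 2.0
        vol = Volume4D(data, (3, 3, 3), 1.8, mask=np.ones((30, 30, 30), bool))
        # smoothing moves mass around but conserves it, so normalizing to
        # the input's own grand mean leaves the total unchanged
        target = data[vol.mask].mean()
        out = smooth_and_normalize(vol, fwhm_mm=5.0, target_grand_mean=target)
        assert out.data.sum() == pytest.approx(data.sum(), rel=0.01)

    def test_missing_mask_error(self, subject42):
        raw, _, _ = subject42
        with pytest.raises(ValueError):
            smooth_and_normalize(discard_initial(raw, 4))
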