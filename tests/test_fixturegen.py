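"""Synthetic subject/cohort generator and the template library."""

import numpy as np
import pytest

from tonguepipe.core import AcquisitionProtocol
from tonguepipe.design import HRFParams, build_design_matrix
from tonguepipe.fixturegen import (CohortSpec, Scenario, build_template_library,
                                   derive_seeds, head_mask, motion_schedule,
                                   simulate_cohort, simulate_subject,
                                   write_subject)


class TestTemplateLibrary:
    def test_ten_named_maps(self, library):
        assert len(library.names) == 10
        assert library.maps.shape[0] == 10
        for m in library.maps:
            assert np.ptp(m[library.mask]) > 0          # non-constant in mask
            assert np.all(m[~library.mask] == 0)        # zero outside

    def test_correlation_structure(self, library):
        corr = library.correlation_matrix()
        assert np.allclose(np.diag(corr), 1.0)
        off = np.abs(corr - np.eye(10))
        assert off.max() < 0.3  # all 45 pairwise correlations

    def test_deterministic(self, protocol):
        a = build_template_library(seed=7)
        b = build_template_library(seed=7)
        assert np.array_equal(a.maps, b.maps)

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError):
            build_template_library(grid_shape=(6, 6, 6))

    def test_label_volume(self, library):
        labels = library.label_volume()
        assert set(np.unique(labels)) == set(range(11))


class TestSimulateSubject:
    def test_recorded_volumes_and_tr(self, subject42, protocol):
        raw, trace, gt = subject42
        assert raw.n_volumes == protocol.n_recorded_volumes == 308
        assert raw.tr_seconds == pytest.approx(1.8)
        assert trace.params.shape == (308, 6)
        assert np.all(trace.rotations_rad == 0)

    def test_task_plant_hits_target_r(self, subject42, protocol, paradigm):
        _, _, gt = subject42
        design = build_design_matrix(paradigm, HRFParams(), protocol)
        task = next(p for p in gt.planted if p.name == "task_sensorimotor")
        r = np.corrcoef(task.timecourse[protocol.n_discard:],
                        design.expected_response)[0, 1]
        assert 0.63 <= r <= 0.77
        anti = next(p for p in gt.planted if p.name == "occipital_anticorrelated")
        r = np.corrcoef(anti.timecourse[protocol.n_discard:],
                        design.expected_response)[0, 1]
        assert -0.66 <= r <= -0.54

    def test_network_plant_map_correlation(self, subject42, library):
        _, _, gt = subject42
        for p in gt.planted:
            if p.timecourse_kind != "network_structured":
                continue
            name = p.name.removeprefix("network_")
            tmpl = library.maps[library.names.index(name)]
            r = np.corrcoef(p.map[library.mask], tmpl[library.mask])[0, 1]
            assert r == pytest.approx(0.6, abs=1e-9)
            assert np.all(p.map >= 0)

    def test_noiseless_single_plant_is_rank_one(self, protocol, paradigm, library):
        sc = Scenario(task=True, anticorr=False, networks=(), motion_component=False,
                      csf_component=False, noise_sd=0.0, head_intensity=0.0,
                      motion="none")
        raw, _, _ = simulate_subject(protocol, paradigm, sc, 1, library)
        mat = raw.data.reshape(-1, raw.n_volumes)
        s = np.linalg.svd(mat, compute_uv=False)
        assert s[1] < 1e-10 * s[0]

    def test_pure_noise_ar1_autocorrelation(self, protocol, paradigm, library):
        sc = Scenario(task=False, anticorr=False, networks=(),
                      motion_component=False, csf_component=False,
                      noise_sd=1.0, ar1=0.3, motion="none")
        raw, _, gt = simulate_subject(protocol, paradigm, sc, 2, library)
        x = raw.data[gt.head_mask]               # (V, T), T >= 200
        x = x - x.mean(axis=1, keepdims=True)
        num = (x[:, 1:] * x[:, :-1]).sum()
        den = (x * x).sum()
        assert num / den == pytest.approx(0.3, abs=0.05)

    def test_bit_identical_for_fixed_seed(self, protocol, paradigm, library):
        a, _, _ = simulate_subject(protocol, paradigm, Scenario(), 5, library)
        b, _, _ = simulate_subject(protocol, paradigm, Scenario(), 5, library)
        assert np.array_equal(a.data, b.data)

    def test_unknown_network_raises(self, protocol, paradigm, library):
        with pytest.raises(ValueError, match="unknown network"):
            simulate_subject(protocol, paradigm,
                             Scenario(networks=("no_such_net",)), 0, library)

    def test_write_subject(self, subject42, library, tmp_path):
        raw, trace, gt = subject42
        write_subject(tmp_path, raw, trace, gt, library)
        assert (tmp_path / "func.nii.gz").exists()
        assert (tmp_path / "motion_injected.tsv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        loaded = np.loadtxt(tmp_path / "motion_injected.tsv", delimiter="\t")
        assert loaded.shape == (308, 6)


class TestMotionSchedule:
    def test_presets(self):
        rng = np.random.default_rng(0)
        assert np.all(motion_schedule("none", 50, rng) == 0)
        mild = motion_schedule("mild", 300, rng)
        assert np.abs(mild).max() < 2.0
        exc = motion_schedule("excessive", 300, rng)
        rel = np.linalg.norm(np.diff(exc, axis=0), axis=1)
        assert rel.mean() > 1.0

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            motion_schedule("wild", 10, np.random.default_rng(0))


class TestSimulateCohort:
    def test_sizes(self, protocol, paradigm, library):
        small = AcquisitionProtocol(n_recorded_volumes=20, n_discard=0)
        quick = Scenario(task=False, anticorr=False, networks=(),
                         motion_component=False, csf_component=False,
                         motion="none")
        assert simulate_cohort(small, paradigm, CohortSpec(n=0, base=quick),
                               1, library) == []
        one = simulate_cohort(small, paradigm, CohortSpec(n=1, base=quick),
                              1, library)
        assert len(one) == 1
        with pytest.raises(ValueError):
            simulate_cohort(small, paradigm, CohortSpec(n=-1), 1, library)

    def test_default_cohort_size_is_17(self):
        assert CohortSpec().n == 17

    def test_network_planting_counts(self, protocol, paradigm, library):
        small = AcquisitionProtocol(n_recorded_volumes=20, n_discard=0)
        with_dmn = Scenario(task=False, anticorr=False,
                            networks=("default_mode",), motion_component=False,
                            csf_component=False, motion="none")
        without = Scenario(task=False, anticorr=False, networks=(),
                           motion_component=False, csf_component=False,
                           motion="none")
        spec = CohortSpec(n=6, base=with_dmn, overrides={5: without})
        subs = simulate_cohort(small, paradigm, spec, 3, library)
        n_dmn = sum("default_mode" in gt.networks_present for _, _, gt in subs)
        assert n_dmn == 5

    def test_derived_seeds(self):
        seeds = derive_seeds(123, 17)
        assert len(set(seeds)) == 17
        assert all(0 <= s < 2**31 for s in seeds)
        assert seeds == derive_seeds(123, 17)


def test_head_mask_is_plausible():
    m = head_mask((24, 24, 14))
    assert 1000 < m.sum() < 24 * 24 * 14
    assert not m[0, 0, 0]
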