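"""End-to-end orchestration: fixture generation, pre-processing, ICA-based
denoising, and the two analysis branches (model-based GLM with cluster
inference; model-free ICA with spatio-temporal filtering).

Stage order follows the analysis protocol: discard -> realign -> mask ->
smooth/normalize -> ICA-based denoising -> high-pass -> {GLM, ICA+filters}.
The high-pass filter deliberately runs *after* the ICA-based denoising.
Subjects whose estimated head motion exceeds the exclusion limits are
marked excluded and both analysis branches are skipped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decompose, denoise, glm, preprocess, stfilter
from .core import AcquisitionProtocol, MotionTrace, Volume4D
from .design import BlockParadigm, HRFParams, build_design_matrix, build_paradigm, highpass_filter
from .fixturegen import (CohortSpec, GroundTruth, Scenario, TemplateLibrary,
                         build_template_library, derive_seeds, simulate_subject,
                         write_subject)


@dataclass
class RunConfig:
    """Serializable configuration for one subject run."""

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    scenario: Scenario = field(default_factory=Scenario)
    thresholds: stfilter.Thresholds = field(default_factory=stfilter.Thresholds)
    noise_thresholds: denoise.NoiseThresholds = field(
        default_factory=denoise.NoiseThresholds)
    K: int = decompose.DEFAULT_K
    seed: int = 0
    paradigm_seed: int = 0
    highpass_sigma_s: float = 45.0
    smooth_fwhm_mm: float = 5.0
    grand_mean: float = 10000.0
    run_aroma: bool = True
    run_glm: bool = True
    run_ica: bool = True
    use_thresholded_maps: bool = False
    cluster_z: float = 3.1
    cluster_p: float = 0.01

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol.to_dict(),
            "scenario": self.scenario.to_dict(),
            "thresholds": dataclasses.asdict(self.thresholds),
            "noise_thresholds": {
                "csf_frac": self.noise_thresholds.csf_frac,
                "hfc": self.noise_thresholds.hfc,
                "hyperplane": list(self.noise_thresholds.hyperplane),
            },
            "K": self.K,
            "seed": self.seed,
            "paradigm_seed": self.paradigm_seed,
            "highpass_sigma_s": self.highpass_sigma_s,
            "smooth_fwhm_mm": self.smooth_fwhm_mm,
            "grand_mean": self.grand_mean,
            "run_aroma": self.run_aroma,
            "run_glm": self.run_glm,
            "run_ica": self.run_ica,
            "use_thresholded_maps": self.use_thresholded_maps,
            "cluster_z": self.cluster_z,
            "cluster_p": self.cluster_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["protocol"] = AcquisitionProtocol.from_dict(d["protocol"])
        d["scenario"] = Scenario.from_dict(d["scenario"])
        d["thresholds"] = stfilter.Thresholds(**d["thresholds"])
        nt = d["noise_thresholds"]
        d["noise_thresholds"] = denoise.NoiseThresholds(
            csf_frac=nt["csf_frac"], hfc=nt["hfc"],
            hyperplane=tuple(nt["hyperplane"]))
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SubjectResult:
    excluded: bool
    motion: preprocess.MotionReport | None
    stage_log: list[tuple[str, dict]]
    aroma_table: object | None = None          # pandas DataFrame
    n_noise_components: int | None = None
    components: decompose.ComponentSet | None = None
    filter_report: stfilter.FilterReport | None = None
    cluster_table: glm.ClusterTable | None = None
    stat_maps: dict | None = None
    ground_truth: GroundTruth | None = None
    skipped: list[str] = field(default_factory=list)

    def manifest_dict(self) -> dict:
        d: dict = {
            "excluded": bool(self.excluded),
            "motion": self.motion.to_dict() if self.motion else None,
            "stages": [s for s, _ in self.stage_log],
            "skipped": list(self.skipped),
        }
        if self.n_noise_components is not None:
            d["n_noise_components"] = int(self.n_noise_components)
        if self.components is not None:
            d["ica"] = {
                "K": self.components.K,
                "explained_var": [round(float(v), 10)
                                  for v in self.components.explained_var],
            }
        if self.filter_report is not None:
            d["filters"] = self.filter_report.to_dict()
        if self.cluster_table is not None:
            d["clusters"] = [
                {"id": c.id, "size": c.size_voxels,
                 "p": float(f"{c.p_cluster:.6g}"),
                 "peaks": [[int(p[0]), int(p[1]), int(p[2]),
                            round(float(p[3]), 6), int(p[4])]
                           for p in c.peaks]}
                for c in self.cluster_table.clusters
            ]
        return d

    def manifest_json(self) -> str:
        return json.dumps(self.manifest_dict(), indent=2, sort_keys=True)


def default_paradigm(seed: int = 0) -> BlockParadigm:
    return build_paradigm(seed=seed)


def run_subject(
    config: RunConfig,
    library: TemplateLibrary | None = None,
    raw: Volume4D | None = None,
    ground_truth: GroundTruth | None = None,
    out_dir=None,
) -> SubjectResult:
    """Run the full per-subject pipeline.

    Without a provided ``raw`` volume a synthetic subject is generated from
    the config's scenario and seed.  Returns a :class:`SubjectResult`; when
    the estimated motion exceeds the exclusion limits, downstream branches
    are skipped and the result is marked excluded.
    """
    log: list[tuple[str, dict]] = []
    protocol = config.protocol
    paradigm = default_paradigm(config.paradigm_seed)
    if library is None:
        library = build_template_library(tuple(protocol.grid_shape),
                                         protocol.voxel_mm)
    if raw is None:
        raw, _, ground_truth = simulate_subject(protocol, paradigm,
                                                config.scenario, config.seed,
                                                library)
        log.append(("simulate", {"seed": config.seed}))
    gt = ground_truth

    vol = preprocess.discard_initial(raw, protocol.n_discard)
    log.append(("discard", {"n_discard": protocol.n_discard,
                            "retained": vol.n_volumes}))

    vol, trace = preprocess.realign_translational(vol)
    log.append(("realign", {"reference_index": trace.reference_index}))

    trace, motion_report = preprocess.displacement_and_exclusion(trace)
    log.append(("motion_check", motion_report.to_dict()))
    if motion_report.exclude:
        return SubjectResult(True, motion_report, log, ground_truth=gt,
                             skipped=["aroma", "glm", "ica_filters"])

    mask = preprocess.brain_mask(vol)
    vol.mask = mask
    log.append(("brain_mask", {"n_voxels": int(mask.sum())}))

    vol = preprocess.smooth_and_normalize(vol, config.smooth_fwhm_mm,
                                          config.grand_mean)
    log.append(("smooth_normalize", {"fwhm_mm": config.smooth_fwhm_mm,
                                     "grand_mean": config.grand_mean}))

    # ICA-based denoising (before temporal filtering)
    table = None
    n_flagged = None
    if config.run_aroma:
        comps_noise = decompose.probabilistic_ica(vol, mask, config.K,
                                                  config.seed)
        edge_mask = denoise.build_edge_mask(mask)
        csf_mask = gt.csf_mask if gt is not None else None
        if csf_mask is None:
            from .fixturegen import csf_region
            csf_mask = csf_region(mask.shape)
        feats = denoise.aroma_features(comps_noise, trace, mask, edge_mask,
                                       csf_mask, protocol.tr_seconds)
        flags = denoise.classify_noise(feats, config.noise_thresholds)
        table = denoise.features_table(feats, flags)
        n_flagged = int(flags.sum())
        vol = denoise.nonaggressive_regress(vol, comps_noise, flags)
        log.append(("aroma", {"K": config.K, "n_flagged": n_flagged}))

    # high-pass AFTER the ICA-based denoising
    filtered = highpass_filter(vol.data[mask].T, config.highpass_sigma_s,
                               protocol.tr_seconds)
    data = vol.data.copy()
    data[mask] = filtered.T
    vol = vol.with_data(data)
    log.append(("highpass", {"sigma_s": config.highpass_sigma_s}))

    design = build_design_matrix(paradigm, HRFParams(), protocol)
    result = SubjectResult(False, motion_report, log, aroma_table=table,
                           n_noise_components=n_flagged,
                           ground_truth=gt)
    if not config.run_aroma:
        result.skipped.append("aroma")

    if config.run_glm:
        fit = glm.fit_first_level(vol, design)
        contrasts = glm.default_contrasts()
        stat_maps = {name: glm.contrast_to_z(fit, c)
                     for name, c in contrasts.items()}
        primary = stat_maps["frontal_gt_rest"]
        ctab = glm.grf_cluster_threshold(primary.zstat, mask, fit.residuals,
                                         config.cluster_z, config.cluster_p)
        ctab = glm.local_maxima(primary.zstat, ctab, protocol.voxel_mm,
                                labels=gt.labels if gt is not None else None)
        result.stat_maps = stat_maps
        result.cluster_table = ctab
        log.append(("glm", {"contrasts": len(contrasts),
                            "z_thresh": config.cluster_z,
                            "p_thresh": config.cluster_p}))
    else:
        result.skipped.append("glm")

    if config.run_ica:
        comps = decompose.probabilistic_ica(vol, mask, config.K,
                                            config.seed + 1)
        report = stfilter.make_report(comps, design.expected_response, library,
                                      config.thresholds,
                                      config.use_thresholded_maps)
        result.components = comps
        result.filter_report = report
        log.append(("ica_filters", {"K": config.K,
                                    "n_positive": report.n_positive,
                                    "n_negative": report.n_negative}))
    else:
        result.skipped.append("ica_filters")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "result.json", "w") as fh:
            fh.write(result.manifest_json())
        if result.aroma_table is not None:
            result.aroma_table.to_csv(out_dir / "aroma_features.tsv",
                                      sep="\t", index=False)
        if result.filter_report is not None:
            result.filter_report.save(out_dir)
        if result.cluster_table is not None:
            result.cluster_table.to_frame().to_csv(out_dir / "clusters.tsv",
                                                   sep="\t", index=False)
    return result


@dataclass
class CohortResult:
    results: list[SubjectResult]
    network_table: object        # pandas DataFrame
    subject_table: object
    n_excluded: int


def run_cohort(
    base_config: RunConfig,
    cohort_spec: CohortSpec,
    out_dir=None,
) -> CohortResult:
    """Run the per-subject pipeline over a synthetic cohort and aggregate
    network-presence counts and exclusions."""
    protocol = base_config.protocol
    library = build_template_library(tuple(protocol.grid_shape),
                                     protocol.voxel_mm)
    seeds = derive_seeds(base_config.seed, cohort_spec.n)
    results: list[SubjectResult] = []
    for i in range(cohort_spec.n):
        cfg = dataclasses.replace(base_config,
                                  scenario=cohort_spec.scenario_for(i),
                                  seed=seeds[i])
        sub_out = None if out_dir is None else Path(out_dir) / f"sub-{i+1:02d}"
        results.append(run_subject(cfg, library=library, out_dir=sub_out))
    reports = [r.filter_report for r in results
               if r.filter_report is not None]
    net_table, subj_table = stfilter.cohort_summary(reports, library.names)
    n_excluded = sum(r.excluded for r in results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        net_table.to_csv(out_dir / "network_summary.tsv", sep="\t", index=False)
        subj_table.to_csv(out_dir / "subject_summary.tsv", sep="\t", index=False)
        with open(out_dir / "cohort.json", "w") as fh:
            json.dump({"n": cohort_spec.n, "n_excluded": n_excluded}, fh,
                      indent=2)
    return CohortResult(results, net_table, subj_table, n_excluded)
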