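"""Spatio-temporal filtering of independent components.

Two complementary filters classify single-subject ICA components:

* **temporal filter** — Pearson correlation of each component time course
  with the expected response (all movement blocks convolved with the HRF).
  Components with ``r > 0.4`` (or ``r < -0.4``) and ``p < 0.05`` are
  task-locked (positively or negatively).
* **spatial filter** — in-mask Pearson correlation of each component map
  with each of ten canonical network templates; ``r > 0.4`` marks a match,
  and a network counts as present in a subject when any component matches
  it.

Components passing the temporal filter are not excluded from the spatial
filter; both statuses are recorded per component.  The p-value of the
temporal correlation uses the t transform with T - 2 dof and ignores
temporal autocorrelation of the series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import ComponentSet, mixture_threshold
from .fixturegen import TemplateLibrary


@dataclass(frozen=True)
class Thresholds:
    r_temporal: float = 0.4
    p_temporal: float = 0.05
    r_spatial: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.r_temporal < 1 and 0 < self.r_spatial < 1):
            raise ValueError("correlation thresholds must be in (0, 1)")
        if not (0 < self.p_temporal < 1):
            raise ValueError("p_temporal must be in (0, 1)")


@dataclass
class FilterReport:
    """Per-subject outcome of both filters."""

    temporal: pd.DataFrame       # component, r, p, flag
    matches: pd.DataFrame        # component, template, r  (r > r_spatial)
    best_match: dict[int, tuple[str, float]]
    networks_present: list[str]

    @property
    def n_positive(self) -> int:
        return int((self.temporal["flag"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.temporal["flag"] == "negative").sum())

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.temporal.to_csv(outdir / "temporal_filter.tsv", sep="\t", index=False)
        self.matches.to_csv(outdir / "spatial_filter.tsv", sep="\t", index=False)
        with open(outdir / "filter_report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_dict(self) -> dict:
        return {
            "temporal": self.temporal.to_dict(orient="records"),
            "matches": self.matches.to_dict(orient="records"),
            "best_match": {str(k): [v[0], float(v[1])]
                           for k, v in self.best_match.items()},
            "networks_present": list(self.networks_present),
        }


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and the two-sided p-value from the t transform (n-2 dof)."""
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.linalg.norm(xm) * np.linalg.norm(ym)
    if denom == 0:
        return np.nan, np.nan
    r = float(np.clip(xm @ ym / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def temporal_filter(components: ComponentSet, expected_response: np.ndarray,
                    thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Correlate every component time course with the expected response."""
    expected = np.asarray(expected_response, dtype=np.float64)
    if len(expected) != components.timecourses.shape[0]:
        raise ValueError("expected response length does not match time courses")
    rows = []
    for k in range(components.K):
        tc = components.timecourses[:, k]
        r, p = pearson_with_p(tc, expected)
        if np.isnan(r):
            warnings.warn(f"component {k + 1}: constant time course, r undefined")
            flag = "none"
        elif r > thresholds.r_temporal and p < thresholds.p_temporal:
            flag = "positive"
        elif r < -thresholds.r_temporal and p < thresholds.p_temporal:
            flag = "negative"
        else:
            flag = "none"
        rows.append({"component": k + 1, "r": r, "p": p, "flag": flag})
    return pd.DataFrame(rows)


def spatial_filter(
    components: ComponentSet,
    library: TemplateLibrary,
    thresholds: Thresholds = Thresholds(),
    use_thresholded_maps: bool = False,
) -> tuple[pd.DataFrame, dict[int, tuple[str, float]], list[str]]:
    """Cross-correlate component maps with the ten network templates.

    Returns the match table (all pairs with ``r > r_spatial``), the best
    template per component, and the list of networks present (matched by at
    least one component).  With ``use_thresholded_maps`` the correlation is
    computed on mixture-thresholded maps (map values kept where active,
    zero elsewhere) instead of the raw z maps.
    """
    if components.mask.shape != library.mask.shape:
        raise ValueError("component and template grids differ")
    # data-driven brain masks may differ slightly from the template mask;
    # correlate over the intersection
    common = components.mask & library.mask
    in_comp = common[components.mask]        # select within component voxels
    tmpl = np.stack([m[common] for m in library.maps])  # (10, Vc)
    rows = []
    best: dict[int, tuple[str, float]] = {}
    present: set[str] = set()
    for k in range(components.K):
        m = components.maps[k]
        if use_thresholded_maps:
            thr = mixture_threshold(m)
            m = np.where(thr.active_set, m, 0.0)
        m = m[in_comp]
        rs = np.array([pearson_with_p(m, tmpl[j])[0] for j in range(10)])
        rs = np.nan_to_num(rs, nan=0.0)
        j_best = int(np.argmax(rs))
        best[k + 1] = (library.names[j_best], float(rs[j_best]))
        for j in range(10):
            if rs[j] > thresholds.r_spatial:
                rows.append({"component": k + 1, "template": library.names[j],
                             "r": float(rs[j])})
                present.add(library.names[j])
    matches = pd.DataFrame(rows, columns=["component", "template", "r"])
    present_ordered = [n for n in library.names if n in present]
    return matches, best, present_ordered


def make_report(components: ComponentSet, expected_response: np.ndarray,
                library: TemplateLibrary,
                thresholds: Thresholds = Thresholds(),
                use_thresholded_maps: bool = False) -> FilterReport:
    """Run both filters and assemble the per-subject report."""
    temporal = temporal_filter(components, expected_response, thresholds)
    matches, best, present = spatial_filter(components, library, thresholds,
                                            use_thresholded_maps)
    return FilterReport(temporal, matches, best, present)


def cohort_summary(reports: list[FilterReport],
                   template_names: list[str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level tables: per-network subject counts and per-subject
    temporal hit counts.  Every template name appears even at count 0."""
    if template_names is None:
        from .fixturegen import TEMPLATE_NAMES
        template_names = list(TEMPLATE_NAMES)
    n_total = len(reports)
    net_rows = [
        {
            "network": name,
            "n_subjects_present": sum(name in r.networks_present for r in reports),
            "n_total": n_total,
        }
        for name in template_names
    ]
    subj_rows = [
        {
            "subject": i + 1,
            "n_temporal_positive": r.n_positive,
            "n_temporal_negative": r.n_negative,
            "n_networks_present": len(r.networks_present),
        }
        for i, r in enumerate(reports)
    ]
    cols = ["network", "n_subjects_present", "n_total"]
    subj_cols = ["subject", "n_temporal_positive", "n_temporal_negative",
                 "n_networks_present"]
    return (pd.DataFrame(net_rows, columns=cols),
            pd.DataFrame(subj_rows, columns=subj_cols))
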