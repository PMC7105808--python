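"""ICA-based motion denoising: four-feature component classification and
non-aggressive (partial) component regression.

Each independent component is scored on four features: high-frequency
content of its time course, maximum correlation with an expanded set of
realignment parameters, and the fractions of its spatial weight falling on
the brain edge and in CSF.  Components are flagged as noise by a CSF rule,
a high-frequency rule, or a linear decision boundary in the
(motion-correlation, edge-fraction) plane; flagged components are then
removed by subtracting only their fitted contribution from a joint
regression of every voxel on all component time courses, leaving variance
shared with retained components untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import MotionTrace, Volume4D
from .decompose import ComponentSet


@dataclass(frozen=True)
class AromaFeatures:
    hfc: float
    max_rp_corr: float
    edge_frac: float
    csf_frac: float

    def __post_init__(self) -> None:
        for name in ("hfc", "max_rp_corr", "edge_frac", "csf_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class NoiseThresholds:
    """Classification thresholds.

    Defaults follow the published ICA-AROMA constants: CSF fraction 0.10,
    high-frequency content 0.35, and the trained hyperplane
    ``b0 + b1*max_rp_corr + b2*edge_frac > 0`` with coefficients
    (-19.9751, 9.9513, 24.8333).
    """

    csf_frac: float = 0.10
    hfc: float = 0.35
    hyperplane: tuple[float, float, float] = (
        -19.9751070082159, 9.95127547670627, 24.8333160239175)


def expanded_motion_regressors(trace: MotionTrace) -> np.ndarray:
    """Expanded realignment-parameter set: the 6 parameters, their first
    differences, and one-volume forward/backward shifts (24 columns)."""
    p = trace.params
    d = np.diff(p, axis=0, prepend=p[:1])
    fwd = np.vstack([p[:1], p[:-1]])
    bwd = np.vstack([p[1:], p[-1:]])
    return np.hstack([p, d, fwd, bwd])


def high_frequency_content(timecourse: np.ndarray, tr: float) -> float:
    """Frequency at which cumulative periodogram power reaches half the
    total, as a fraction of the Nyquist frequency."""
    f, pxx = signal.periodogram(timecourse, fs=1.0 / tr, detrend="constant")
    f, pxx = f[1:], pxx[1:]  # drop DC
    total = pxx.sum()
    if total <= 0:
        return 0.0
    cum = np.cumsum(pxx) / total
    idx = int(np.searchsorted(cum, 0.5))
    nyquist = 0.5 / tr
    return float(min(f[min(idx, len(f) - 1)] / nyquist, 1.0))


def aroma_features(
    components: ComponentSet,
    motion_trace: MotionTrace,
    mask: np.ndarray,
    edge_mask: np.ndarray,
    csf_mask: np.ndarray,
    tr: float,
) -> list[AromaFeatures]:
    """Compute the four noise features for every component."""
    mask = np.asarray(mask).astype(bool)
    edge_in = np.asarray(edge_mask).astype(bool)[mask]
    csf_in = np.asarray(csf_mask).astype(bool)[mask]
    if not edge_in.any() or not csf_in.any():
        raise ValueError("edge/CSF masks are empty within the brain mask")
    if components.timecourses.shape[0] < 20:
        raise ValueError("need at least 20 time points")

    rp = expanded_motion_regressors(motion_trace)
    rp_sd = rp.std(axis=0)
    rp_ok = rp[:, rp_sd > 0]
    out: list[AromaFeatures] = []
    for k in range(components.K):
        tc = components.timecourses[:, k]
        hfc = high_frequency_content(tc, tr)
        if rp_ok.shape[1] and tc.std() > 0:
            tc_z = (tc - tc.mean()) / tc.std()
            rp_z = (rp_ok - rp_ok.mean(axis=0)) / rp_ok.std(axis=0)
            corrs = np.abs(tc_z @ rp_z) / len(tc)
            max_rp = float(min(corrs.max(), 1.0))
        else:
            max_rp = 0.0
        absmap = np.abs(components.maps[k])
        denom = absmap.sum()
        edge_frac = float(absmap[edge_in].sum() / denom) if denom > 0 else 0.0
        csf_frac = float(absmap[csf_in].sum() / denom) if denom > 0 else 0.0
        out.append(AromaFeatures(hfc, max_rp, edge_frac, csf_frac))
    return out


def classify_noise(features: list[AromaFeatures],
                   thresholds: NoiseThresholds = NoiseThresholds()
                   ) -> np.ndarray:
    """Per-component noise flags from the four features."""
    b0, b1, b2 = thresholds.hyperplane
    flags = []
    for ft in features:
        noise = (
            ft.csf_frac > thresholds.csf_frac
            or ft.hfc > thresholds.hfc
            or (b0 + b1 * ft.max_rp_corr + b2 * ft.edge_frac) > 0
        )
        flags.append(bool(noise))
    return np.array(flags, dtype=bool)


def features_table(features: list[AromaFeatures], flags: np.ndarray
                   ) -> pd.DataFrame:
    return pd.DataFrame({
        "component": np.arange(1, len(features) + 1),
        "hfc": [f.hfc for f in features],
        "max_rp_corr": [f.max_rp_corr for f in features],
        "edge_frac": [f.edge_frac for f in features],
        "csf_frac": [f.csf_frac for f in features],
        "flagged": flags.astype(bool),
    })


def nonaggressive_regress(vol4d: Volume4D, components: ComponentSet,
                          noise_flags: np.ndarray) -> Volume4D:
    """Partial component regression.

    Every in-mask voxel series is regressed on ALL component time courses
    jointly (plus an intercept); only the fitted contribution of flagged
    components is subtracted.
    """
    flags = np.asarray(noise_flags, dtype=bool)
    if components.K == 0:
        raise ValueError("no components")
    if not flags.any():
        return vol4d.with_data(vol4d.data.copy())
    A = components.timecourses
    X = np.column_stack([np.ones(A.shape[0]), A])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("component time courses are rank deficient")
    mask = components.mask
    Y = vol4d.data[mask].T                           # (T, V)
    beta = np.linalg.solve(X.T @ X, X.T @ Y)         # (K+1, V)
    noise_cols = np.where(flags)[0] + 1              # skip intercept
    cleaned = Y - X[:, noise_cols] @ beta[noise_cols]
    out = vol4d.data.copy()
    out[mask] = cleaned.T
    return vol4d.with_data(out)


def build_edge_mask(mask: np.ndarray) -> np.ndarray:
    """Voxels within one voxel of the mask boundary (the boundary layer and
    one layer inside) plus a one-voxel shell outside."""
    mask = np.asarray(mask).astype(bool)
    inner = mask & ~ndimage.binary_erosion(mask, iterations=2)
    outer = ndimage.binary_dilation(mask) & ~mask
    return inner | outer
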