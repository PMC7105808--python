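"""Prewhitened voxel-wise GLM, contrasts, simplified mixed-effects group
maps, Gaussian-random-field cluster inference, and local-maxima tables.

First-level fitting is OLS followed by voxel-wise AR(1) prewhitening: the
lag-1 autocorrelation of the OLS residuals is estimated per voxel,
spatially smoothed, and data and design are transformed by the AR(1)
whitening filter before the refit.  Contrasts of parameter estimates are
converted to z-statistics by a t-to-z probability transform.  The group map
is a per-voxel one-sample mixed-effects estimate with a method-of-moments
between-subject variance (a deliberate simplification of fully Bayesian
two-stage estimators).  Cluster inference assumes a Gaussian random field:
smoothness (FWHM) is estimated from spatial derivatives of the normalized
residuals and supra-threshold clusters receive corrected p-values from the
expected-cluster-count / Poisson-clumping formula.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .core import Volume4D
from .design import DesignMatrix

FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass
class FirstLevelFit:
    betas: np.ndarray          # (V, P)
    sigma2: np.ndarray         # (V,)
    xtx: np.ndarray            # (V, P, P), whitened X'X per voxel
    dof: float
    columns: list[str]
    mask: np.ndarray
    residuals: np.ndarray      # (T, V), whitened residuals
    rho: np.ndarray            # (V,), smoothed AR(1) coefficients
    voxel_mm: tuple[float, float, float]


@dataclass
class StatMap:
    cope: np.ndarray
    varcope: np.ndarray
    tstat: np.ndarray
    zstat: np.ndarray
    dof: float


@dataclass
class SmoothnessEstimate:
    fwhm_voxels: tuple[float, float, float]
    resel_count: float


@dataclass
class Cluster:
    id: int
    size_voxels: int
    p_cluster: float
    peaks: list = field(default_factory=list)  # (x, y, z, Z, label)


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    label_map: np.ndarray
    smoothness: SmoothnessEstimate

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for (x, y, z, zval, lab) in c.peaks:
                rows.append({"cluster": c.id, "size_voxels": c.size_voxels,
                             "p_cluster": c.p_cluster, "x": x, "y": y, "z": z,
                             "Z": zval, "label": lab})
            if not c.peaks:
                rows.append({"cluster": c.id, "size_voxels": c.size_voxels,
                             "p_cluster": c.p_cluster, "x": np.nan, "y": np.nan,
                             "z": np.nan, "Z": np.nan, "label": None})
        return pd.DataFrame(rows)


def default_contrasts() -> dict[str, np.ndarray]:
    """The nine condition contrasts over (F, H, V) primary regressors.

    Contrast vectors span only the primary EVs; derivative (and intercept)
    columns receive zero weight.
    """
    F, H, V = np.eye(3)
    return {
        "frontal_gt_rest": F,
        "horizontal_gt_rest": H,
        "vertical_gt_rest": V,
        "horizontal_gt_frontal": H - F,
        "vertical_gt_frontal": V - F,
        "frontal_gt_vertical": F - V,
        "horizontal_gt_vertical": H - V,
        "frontal_gt_horizontal": F - H,
        "vertical_gt_horizontal": V - H,
    }


def _ar1_whiten(y: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Apply the AR(1) whitening transform along the first axis.

    ``y`` is (T,) broadcast or (V, T, ...); ``rho`` is (V,).
    """
    out = np.empty_like(y)
    out[..., 0, :] = np.sqrt(1.0 - rho[:, None] ** 2) * y[..., 0, :]
    out[..., 1:, :] = y[..., 1:, :] - rho[:, None, None] * y[..., :-1, :]
    return out


def _smooth_in_mask(values: np.ndarray, mask: np.ndarray, fwhm_vox: float
                    ) -> np.ndarray:
    """Gaussian-smooth a per-voxel scalar field within the mask (normalized
    by the smoothed mask so edges are unbiased); returns in-mask vector."""
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vol = np.zeros(mask.shape)
    vol[mask] = values
    num = ndimage.gaussian_filter(vol, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 1e-8, num / den, 0.0)
    return sm[mask]


def fit_first_level(vol4d: Volume4D, design: DesignMatrix,
                    prewhiten: bool = True,
                    rho_smooth_fwhm_vox: float = 5.0,
                    rho: np.ndarray | None = None) -> FirstLevelFit:
    """Voxel-wise multiple linear regression with AR(1) prewhitening.

    ``rho`` overrides the estimated per-voxel AR(1) coefficients (in-mask
    vector); with ``rho=0`` the whitening transform is the identity (up to
    the first-sample scaling) and the fit reduces to OLS.
    """
    if vol4d.mask is None:
        raise ValueError("fit_first_level requires a masked Volume4D")
    X0 = np.column_stack([design.matrix, np.ones(design.n_timepoints)])
    cols = design.columns + ["intercept"]
    T, P = X0.shape
    if T != vol4d.n_volumes:
        raise ValueError("design length does not match data")
    if T <= P + 2:
        raise ValueError("too few time points for the design")
    if np.linalg.matrix_rank(X0) < P:
        raise ValueError("rank-deficient design matrix")

    mask = vol4d.mask
    Y = vol4d.data[mask]                     # (V, T)
    V = Y.shape[0]

    beta_ols, *_ = np.linalg.lstsq(X0, Y.T, rcond=None)
    resid = Y.T - X0 @ beta_ols              # (T, V)

    if rho is not None:
        rho = np.broadcast_to(np.asarray(rho, dtype=np.float64), (V,)).copy()
    elif prewhiten:
        num = np.einsum("tv,tv->v", resid[1:], resid[:-1])
        den = np.einsum("tv,tv->v", resid, resid)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(den > 0, num / den, 0.0)
        rho = np.clip(rho, -0.95, 0.95)
        rho = np.clip(_smooth_in_mask(rho, mask, rho_smooth_fwhm_vox), -0.95, 0.95)
    else:
        rho = np.zeros(V)

    Yw = _ar1_whiten(Y[:, :, None], rho)[:, :, 0]          # (V, T)
    Xw = _ar1_whiten(np.broadcast_to(X0, (V, T, P)), rho)  # (V, T, P)

    xtx = np.einsum("vtp,vtq->vpq", Xw, Xw)
    xty = np.einsum("vtp,vt->vp", Xw, Yw)
    betas = np.linalg.solve(xtx, xty[..., None])[..., 0]   # (V, P)
    fitted = np.einsum("vtp,vp->vt", Xw, betas)
    res_w = Yw - fitted
    dof = float(T - P)
    sigma2 = np.einsum("vt,vt->v", res_w, res_w) / dof
    return FirstLevelFit(betas, sigma2, xtx, dof, cols, mask, res_w.T, rho,
                         vol4d.voxel_mm)


def t_to_z(tvals: np.ndarray, dof: float) -> np.ndarray:
    """Probability transform of t to standard-normal z, stable in the tails."""
    t = np.asarray(tvals, dtype=np.float64)
    p_tail = stats.t.sf(np.abs(t), dof)
    z = stats.norm.isf(np.clip(p_tail, 1e-300, 1.0))
    return np.sign(t) * z


def contrast_to_z(fit: FirstLevelFit, contrast: np.ndarray) -> StatMap:
    """COPE, VARCOPE, t and z maps for one contrast vector.

    The contrast may span the primary EVs only, the EVs + derivatives, or
    the full design including the intercept; missing entries get weight 0.
    """
    c = np.zeros(len(fit.columns))
    contrast = np.asarray(contrast, dtype=np.float64)
    c[: len(contrast)] = contrast
    cope = fit.betas @ c
    rhs = np.broadcast_to(c[:, None], (fit.xtx.shape[0], len(c), 1))
    xtx_inv_c = np.linalg.solve(fit.xtx, rhs)[..., 0]
    varcope = fit.sigma2 * np.einsum("vp,p->v", xtx_inv_c, c)
    varcope = np.maximum(varcope, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(varcope > 0, cope / np.sqrt(varcope), 0.0)
    inf_t = (varcope == 0) & (cope != 0)
    if inf_t.any():
        warnings.warn("zero varcope with nonzero cope: t set to +/- inf")
        t = np.where(inf_t, np.sign(cope) * np.inf, t)
    z = t_to_z(np.where(np.isfinite(t), t, 0.0), fit.dof)
    z = np.where(np.isfinite(t), z, np.sign(t) * 40.0)

    def unflat(v):
        out = np.zeros(fit.mask.shape)
        out[fit.mask] = v
        return out

    return StatMap(unflat(cope), unflat(varcope), unflat(t), unflat(z), fit.dof)


def group_level(copes: np.ndarray, varcopes: np.ndarray,
                mask: np.ndarray) -> StatMap:
    """One-sample mixed-effects group map.

    Between-subject variance is estimated per voxel by method of moments
    (clamped at zero); subjects are combined with inverse-variance weights
    ``1/(varcope_i + sigma_b^2)`` and the weighted mean is converted to z
    through the t distribution at ``n - 1`` dof.
    """
    copes = np.asarray(copes, dtype=np.float64)
    varcopes = np.asarray(varcopes, dtype=np.float64)
    n = copes.shape[0]
    if n < 3:
        raise ValueError("group_level needs at least 3 subjects")
    mask = np.asarray(mask).astype(bool)
    C = copes[:, mask]                       # (n, V)
    Vc = varcopes[:, mask]
    mean = C.mean(axis=0)
    s2 = C.var(axis=0, ddof=1)
    sigma_b2 = np.maximum(s2 - Vc.mean(axis=0), 0.0)
    w = 1.0 / np.maximum(Vc + sigma_b2[None, :], 1e-30)
    wsum = w.sum(axis=0)
    gcope = (w * C).sum(axis=0) / wsum
    gvar = 1.0 / wsum
    with np.errstate(invalid="ignore", divide="ignore"):
        t = gcope / np.sqrt(gvar)
    t = np.where(np.isfinite(t), t, 0.0)
    z = t_to_z(t, n - 1)

    def unflat(v):
        out = np.zeros(mask.shape)
        out[mask] = v
        return out

    return StatMap(unflat(gcope), unflat(gvar), unflat(t), unflat(z),
                   float(n - 1))


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray
                        ) -> SmoothnessEstimate:
    """Estimate the field smoothness (FWHM per axis, in voxels) from the
    spatial derivatives of variance-normalized residuals.

    For a Gaussian autocorrelation the lag-1 correlation r satisfies
    ``r = exp(-2 ln2 / FWHM^2)``; we invert the observed mean squared
    difference of neighbouring normalized residuals.  FWHM below 1 voxel is
    clamped (with a warning).
    """
    mask = np.asarray(mask).astype(bool)
    T = residuals.shape[0]
    sd = residuals.std(axis=0)
    sd[sd == 0] = 1.0
    norm = residuals / sd[None, :]
    vol = np.zeros((T,) + mask.shape)
    vol[:, mask] = norm
    fwhm = []
    for ax in range(3):
        a = np.moveaxis(vol, 1 + ax, 1)
        m = np.moveaxis(mask, ax, 0)
        pair = m[:-1] & m[1:]
        if not pair.any():
            fwhm.append(1.0)
            continue
        diff = a[:, 1:] - a[:, :-1]
        msd = float((diff[:, pair] ** 2).mean())
        r = 1.0 - msd / 2.0
        if r <= 0:
            f = 1.0
        else:
            f = float(np.sqrt(-2.0 * np.log(2.0) / np.log(r)))
        if f < 1.0:
            warnings.warn("estimated smoothness below one voxel; clamped")
            f = 1.0
        fwhm.append(f)
    resels = float(mask.sum() / np.prod(fwhm))
    return SmoothnessEstimate(tuple(fwhm), resels)


def _grf_cluster_p(size_voxels: int, z_thresh: float, n_mask: int,
                   resels: float) -> float:
    """Corrected cluster p-value under Gaussian-random-field theory.

    Expected cluster count (3D Euler characteristic density) times the
    survival function of cluster extent, Poisson-clumping corrected.
    """
    em = (resels * FOUR_LN2**1.5 / (2.0 * np.pi) ** 2
          * (z_thresh**2 - 1.0) * np.exp(-0.5 * z_thresh**2))
    en = n_mask * stats.norm.sf(z_thresh)
    if em <= 0 or en <= 0:
        return 1.0
    beta = (special.gamma(2.5) * em / en) ** (2.0 / 3.0)
    p_extent = np.exp(-beta * size_voxels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_extent))


def label_clusters(binary: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected component labelling of a binary 3D map."""
    structure = np.ones((3, 3, 3), dtype=bool)
    return ndimage.label(binary, structure=structure)


def grf_cluster_threshold(
    zmap: np.ndarray,
    mask: np.ndarray,
    residuals: np.ndarray,
    z_thresh: float = 3.1,
    p_thresh: float = 0.01,
) -> ClusterTable:
    """Threshold a z map at ``z > z_thresh`` and keep 26-connected clusters
    whose GRF-corrected p-value is below ``p_thresh``."""
    mask = np.asarray(mask).astype(bool)
    sm = estimate_smoothness(residuals, mask)
    binary = (zmap > z_thresh) & mask
    labels, n = label_clusters(binary)
    n_mask = int(mask.sum())
    clusters: list[Cluster] = []
    keep_map = np.zeros_like(labels)
    if n:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1]
        next_id = 1
        for i in order:
            size = int(sizes[i])
            p = _grf_cluster_p(size, z_thresh, n_mask, sm.resel_count)
            if p < p_thresh:
                clusters.append(Cluster(next_id, size, p))
                keep_map[labels == i + 1] = next_id
                next_id += 1
    return ClusterTable(clusters, keep_map, sm)


def _is_local_max(zmap: np.ndarray, idx: tuple[int, int, int],
                  region: np.ndarray) -> bool:
    x, y, z = idx
    v = zmap[x, y, z]
    nx, ny, nz = zmap.shape
    for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
        if dx == dy == dz == 0:
            continue
        a, b, c = x + dx, y + dy, z + dz
        if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
            if region[a, b, c] and zmap[a, b, c] > v:
                return False
    return True


def local_maxima(
    zmap: np.ndarray,
    table: ClusterTable,
    voxel_mm: tuple[float, float, float],
    min_dist_mm: float = 20.0,
    max_n: int = 100,
    labels: np.ndarray | None = None,
) -> ClusterTable:
    """Fill in per-cluster local maxima.

    Within each cluster, voxels that are >= all their 26-neighbours are
    considered, in descending Z (lexicographic voxel-index tie-break); a
    peak within ``min_dist_mm`` of an already accepted peak of the same
    cluster is suppressed.  At most ``max_n`` peaks are reported overall,
    each labelled from the toy anatomical label volume when provided.
    """
    vox = np.asarray(voxel_mm)
    total = 0
    for cl in table.clusters:
        region = table.label_map == cl.id
        coords = np.argwhere(region)
        cands = [tuple(c) for c in coords if _is_local_max(zmap, tuple(c), region)]
        cands.sort(key=lambda c: (-zmap[c], c))
        accepted: list[tuple[int, int, int]] = []
        for c in cands:
            if total >= max_n:
                break
            ok = all(
                np.linalg.norm((np.array(c) - np.array(a)) * vox) >= min_dist_mm
                for a in accepted
            )
            if ok:
                accepted.append(c)
                total += 1
        cl.peaks = [
            (int(c[0]), int(c[1]), int(c[2]), float(zmap[c]),
             int(labels[c]) if labels is not None else 0)
            for c in accepted
        ]
    return table
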