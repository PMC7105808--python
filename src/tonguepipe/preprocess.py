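"""Functional pre-processing: volume discard, translational realignment,
displacement metrics with motion exclusion, brain masking, smoothing and
grand-mean normalization.

Realignment is translation-only: the generator injects pure translations,
so a 6-dof estimator is unnecessary; rotations are carried as zeros and the
displacement formulas remain general (rotational arc on an 80 mm sphere).
The brain mask is a simple intensity threshold plus largest-component rule —
adequate for synthetic heads, not a substitute for proper brain extraction
on real data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MotionTrace, Volume4D

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def discard_initial(vol4d: Volume4D, n_discard: int) -> Volume4D:
    """Drop the first ``n_discard`` volumes (signal equilibration).

    Event onsets defined on the recorded clock must be shifted by
    ``-n_discard * TR`` (see ``BlockParadigm.shifted``).
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= vol4d.n_volumes:
        raise ValueError("cannot discard all volumes")
    return vol4d.with_data(vol4d.data[..., n_discard:])


def _ssd_table(data: np.ndarray, ref: np.ndarray, max_shift: int) -> np.ndarray:
    """SSD between every volume and the reference rolled by each integer
    shift in [-max_shift, max_shift]^3.  Returns (S, S, S, T)."""
    nxyz = data.shape[:3]
    T = data.shape[3]
    V = int(np.prod(nxyz))
    flat = data.reshape(V, T)
    d2 = np.einsum("vt,vt->t", flat, flat)
    S = 2 * max_shift + 1
    table = np.empty((S, S, S, T))
    offsets = range(-max_shift, max_shift + 1)
    for i, j, k in itertools.product(range(S), range(S), range(S)):
        sx, sy, sz = offsets[i], offsets[j], offsets[k]
        ref_s = np.roll(ref, (sx, sy, sz), axis=(0, 1, 2)).ravel()
        cross = ref_s @ flat
        table[i, j, k] = d2 + ref_s @ ref_s - 2.0 * cross
    return table


def _parabolic_offset(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2.0 * f0 + fp
    if denom <= 0:
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def realign_translational(vol4d: Volume4D, max_shift_vox: int = 2,
                          estimator_smooth_vox: float = 1.0
                          ) -> tuple[Volume4D, MotionTrace]:
    """Estimate and undo per-volume rigid translations.

    The reference is the middle volume.  Per-volume 3D translation is found
    by an integer grid search (SSD against the rolled reference) followed by
    per-axis parabolic sub-voxel refinement; volumes are resampled by linear
    interpolation.  Estimation runs on lightly smoothed copies
    (``estimator_smooth_vox`` Gaussian SD) so the SSD surface is locally
    quadratic and the parabolic step unbiased; resampling uses the original
    data.  Estimated parameters are reported in mm (rotations 0).
    """
    if vol4d.n_volumes < 2:
        raise ValueError("need at least 2 volumes to realign")
    ref_idx = vol4d.n_volumes // 2
    ref = vol4d.data[..., ref_idx]
    if not np.any(ref):
        raise ValueError("reference volume is all zero")

    if estimator_smooth_vox > 0:
        sm = ndimage.gaussian_filter(
            vol4d.data, (estimator_smooth_vox,) * 3 + (0.0,))
    else:
        sm = vol4d.data
    table = _ssd_table(sm, sm[..., ref_idx], max_shift_vox)
    S = 2 * max_shift_vox + 1
    T = vol4d.n_volumes
    est_vox = np.zeros((T, 3))
    for t in range(T):
        f = table[..., t]
        b = np.unravel_index(np.argmin(f), f.shape)
        est = np.array(b, dtype=float) - max_shift_vox
        if f[b] > 0:  # skip refinement for an exact match (self-alignment)
            for ax in range(3):
                if 0 < b[ax] < S - 1:
                    lo = list(b); hi = list(b)
                    lo[ax] -= 1; hi[ax] += 1
                    est[ax] += _parabolic_offset(f[tuple(lo)], f[b], f[tuple(hi)])
        est_vox[t] = est

    out = np.empty_like(vol4d.data)
    for t in range(T):
        if np.all(est_vox[t] == 0):
            out[..., t] = vol4d.data[..., t]
        else:
            out[..., t] = ndimage.shift(vol4d.data[..., t], -est_vox[t],
                                        order=1, mode="constant")
    params = np.zeros((T, 6))
    params[:, 3:6] = est_vox * np.asarray(vol4d.voxel_mm)[None, :]
    trace = MotionTrace(params, reference_index=ref_idx)
    return vol4d.with_data(out), trace


@dataclass
class MotionReport:
    exclude: bool
    abs_mean: float
    rel_mean: float
    abs_disp: np.ndarray
    rel_disp: np.ndarray

    def to_dict(self) -> dict:
        return {
            "exclude": bool(self.exclude),
            "abs_mean_mm": float(self.abs_mean),
            "rel_mean_mm": float(self.rel_mean),
            "abs_max_mm": float(self.abs_disp.max()),
            "rel_max_mm": float(self.rel_disp.max()) if len(self.rel_disp) else 0.0,
        }


def _param_displacement(delta: np.ndarray, sphere_mm: float) -> np.ndarray:
    """Displacement magnitude of a 6-parameter difference: translations plus
    rotational arc (theta * radius per axis), combined in quadrature."""
    rot = delta[..., 0:3] * sphere_mm
    trans = delta[..., 3:6]
    return np.sqrt((trans**2).sum(axis=-1) + (rot**2).sum(axis=-1))


def displacement_and_exclusion(
    trace: MotionTrace,
    rel_limit_mm: float = 1.0,
    abs_limit_mm: float = 3.0,
    sphere_mm: float = 80.0,
) -> tuple[MotionTrace, MotionReport]:
    """Fill in absolute/relative displacement series and decide exclusion.

    Absolute displacement is relative to the reference volume; relative
    displacement between consecutive volumes.  A subject is excluded when
    the mean relative displacement is >= ``rel_limit_mm`` (1 mm) or the mean
    absolute displacement is >= ``abs_limit_mm`` (3 mm).
    """
    if trace.n_volumes == 0:
        raise ValueError("empty motion trace")
    p = trace.params
    ref = p[trace.reference_index]
    abs_disp = _param_displacement(p - ref[None, :], sphere_mm)
    rel_disp = _param_displacement(np.diff(p, axis=0), sphere_mm)
    abs_mean = float(abs_disp.mean())
    rel_mean = float(rel_disp.mean()) if len(rel_disp) else 0.0
    trace.abs_disp, trace.rel_disp = abs_disp, rel_disp
    trace.abs_mean, trace.rel_mean = abs_mean, rel_mean
    exclude = rel_mean >= rel_limit_mm or abs_mean >= abs_limit_mm
    return trace, MotionReport(exclude, abs_mean, rel_mean, abs_disp, rel_disp)


def brain_mask(vol4d: Volume4D, threshold_frac: float = 0.25) -> np.ndarray:
    """Intensity-based functional brain mask.

    Threshold the temporal-mean volume at ``threshold_frac`` of its robust
    (98th percentile) maximum, keep the largest 6-connected component, and
    fill holes.
    """
    mean_vol = vol4d.data.mean(axis=3)
    robust_max = np.percentile(mean_vol, 98)
    if robust_max <= 0 or np.ptp(mean_vol) == 0:
        raise ValueError("mean volume is degenerate; cannot mask")
    binary = mean_vol > threshold_frac * robust_max
    if not binary.any():
        raise ValueError("empty mask after thresholding")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        raise ValueError("empty mask after thresholding")
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def smooth_and_normalize(
    vol4d: Volume4D,
    fwhm_mm: float = 5.0,
    target_grand_mean: float = 10000.0,
) -> Volume4D:
    """Per-volume Gaussian smoothing followed by grand-mean scaling.

    The whole 4D set is rescaled by one multiplicative factor so its
    in-mask grand mean equals ``target_grand_mean``.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if vol4d.mask is None:
        raise ValueError("smooth_and_normalize requires a mask")
    data = vol4d.data
    if fwhm_mm > 0:
        sigma_vox = tuple(fwhm_mm / (FWHM_TO_SIGMA * v) for v in vol4d.voxel_mm)
        data = ndimage.gaussian_filter(data, sigma=sigma_vox + (0.0,))
    grand = data[vol4d.mask].mean()
    if abs(grand) < 1e-12:
        raise ValueError("zero in-mask grand mean; cannot normalize")
    return vol4d.with_data(data * (target_grand_mean / grand))
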