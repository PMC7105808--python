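"""Single-subject probabilistic spatial ICA and Gaussian-mixture map
thresholding.

The 4D series is decomposed into K spatially independent maps with
associated time courses (melodic-style spatial ICA): voxel-wise demeaning,
PCA whitening to K dimensions, then deflationary fixed-point ICA with a
tanh contrast, run from several random initializations with the most
non-Gaussian converged solution kept.  Time courses are variance-normalized;
spatial maps are scaled to z-like units by the residual noise SD, sign-fixed
so the strongest voxel is positive, and ordered by explained variance.

Thresholding of a spatial map fits a two-class Gaussian mixture
(background + active) to map intensities and keeps voxels whose posterior
probability of the higher-mean class exceeds 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .core import Volume4D

DEFAULT_K = 20


@dataclass
class ComponentSet:
    """K spatial maps over in-mask voxels plus K time courses."""

    maps: np.ndarray          # (K, V), z-scaled
    timecourses: np.ndarray   # (T, K), unit sample variance per column
    explained_var: np.ndarray  # (K,)
    K: int
    seed: int
    mask: np.ndarray          # 3D bool, to unflatten maps

    def map_volume(self, k: int) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.maps[k]
        return out

    def save(self, outdir, voxel_mm=(3.0, 3.0, 3.0)) -> None:
        import nibabel as nib
        import pandas as pd
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vols = np.stack([self.map_volume(k) for k in range(self.K)], axis=-1)
        aff = np.diag(list(voxel_mm) + [1.0])
        nib.save(nib.Nifti1Image(vols.astype(np.float32), aff),
                 str(outdir / "melodic_like_IC.nii.gz"))
        pd.DataFrame(self.timecourses,
                     columns=[f"IC{k+1}" for k in range(self.K)]).to_csv(
            outdir / "timecourses.tsv", sep="\t", index=False)


# E[log cosh(nu)] for standard-normal nu; reference point of the negentropy
# proxy used to rank restarts
_LOGCOSH_GAUSS = 0.374567207491438


def _negentropy_proxy(S: np.ndarray) -> float:
    """Sum over components of the squared logcosh deviation from
    Gaussianity; higher means a more non-Gaussian (better separated)
    decomposition."""
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    g = np.log(np.cosh(S / sd)).mean(axis=0)
    return float(((g - _LOGCOSH_GAUSS) ** 2).sum())


def probabilistic_ica(vol4d: Volume4D, mask: np.ndarray, K: int = DEFAULT_K,
                      seed: int = 0, max_restarts: int = 5,
                      n_init: int = 4) -> ComponentSet:
    """Decompose a 4D series into K independent spatial components.

    The fixed-point iteration is run from ``n_init`` random initializations
    and the most non-Gaussian converged solution (logcosh negentropy proxy)
    is kept — deflationary ICA can land in local optima that leave sources
    mixed.  Each initialization is restarted with fresh seeds (up to
    ``max_restarts``) if it does not converge.
    """
    mask = np.asarray(mask).astype(bool)
    V = int(mask.sum())
    T = vol4d.n_volumes
    if K > min(T, V) - 1:
        raise ValueError(f"K={K} too large for T={T}, V={V}")
    if V < 10 * K:
        raise ValueError(f"need at least 10*K in-mask voxels (have {V})")

    X = vol4d.data[mask]                     # (V, T)
    X = X - X.mean(axis=1, keepdims=True)    # voxel-wise demean

    best: tuple[float, object, np.ndarray] | None = None
    last_err: Exception | None = None
    for init in range(n_init):
        for attempt in range(max_restarts):
            # deflation (one-unit fixed point + Gram-Schmidt decorrelation):
            # converges component-by-component even when the trailing noise
            # subspace is rotation-degenerate, where the symmetric update's
            # global convergence criterion never settles
            ica = FastICA(n_components=K, fun="logcosh", max_iter=500,
                          tol=1e-6, whiten="unit-variance",
                          algorithm="deflation",
                          random_state=seed + 7919 * init + 1000 * attempt)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    S = ica.fit_transform(X)     # (V, K) spatial sources
                except Exception as err:  # pragma: no cover
                    last_err = err
                    continue
            if not any(issubclass(w.category, ConvergenceWarning)
                       for w in caught):
                score = _negentropy_proxy(S)
                if best is None or score > best[0]:
                    best = (score, ica, S)
                break
    if best is None:
        raise RuntimeError(
            f"FastICA failed to converge after {max_restarts} restarts"
            + (f": {last_err}" if last_err else ""))
    _, ica, S = best

    A = ica.mixing_                          # (T, K) time courses
    # absorb scale into maps so each time course has unit sample variance
    sd = A.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    A = A / sd
    M = (S * sd).T                           # (K, V)

    # FastICA centres each time point across voxels; add that back for the
    # reconstruction residual of the voxel-demeaned data
    resid = X.T - A @ M - ica.mean_[:, None]
    sigma = max(float(resid.std()), 1e-12)
    Z = M / sigma

    # sign convention: orient each component so its extreme tail is
    # positive (mean of the top-1%-|z| voxels); activation-positive, and
    # robust both to broad map offsets (which defeat skewness) and to
    # single noise voxels (which defeat a lone-peak rule)
    n_tail = max(1, Z.shape[1] // 100)
    for k in range(K):
        tail = np.argsort(np.abs(Z[k]))[-n_tail:]
        if Z[k, tail].mean() < 0:
            Z[k] = -Z[k]
            A[:, k] = -A[:, k]

    total = float((X**2).sum())
    ev = np.array([float((A[:, k] @ A[:, k]) * (M[k] @ M[k])) for k in range(K)])
    ev = ev / max(total, 1e-300)
    order = np.argsort(ev)[::-1]
    return ComponentSet(maps=Z[order], timecourses=A[:, order],
                        explained_var=ev[order], K=K, seed=seed, mask=mask)


@dataclass
class MixtureThresholdedMap:
    posterior: np.ndarray   # P(active class) per voxel, in [0, 1]
    active_set: np.ndarray  # posterior > 0.5


def mixture_threshold(map_values: np.ndarray, seed: int = 0,
                      max_iter: int = 200, tol: float = 1e-6
                      ) -> MixtureThresholdedMap:
    """Two-class Gaussian-mixture thresholding of a spatial map.

    Fits background + active Gaussians by EM (k-means init); voxels are
    active where the posterior of the higher-mean class exceeds 0.5.
    Degenerate fits (a vanishing class weight, or an essentially constant
    map) yield an empty active set.
    """
    x = np.asarray(map_values, dtype=np.float64).ravel()
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("constant map cannot be mixture-thresholded")
    scale = max(np.abs(x).max(), 1.0)
    if np.ptp(x) < 1e-8 * scale:  # near-constant: no meaningful split
        return MixtureThresholdedMap(np.zeros_like(x), np.zeros_like(x, dtype=bool))

    gmm = GaussianMixture(n_components=2, covariance_type="full",
                          max_iter=max_iter, tol=tol, init_params="kmeans",
                          reg_covar=1e-10, random_state=seed)
    gmm.fit(x[:, None])
    hi = int(np.argmax(gmm.means_.ravel()))
    if gmm.weights_[hi] < 1e-3 or gmm.weights_[1 - hi] < 1e-3:
        return MixtureThresholdedMap(np.zeros_like(x), np.zeros_like(x, dtype=bool))
    posterior = gmm.predict_proba(x[:, None])[:, hi]
    return MixtureThresholdedMap(posterior, posterior > 0.5)
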