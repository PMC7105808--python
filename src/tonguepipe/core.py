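"""Core data containers shared across pipeline stages.

The unit of data exchanged between stages is a :class:`Volume4D`: a 4D
intensity grid (x, y, z, t) with voxel size in mm, repetition time in
seconds, and an optional binary brain mask.  Rigid head-motion parameters
travel as a :class:`MotionTrace` (FSL ``.par`` ordering: three rotations in
radians, then three translations in mm, one row per volume).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scan-timing and grid bookkeeping for one functional run.

    Defaults describe a 3 T echo-planar acquisition with TR 1.8 s in which
    308 volumes are recorded and the first 4 are discarded for signal
    equilibration, leaving 304 analysed volumes.
    """

    tr_seconds: float = 1.8
    n_recorded_volumes: int = 308
    n_discard: int = 4
    grid_shape: tuple[int, int, int] = (24, 24, 14)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_recorded_volumes < 1:
            raise ValueError("n_recorded_volumes must be positive")
        if not (0 <= self.n_discard < self.n_recorded_volumes):
            raise ValueError("n_discard must be in [0, n_recorded_volumes)")
        if len(self.grid_shape) != 3 or any(int(d) < 4 for d in self.grid_shape):
            raise ValueError("grid_shape must be three dims, all >= 4")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be three positive reals")

    @property
    def n_retained(self) -> int:
        return self.n_recorded_volumes - self.n_discard

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_mm"] = list(self.voxel_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        d["grid_shape"] = tuple(int(x) for x in d["grid_shape"])
        d["voxel_mm"] = tuple(float(x) for x in d["voxel_mm"])
        return cls(**d)


@dataclass
class Volume4D:
    """A 4D functional image: ``data[x, y, z, t]`` plus grid metadata."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    tr_seconds: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match spatial grid")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return the in-mask voxel series as a (T, V) matrix."""
        m = mask if mask is not None else self.mask
        if m is None:
            raise ValueError("no mask available")
        return self.data[m.astype(bool)].T.copy()

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(data, self.voxel_mm, self.tr_seconds, self.mask)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_mm) + [1.0])
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header.set_zooms(tuple(self.voxel_mm) + (self.tr_seconds,))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, mask: np.ndarray | None = None) -> "Volume4D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(np.asarray(img.dataobj, dtype=np.float64),
                   tuple(float(z) for z in zooms[:3]), tr, mask)


def save_mask(mask: np.ndarray, voxel_mm, path) -> None:
    aff = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), aff), str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


@dataclass
class MotionTrace:
    """Per-volume rigid parameters and derived displacement series.

    ``params`` has one row per volume: three rotations (rad) followed by
    three translations (mm).  Displacement series are filled in by
    ``preprocess.displacement_and_exclusion`` using the 80 mm-sphere
    convention for rotational arc length.
    """

    params: np.ndarray
    reference_index: int
    abs_disp: np.ndarray | None = None
    rel_disp: np.ndarray | None = None
    abs_mean: float | None = None
    rel_mean: float | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("params must be (T, 6)")
        if not (0 <= self.reference_index < self.params.shape[0]):
            raise ValueError("reference_index out of range")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, 3:6]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 0:3]

    def save_tsv(self, path) -> None:
        np.savetxt(str(path), self.params, fmt="%.8f", delimiter="\t")

    @classmethod
    def load_tsv(cls, path, reference_index: int = 0) -> "MotionTrace":
        params = np.loadtxt(str(path), delimiter="\t", ndmin=2)
        return cls(params, reference_index)
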