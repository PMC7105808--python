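"""Synthetic 4D-fMRI subjects and cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is verifiable without scanner data:

* a bright ellipsoidal "head" on a dark background (for masking and
  realignment),
* planted spatial components: a bilateral sensorimotor component whose time
  course is task-locked at a controlled correlation with the expected
  response, an occipital component anti-correlated with it, canonical
  network-like components with band-limited (0.01-0.1 Hz) structured time
  courses at a controlled spatial correlation with a template, an edge-ring
  motion component, and a central CSF component,
* voxel-wise AR(1) noise (the innovations are white),
* injected per-volume rigid translations (piecewise-constant with spikes).

A synthetic ten-network template library stands in for canonical
resting-state network maps; users can substitute their own template NIfTI
files via :func:`load_template_library`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import AcquisitionProtocol, MotionTrace, Volume4D, save_mask
from .design import BlockParadigm, HRFParams, build_design_matrix, build_paradigm

TEMPLATE_NAMES = (
    "visual_medial",
    "visual_pole",
    "visual_lateral",
    "default_mode",
    "cerebellum_stub",
    "superior_sensorimotor",
    "auditory",
    "executive_control",
    "left_frontoparietal",
    "right_frontoparietal",
)

# blobs per template; every network is distributed (>= 2 foci) so that a
# compact noise fluctuation cannot dominate its spatial correlation
_BLOBS_PER_TEMPLATE = {
    "visual_medial": 2,
    "visual_pole": 2,
    "visual_lateral": 2,
    "default_mode": 3,
    "cerebellum_stub": 2,
    "superior_sensorimotor": 2,
    "auditory": 2,
    "executive_control": 2,
    "left_frontoparietal": 2,
    "right_frontoparietal": 2,
}

_BLOB_SIGMA_VOX = 1.5


def head_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal head mask centred in the grid."""
    nx, ny, nz = grid_shape
    c = (np.array(grid_shape) - 1) / 2.0
    semi = np.array([0.44 * nx, 0.44 * ny, 0.43 * nz])
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r2 = (((x - c[0]) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2
          + ((z - c[2]) / semi[2]) ** 2)
    return r2 <= 1.0


def _normalized_radius(points: np.ndarray, grid_shape) -> np.ndarray:
    c = (np.array(grid_shape) - 1) / 2.0
    semi = np.array([0.44 * grid_shape[0], 0.44 * grid_shape[1], 0.43 * grid_shape[2]])
    return np.sqrt((((points - c) / semi) ** 2).sum(axis=1))


def _reserved_centers(grid_shape) -> dict[str, np.ndarray]:
    """Blob centres reserved for non-template plants (task, occipital, CSF)."""
    c = (np.array(grid_shape) - 1) / 2.0
    ax = np.array([0.44 * grid_shape[0], 0.44 * grid_shape[1], 0.43 * grid_shape[2]])
    return {
        "task_left": c + np.array([0.58 * ax[0], 0.05 * ax[1], 0.20 * ax[2]]),
        "task_right": c + np.array([-0.58 * ax[0], 0.05 * ax[1], 0.20 * ax[2]]),
        "occ_left": c + np.array([0.28 * ax[0], -0.62 * ax[1], -0.10 * ax[2]]),
        "occ_right": c + np.array([-0.28 * ax[0], -0.62 * ax[1], -0.10 * ax[2]]),
        "csf": c.astype(float),
    }


def _farthest_point_centers(grid_shape, n_needed: int, reserved: np.ndarray,
                            margin: float = 0.70) -> np.ndarray:
    """Greedy farthest-point sampling of blob centres inside the head,
    keeping clear of the reserved centres.

    ``margin`` (fraction of the head semi-axes) keeps template blobs away
    from the brain edge, where motion artifacts concentrate.
    """
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1).astype(float)
    pts = pts[_normalized_radius(pts, grid_shape) <= margin]
    if len(pts) < n_needed:
        raise ValueError("grid too small to place template blobs")
    mind = np.full(len(pts), np.inf)
    for r in reserved:
        mind = np.minimum(mind, np.sqrt(((pts - r) ** 2).sum(axis=1)))
    chosen: list[np.ndarray] = []
    for _ in range(n_needed):
        i = int(np.argmax(mind))
        chosen.append(pts[i])
        mind = np.minimum(mind, np.sqrt(((pts - pts[i]) ** 2).sum(axis=1)))
    return np.array(chosen)


def _gaussian_blob(grid_shape, center: np.ndarray, sigma_vox: float) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return np.exp(-d2 / (2.0 * sigma_vox**2))


@dataclass
class TemplateLibrary:
    """Ten named network template maps on the analysis grid."""

    names: list[str]
    maps: np.ndarray  # (10, nx, ny, nz)
    mask: np.ndarray
    voxel_mm: tuple[float, float, float]
    peak_centers: np.ndarray | None = None  # (10, 3), primary blob per template

    def __post_init__(self) -> None:
        if len(self.names) != 10 or self.maps.shape[0] != 10:
            raise ValueError("a template library has exactly 10 entries")
        self.mask = np.asarray(self.mask).astype(bool)

    def in_mask_matrix(self) -> np.ndarray:
        """Templates as a (10, V) matrix over in-mask voxels."""
        return self.maps[:, self.mask]

    def correlation_matrix(self) -> np.ndarray:
        m = self.in_mask_matrix()
        return np.corrcoef(m)

    def label_volume(self, radius_vox: float = 2.0) -> np.ndarray:
        """Toy anatomical label volume: label i+1 around template i's peak."""
        if self.peak_centers is None:
            raise ValueError("library has no peak centres")
        labels = np.zeros(self.mask.shape, dtype=np.int16)
        nx, ny, nz = self.mask.shape
        x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                              indexing="ij")
        for i, c in enumerate(self.peak_centers):
            d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
            labels[(d2 <= radius_vox**2) & self.mask] = i + 1
        return labels

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aff = np.diag(list(self.voxel_mm) + [1.0])
        for name, m in zip(self.names, self.maps):
            nib.save(nib.Nifti1Image(m.astype(np.float32), aff),
                     str(outdir / f"template_{name}.nii.gz"))
        save_mask(self.mask, self.voxel_mm, outdir / "template_mask.nii.gz")


def build_template_library(
    grid_shape: tuple[int, int, int] = (24, 24, 14),
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 7,
    max_pairwise_r: float = 0.3,
) -> TemplateLibrary:
    """Build the synthetic ten-network template library.

    Templates are sums of Gaussian blobs at well-separated centres inside an
    ellipsoidal head mask, zero outside.  Construction fails if the grid is
    too small to keep all pairwise in-mask correlations below
    ``max_pairwise_r``.
    """
    rng = np.random.default_rng(seed)
    mask = head_mask(grid_shape)
    reserved = np.array(list(_reserved_centers(grid_shape).values()))
    n_blobs = sum(_BLOBS_PER_TEMPLATE[n] for n in TEMPLATE_NAMES)
    centers = _farthest_point_centers(grid_shape, n_blobs, reserved)

    maps = np.zeros((10,) + tuple(grid_shape))
    peak_centers = np.zeros((10, 3))
    idx = 0
    for i, name in enumerate(TEMPLATE_NAMES):
        k = _BLOBS_PER_TEMPLATE[name]
        for j in range(k):
            amp = rng.uniform(0.8, 1.2)
            maps[i] += amp * _gaussian_blob(grid_shape, centers[idx], _BLOB_SIGMA_VOX)
            if j == 0:
                peak_centers[i] = centers[idx]
            idx += 1
        maps[i][~mask] = 0.0

    lib = TemplateLibrary(list(TEMPLATE_NAMES), maps, mask, tuple(voxel_mm),
                          peak_centers)
    corr = lib.correlation_matrix()
    off = np.abs(corr - np.eye(10))
    if off.max() >= max_pairwise_r:
        raise ValueError(
            f"grid too small: max pairwise template correlation {off.max():.3f} "
            f">= {max_pairwise_r}")
    return lib


def load_template_library(paths: list, mask_path, names: list[str] | None = None
                          ) -> TemplateLibrary:
    """Import user-supplied template NIfTI maps (exactly ten) plus a mask."""
    if len(paths) != 10:
        raise ValueError("exactly 10 template maps are required")
    imgs = [nib.load(str(p)) for p in paths]
    maps = np.stack([np.asarray(i.dataobj, dtype=np.float64) for i in imgs])
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    zooms = imgs[0].header.get_zooms()[:3]
    if names is None:
        names = [Path(p).name.split(".")[0] for p in paths]
    return TemplateLibrary(list(names), maps, mask, tuple(float(z) for z in zooms))


@dataclass
class PlantedComponent:
    """Ground-truth source: spatial weight map x time course."""

    name: str
    map: np.ndarray
    timecourse: np.ndarray  # one sample per recorded volume
    timecourse_kind: str  # task_locked | network_structured | motion_spike | csf
    amplitude: float
    target_temporal_r: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.map)):
            raise ValueError("map must be finite")


@dataclass
class GroundTruth:
    planted: list[PlantedComponent]
    motion_truth: np.ndarray  # (T_recorded, 3) injected translations, mm
    labels: np.ndarray  # toy anatomical label volume
    networks_present: list[str]
    head_mask: np.ndarray
    csf_mask: np.ndarray

    def manifest_dict(self) -> dict:
        return {
            "planted": [
                {
                    "name": p.name,
                    "kind": p.timecourse_kind,
                    "amplitude": p.amplitude,
                    "target_temporal_r": p.target_temporal_r,
                }
                for p in self.planted
            ],
            "networks_present": list(self.networks_present),
            "motion_max_abs_mm": float(np.abs(self.motion_truth).max()),
            "n_volumes": int(self.motion_truth.shape[0]),
        }


@dataclass
class Scenario:
    """What to plant in one synthetic subject.

    Amplitudes are in intensity units per unit-variance time course; the
    AR(1) noise innovation SD is ``noise_sd`` (lag-1 autocorrelation
    ``ar1``).  ``motion`` is ``"none"``, ``"mild"``, ``"excessive"``, or an
    explicit (T, 3) array of translations in mm.
    """

    task: bool = True
    task_bilateral: bool = True
    task_target_r: float = 0.7
    task_amplitude: float = 4.0
    anticorr: bool = True
    anticorr_target_r: float = -0.6
    anticorr_amplitude: float = 3.0
    networks: tuple[str, ...] = ("default_mode", "left_frontoparietal")
    network_map_r: float = 0.6
    network_amplitude: float = 3.0
    motion_component: bool = True
    motion_amplitude: float = 4.0
    csf_component: bool = True
    csf_amplitude: float = 3.0
    noise_sd: float = 1.0
    ar1: float = 0.3
    head_intensity: float = 100.0
    motion: object = "mild"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["networks"] = list(self.networks)
        if isinstance(d["motion"], np.ndarray):
            d["motion"] = d["motion"].tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["networks"] = tuple(d.get("networks", ()))
        if isinstance(d.get("motion"), list):
            d["motion"] = np.asarray(d["motion"], dtype=float)
        return cls(**d)


def _unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a constant series")
    return v / n


def mix_to_target_correlation(reference: np.ndarray, noise: np.ndarray,
                              target_r: float) -> np.ndarray:
    """Return a unit-variance series whose Pearson correlation with
    ``reference`` is exactly ``target_r`` (noise is orthogonalized first)."""
    ref_u = _unit(reference)
    g = noise - noise.mean()
    g = g - (g @ ref_u) * ref_u
    g_u = g / np.linalg.norm(g)
    mixed = target_r * ref_u + np.sqrt(1.0 - target_r**2) * g_u
    return mixed * np.sqrt(len(mixed))  # unit sample variance


def _bandlimited_series(rng: np.random.Generator, n: int, tr: float,
                        f_lo: float = 0.01, f_hi: float = 0.1) -> np.ndarray:
    """Band-limited Gaussian series, unit variance."""
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate band-limited series (n too small?)")
    return (x - x.mean()) / sd


def edge_ring(mask: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Inner shell of the mask (voxels within ``thickness`` of the edge)."""
    return mask & ~ndimage.binary_erosion(mask, iterations=thickness)


def csf_region(grid_shape, radius_vox: float = 2.2) -> np.ndarray:
    c = (np.array(grid_shape) - 1) / 2.0
    x, y, z = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    return d2 <= radius_vox**2


def motion_schedule(kind, n_volumes: int, rng: np.random.Generator) -> np.ndarray:
    """Injected per-volume translations (mm): piecewise-constant segments
    with occasional spikes."""
    if isinstance(kind, np.ndarray):
        if kind.shape != (n_volumes, 3):
            raise ValueError("explicit motion must be (T, 3)")
        return kind.astype(float)
    out = np.zeros((n_volumes, 3))
    if kind in (None, "none"):
        return out
    if kind == "mild":
        seg_len, step_sd, spike = 60, 0.15, 0.8
    elif kind == "excessive":
        # alternating large jumps: relative displacement ~1.2 mm per step
        half = np.array([0.8, 0.55, 0.65])
        out[1::2] = half
        return out
    else:
        raise ValueError(f"unknown motion schedule {kind!r}")
    pos = np.zeros(3)
    for start in range(0, n_volumes, seg_len):
        pos = pos + rng.normal(0.0, step_sd, size=3)
        out[start:start + seg_len] = pos
    for t in rng.choice(n_volumes, size=2, replace=False):
        out[t] = out[t] + rng.choice([-1.0, 1.0], size=3) * spike
    return out


def _random_blob_field(rng: np.random.Generator, grid_shape, n_blobs: int = 8,
                       sigma_vox: float = _BLOB_SIGMA_VOX,
                       margin: float = 0.72) -> np.ndarray:
    """Sum of Gaussian blobs at random interior positions: a sparse,
    super-Gaussian spatial field (the kind of structure spatial ICA can
    isolate), used as the off-template part of planted network maps."""
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1).astype(float)
    pts = pts[_normalized_radius(pts, grid_shape) <= margin]
    centers = pts[rng.choice(len(pts), size=n_blobs, replace=False)]
    field = np.zeros(grid_shape)
    for c in centers:
        field += rng.uniform(0.7, 1.3) * _gaussian_blob(grid_shape, c, sigma_vox)
    return field


def _network_map(library: "TemplateLibrary", name: str, target_r: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Non-negative 3D map whose in-mask Pearson correlation with the named
    template is exactly ``target_r`` (and ~0 with every other template).

    The off-template structure is itself a sparse blob field, so the plant
    stays spatially super-Gaussian (like a real network map) rather than
    dissolving into a Gaussian texture that ICA cannot separate; it is
    orthogonalized against the whole template library so the plant cannot
    spuriously resemble another network.
    """
    mask = library.mask
    tau_u = _unit(library.maps[library.names.index(name)][mask])
    g = _random_blob_field(rng, mask.shape)[mask]
    g = g - g.mean()
    for other in library.maps:
        o_u = _unit(other[mask])
        g = g - (g @ o_u) * o_u
    g = g - (g @ tau_u) * tau_u
    g_u = g / np.linalg.norm(g)
    m = target_r * tau_u + np.sqrt(1.0 - target_r**2) * g_u
    m = m - m.min()   # additive offset keeps the correlation unchanged...
    m = m / m.max()   # ...as does scaling; unit peak weight like all plants
    out = np.zeros(mask.shape)
    out[mask] = m
    return out


def _ar1_noise(rng: np.random.Generator, n_voxels: int, n_t: int,
               sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series per voxel, (V, T)."""
    out = np.empty((n_voxels, n_t))
    out[:, 0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2), size=n_voxels)
    innov = rng.normal(0.0, sd, size=(n_voxels, n_t - 1))
    for t in range(1, n_t):
        out[:, t] = phi * out[:, t - 1] + innov[:, t - 1]
    return out


def simulate_subject(
    protocol: AcquisitionProtocol,
    paradigm: BlockParadigm,
    scenario: Scenario,
    seed: int,
    library: TemplateLibrary | None = None,
) -> tuple[Volume4D, MotionTrace, GroundTruth]:
    """Generate one synthetic subject.

    Data are ``sum_k amplitude_k * map_k (x) timecourse_k`` over a bright
    head baseline, plus AR(1) noise in the head, then resampled under the
    injected per-volume translations.  The paradigm clock starts at the
    first *retained* volume; planted task time courses are zero during the
    initial discarded volumes.
    """
    rng = np.random.default_rng(seed)
    grid = tuple(protocol.grid_shape)
    if library is None:
        library = build_template_library(grid, protocol.voxel_mm)
    if library.mask.shape != grid:
        raise ValueError("library grid does not match protocol grid")
    for name in scenario.networks:
        if name not in library.names:
            raise ValueError(f"scenario requests unknown network {name!r}")

    mask = library.mask
    T_rec, n_disc = protocol.n_recorded_volumes, protocol.n_discard
    T_ret = protocol.n_retained
    centers = _reserved_centers(grid)

    # the expected response is only needed for task-locked plants, and a
    # paradigm longer than a (deliberately short) scan is fine without them
    expected: np.ndarray | None = None
    if scenario.task or scenario.anticorr:
        design = build_design_matrix(paradigm, HRFParams(), protocol)
        expected = design.expected_response  # length T_ret

    def pad(tc_retained: np.ndarray) -> np.ndarray:
        return np.concatenate([np.zeros(n_disc), tc_retained])

    # residual fluctuations of task-locked plants are band-limited, like
    # BOLD: the hemodynamic response suppresses power above ~0.15 Hz
    def bold_noise() -> np.ndarray:
        return _bandlimited_series(rng, T_ret, protocol.tr_seconds, 0.005, 0.15)

    planted: list[PlantedComponent] = []
    if scenario.task:
        tc = pad(mix_to_target_correlation(expected, bold_noise(),
                                           scenario.task_target_r))
        m = _gaussian_blob(grid, centers["task_left"], 1.6)
        if scenario.task_bilateral:
            m = m + _gaussian_blob(grid, centers["task_right"], 1.6)
        m[~mask] = 0.0
        planted.append(PlantedComponent("task_sensorimotor", m, tc, "task_locked",
                                        scenario.task_amplitude,
                                        scenario.task_target_r))
    if scenario.anticorr:
        tc = pad(mix_to_target_correlation(expected, bold_noise(),
                                           scenario.anticorr_target_r))
        m = (_gaussian_blob(grid, centers["occ_left"], 1.6)
             + _gaussian_blob(grid, centers["occ_right"], 1.6))
        m[~mask] = 0.0
        planted.append(PlantedComponent("occipital_anticorrelated", m, tc,
                                        "task_locked", scenario.anticorr_amplitude,
                                        scenario.anticorr_target_r))
    for name in scenario.networks:
        m = _network_map(library, name, scenario.network_map_r, rng)
        tc = _bandlimited_series(rng, T_rec, protocol.tr_seconds)
        planted.append(PlantedComponent(f"network_{name}", m, tc,
                                        "network_structured",
                                        scenario.network_amplitude, None))

    motion_mm = motion_schedule(scenario.motion, T_rec, rng)

    if scenario.motion_component:
        ring = edge_ring(mask).astype(float)
        hf = rng.standard_normal(T_rec)
        # motion artifacts track the signed volume-to-volume displacement
        # (spiky at movement transitions), plus broadband jitter
        jump = np.diff(motion_mm[:, 0], prepend=motion_mm[0, 0])
        if jump.std() > 0:
            tc = (0.75 * _unit(jump) + 0.66 * _unit(hf)) * np.sqrt(T_rec)
        else:
            tc = _unit(hf) * np.sqrt(T_rec)
        planted.append(PlantedComponent("edge_motion", ring, tc, "motion_spike",
                                        scenario.motion_amplitude, None))
    csf_mask = csf_region(grid)
    if scenario.csf_component:
        m = _gaussian_blob(grid, centers["csf"], 1.3)
        m[~mask] = 0.0
        tc = _unit(rng.standard_normal(T_rec)) * np.sqrt(T_rec)
        planted.append(PlantedComponent("csf", m, tc, "csf",
                                        scenario.csf_amplitude, None))

    # assert the task-locked plants hit their target correlation
    for p in planted:
        if p.timecourse_kind == "task_locked":
            r = np.corrcoef(p.timecourse[n_disc:], expected)[0, 1]
            if abs(r - p.target_temporal_r) > 0.1:
                raise AssertionError(
                    f"planted {p.name}: achieved r {r:.3f} vs target "
                    f"{p.target_temporal_r}")

    data = np.zeros(grid + (T_rec,))
    data[mask] = scenario.head_intensity
    for p in planted:
        data += p.map[..., None] * (p.amplitude * p.timecourse)[None, None, None, :]
    if scenario.noise_sd > 0:
        data[mask] += _ar1_noise(rng, int(mask.sum()), T_rec,
                                 scenario.noise_sd, scenario.ar1)

    # motion injection: resample each volume under its translation
    if np.any(motion_mm != 0):
        shifts_vox = motion_mm / np.asarray(protocol.voxel_mm)[None, :]
        uniq, inv = np.unique(shifts_vox, axis=0, return_inverse=True)
        for u_i, shift in enumerate(uniq):
            if np.all(shift == 0):
                continue
            idx = np.where(inv == u_i)[0]
            data[..., idx] = ndimage.shift(
                data[..., idx], tuple(shift) + (0.0,), order=1, mode="constant")

    raw = Volume4D(data, tuple(protocol.voxel_mm), protocol.tr_seconds)
    params = np.zeros((T_rec, 6))
    params[:, 3:6] = motion_mm
    ref = n_disc + T_ret // 2
    trace = MotionTrace(params, reference_index=ref)
    gt = GroundTruth(planted, motion_mm, library.label_volume(),
                     list(scenario.networks), mask, csf_mask)
    return raw, trace, gt


@dataclass
class CohortSpec:
    """Per-subject scenarios for a cohort; ``overrides`` maps subject index
    to a full replacement Scenario."""

    n: int = 17
    base: Scenario = field(default_factory=Scenario)
    overrides: dict[int, Scenario] = field(default_factory=dict)

    def scenario_for(self, i: int) -> Scenario:
        return self.overrides.get(i, self.base)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds below 2**31."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def simulate_cohort(
    protocol: AcquisitionProtocol,
    paradigm: BlockParadigm,
    cohort_spec: CohortSpec,
    seed: int,
    library: TemplateLibrary | None = None,
) -> list[tuple[Volume4D, MotionTrace, GroundTruth]]:
    """Generate ``n`` independent subjects with seeds derived from the
    master seed; all subjects share one template library."""
    if cohort_spec.n < 0:
        raise ValueError("cohort size must be non-negative")
    if library is None:
        library = build_template_library(tuple(protocol.grid_shape),
                                         protocol.voxel_mm)
    seeds = derive_seeds(seed, cohort_spec.n) if cohort_spec.n else []
    return [
        simulate_subject(protocol, paradigm, cohort_spec.scenario_for(i),
                         seeds[i], library)
        for i in range(cohort_spec.n)
    ]


def write_subject(outdir, raw: Volume4D, trace: MotionTrace, gt: GroundTruth,
                  library: TemplateLibrary | None = None) -> None:
    """Write one subject's fixture: 4D NIfTI, motion TSV, masks, labels and
    a JSON ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw.save(outdir / "func.nii.gz")
    trace.save_tsv(outdir / "motion_injected.tsv")
    save_mask(gt.head_mask, raw.voxel_mm, outdir / "head_mask.nii.gz")
    save_mask(gt.csf_mask, raw.voxel_mm, outdir / "csf_mask.nii.gz")
    aff = np.diag(list(raw.voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(gt.labels.astype(np.int16), aff),
             str(outdir / "labels.nii.gz"))
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt.manifest_dict(), fh, indent=2)
    if library is not None:
        library.save(outdir / "templates")
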