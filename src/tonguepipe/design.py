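"""Block paradigm, gamma HRF, design matrix, and high-pass filter.

The experiment is a three-condition tongue-movement block design: frontal
(protrusion, ``F``), horizontal (side to side, ``H``) and vertical
(elevation, ``V``) movements.  Blocks last 15 s; after every third movement
block comes a 15 s rest, other blocks are separated by 3 s of rest.  Each
condition's boxcar is convolved with a gamma hemodynamic response function
(mean lag 6 s, SD 3 s, phase 0 s) and sampled at the TR; temporal
derivatives of the primary regressors are appended as confounds.  The
"expected response" — the union of all movement blocks convolved with the
HRF — is the reference series for the temporal component filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AcquisitionProtocol

DEFAULT_CONDITIONS = ("F", "H", "V")


@dataclass(frozen=True)
class HRFParams:
    """Gamma HRF parameterized by onset phase, width (SD) and mean lag.

    The gamma density has shape ``k = (mean_lag/sd)**2`` and scale
    ``theta = sd**2/mean_lag`` (so its mean is ``mean_lag`` and its SD is
    ``sd``), shifted right by ``phase_s``.
    """

    phase_s: float = 0.0
    sd_s: float = 3.0
    mean_lag_s: float = 6.0

    def __post_init__(self) -> None:
        if self.sd_s <= 0 or self.mean_lag_s <= 0:
            raise ValueError("sd_s and mean_lag_s must be positive")

    @property
    def shape(self) -> float:
        return (self.mean_lag_s / self.sd_s) ** 2

    @property
    def scale(self) -> float:
        return self.sd_s**2 / self.mean_lag_s


@dataclass(frozen=True)
class Event:
    trial_type: str
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class BlockParadigm:
    """Ordered, non-overlapping condition/rest timeline."""

    events: list[Event]
    lead_in_s: float = 15.0

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.onset_s)
        for a, b in zip(ev, ev[1:]):
            if b.onset_s < a.end_s - 1e-9:
                raise ValueError("events overlap")
        self.events = ev

    @property
    def movement_events(self) -> list[Event]:
        return [e for e in self.events if e.trial_type != "rest"]

    @property
    def conditions(self) -> list[str]:
        """Unique movement condition labels, in sorted order (F, H, V for
        the default design) so design-matrix columns are stable."""
        return sorted({e.trial_type for e in self.movement_events})

    @property
    def end_s(self) -> float:
        return max((e.end_s for e in self.events), default=0.0)

    def shifted(self, delta_s: float) -> "BlockParadigm":
        """Return a copy with every onset moved by ``delta_s`` seconds."""
        return BlockParadigm(
            [Event(e.trial_type, e.onset_s + delta_s, e.duration_s) for e in self.events],
            lead_in_s=self.lead_in_s,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [e.onset_s for e in self.events],
                "duration": [e.duration_s for e in self.events],
                "trial_type": [e.trial_type for e in self.events],
            }
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(str(path), sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path, lead_in_s: float = 15.0) -> "BlockParadigm":
        df = pd.read_csv(str(path), sep="\t")
        events = [Event(str(r.trial_type), float(r.onset), float(r.duration))
                  for r in df.itertuples()]
        return cls(events, lead_in_s=lead_in_s)


def build_paradigm(
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    blocks_per_condition: int = 8,
    block_s: float = 15.0,
    long_rest_s: float = 15.0,
    short_rest_s: float = 3.0,
    lead_in_s: float = 15.0,
    seed: int = 0,
    max_consecutive: int = 2,
) -> BlockParadigm:
    """Build the pseudorandomized block timeline.

    The condition order is a seeded shuffle constrained so that no condition
    appears more than ``max_consecutive`` times in a row.  A 15 s rest
    follows every third movement block (and the final block); remaining
    blocks are separated by 3 s rests.
    """
    if blocks_per_condition < 1:
        raise ValueError("blocks_per_condition must be >= 1")
    if not conditions:
        raise ValueError("need at least one condition")
    rng = np.random.default_rng(seed)
    pool = [c for c in conditions for _ in range(blocks_per_condition)]

    order = None
    for _ in range(2000):
        cand = list(rng.permutation(pool))
        run, ok = 1, True
        for a, b in zip(cand, cand[1:]):
            run = run + 1 if a == b else 1
            if run > max_consecutive:
                ok = False
                break
        if ok:
            order = cand
            break
    if order is None:
        raise ValueError("could not pseudorandomize order under the "
                         f"max-{max_consecutive}-consecutive constraint")

    events: list[Event] = []
    t = lead_in_s
    n = len(order)
    for i, cond in enumerate(order, start=1):
        events.append(Event(cond, t, block_s))
        t += block_s
        rest = long_rest_s if (i % 3 == 0 or i == n) else short_rest_s
        events.append(Event("rest", t, rest))
        t += rest
    return BlockParadigm(events, lead_in_s=lead_in_s)


def gamma_hrf(params: HRFParams, dt_s: float, support_s: float = 32.0) -> np.ndarray:
    """Sample the gamma HRF kernel on ``t = 0, dt, 2dt, ...`` and normalize
    it to unit sum."""
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if support_s < params.mean_lag_s + 5 * params.sd_s:
        raise ValueError("support_s must cover mean_lag + 5*sd")
    t = np.arange(0.0, support_s + dt_s / 2, dt_s)
    kernel = stats.gamma.pdf(t - params.phase_s, a=params.shape, scale=params.scale)
    total = kernel.sum()
    if total <= 0:
        raise ValueError("degenerate HRF kernel")
    return kernel / total


@dataclass
class DesignMatrix:
    """Sampled first-level design: condition EVs, temporal derivatives, and
    the combined expected response."""

    frame: pd.DataFrame
    expected_response: np.ndarray
    tr_seconds: float

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    def save_tsv(self, path) -> None:
        out = self.frame.copy()
        out["expected_response"] = self.expected_response
        out.to_csv(str(path), sep="\t", index=False)


def _boxcar(events: list[Event], t_fine: np.ndarray) -> np.ndarray:
    box = np.zeros_like(t_fine)
    for e in events:
        box[(t_fine >= e.onset_s) & (t_fine < e.end_s)] = 1.0
    return box


def build_design_matrix(
    paradigm: BlockParadigm,
    hrf_params: HRFParams = HRFParams(),
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    dt_s: float = 0.05,
) -> DesignMatrix:
    """Convolve condition boxcars with the HRF at fine resolution and sample
    them at the volume acquisition times ``t = i * TR``.

    Returns one EV per condition plus its temporal derivative
    (``np.gradient`` of the sampled EV), and the expected response built
    from the union of all movement blocks.
    """
    n_t = protocol.n_retained
    span = n_t * protocol.tr_seconds
    if paradigm.end_s > span + 1e-6:
        raise ValueError(
            f"paradigm ({paradigm.end_s:.1f} s) exceeds retained scan span ({span:.1f} s)")
    t_fine = np.arange(0.0, span + dt_s / 2, dt_s)
    kernel = gamma_hrf(hrf_params, dt_s)
    sample_idx = np.rint(np.arange(n_t) * protocol.tr_seconds / dt_s).astype(int)

    def convolve_sample(events: list[Event]) -> np.ndarray:
        box = _boxcar(events, t_fine)
        conv = np.convolve(box, kernel)[: len(t_fine)]
        return conv[sample_idx]

    cols: dict[str, np.ndarray] = {}
    conditions = paradigm.conditions
    for cond in conditions:
        cols[cond] = convolve_sample([e for e in paradigm.movement_events
                                      if e.trial_type == cond])
    for cond in conditions:
        cols[f"{cond}_deriv"] = np.gradient(cols[cond])
    expected = convolve_sample(paradigm.movement_events)
    frame = pd.DataFrame(cols) if cols else pd.DataFrame(index=range(n_t))
    if not cols:
        expected = np.zeros(n_t)
    return DesignMatrix(frame=frame, expected_response=expected,
                        tr_seconds=protocol.tr_seconds)


def highpass_filter(series: np.ndarray, sigma_s: float, tr_seconds: float) -> np.ndarray:
    """Gaussian-weighted running-line high-pass filter.

    At each time point a straight line is fitted by weighted least squares
    with Gaussian weights (SD ``sigma_s``) centred there; the fitted value
    is subtracted and the series' global mean re-added.  Accepts a (T,) or
    (T, V) array.
    """
    y = np.asarray(series, dtype=np.float64)
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    if y.shape[0] < 3:
        raise ValueError("series must have length >= 3")
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    T = y.shape[0]
    t = np.arange(T) * tr_seconds
    # W[i, j] = weight of sample j in the fit centred at i
    W = np.exp(-0.5 * ((t[None, :] - t[:, None]) / sigma_s) ** 2)
    s0 = W.sum(axis=1)
    s1 = W @ t
    s2 = W @ (t * t)
    sy = W @ y
    sty = W @ (t[:, None] * y)
    denom = s0 * s2 - s1 * s1
    b = (s0[:, None] * sty - s1[:, None] * sy) / denom[:, None]
    a = (sy - b * s1[:, None]) / s0[:, None]
    fit = a + b * t[:, None]
    out = y - fit + y.mean(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out
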