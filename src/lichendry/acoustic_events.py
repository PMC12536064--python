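"""Ultrasonic acoustic emission (UAE) hit streams during thallus desiccation.

A piezoelectric sensor records discrete hits (time, amplitude in dB,
absolute energy in aJ) while the sample dries. Because a sample wired to the
acoustic system cannot be weighed continuously, a twin sample dried next to
it provides fresh-weight checkpoints every 30 minutes; the monitored
sample's cumulative hit count is read off at those checkpoint times and
normalized to its final count (rcUAE, %). Plotted against the twin's
relative water content this yields the rcUAE-RWC trajectory, whose
breakpoint (RWC_UAE) marks the onset of the emission burst.

Processing steps:

* a debounce filter drops hits arriving less than 1 s after the last kept
  hit (reverberation / background noise);
* trajectories couple cumulative counts to RWC via the twin series;
* RWC_UAE is the breakpoint of a random-intercept segmented model pooling
  the per-sample trajectories;
* the amplitude-energy structure is summarized by a cubic polynomial per
  vitality class (living / devitalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import stats_core
from .errors import (
    CoverageError,
    InvalidInputError,
    NoEmissionsError,
    SilentSampleWarning,
)
from .water_relations import compute_rwc

#: minimum inter-hit gap (s) of the debounce filter
DEFAULT_MIN_GAP = 1.0

#: RWC band (%, dry mass) of the rubbery-to-glassy cytoplasm transition,
#: reported for annotation only
GLASSY_BAND = (8.0, 12.0)

VITALITIES = ("living", "devitalized")

__all__ = [
    "AEHit",
    "AETrace",
    "DryingSeries",
    "UAETrajectory",
    "filter_hits",
    "compute_trajectory",
    "estimate_rwc_uae",
    "characterize_energy_amplitude",
    "annotate_low_rwc_band",
    "rwc_at_times",
    "DEFAULT_MIN_GAP",
    "GLASSY_BAND",
]


@dataclass(frozen=True)
class AEHit:
    """One acoustic hit: arrival time (s), amplitude (dB), absolute energy (aJ)."""

    time: float
    amplitude: float
    energy: float

    def __post_init__(self):
        if self.time < 0:
            raise InvalidInputError("hit time must be non-negative")
        if self.energy < 0:
            raise InvalidInputError("hit energy must be non-negative")


@dataclass(frozen=True)
class AETrace:
    """A time-ordered hit stream for one monitored sample.

    Gel-mass bookkeeping (``gel_mass = fw_with_gel - fw_without_gel``)
    records the acoustic-coupling gel spread on the sample; it plays no role
    in the RWC arithmetic, which uses the twin sample throughout. Hardware
    acquisition settings live in ``metadata``.
    """

    sample_id: str
    species: str
    vitality: str  # "living" | "devitalized"
    hits: tuple[AEHit, ...]
    gel_mass: float | None = None  # mg
    fw_with_gel: float | None = None  # mg
    fw_without_gel: float | None = None  # mg
    metadata: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "hits", tuple(self.hits))
        if self.vitality not in VITALITIES:
            raise InvalidInputError(f"vitality must be one of {VITALITIES}")
        times = [h.time for h in self.hits]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidInputError("hits must be strictly time-ordered")
        if self.gel_mass is not None and self.fw_with_gel is not None and self.fw_without_gel is not None:
            if self.gel_mass < 0:
                raise InvalidInputError("gel mass must be non-negative")
            if abs(self.gel_mass - (self.fw_with_gel - self.fw_without_gel)) > 0.5:
                raise InvalidInputError(
                    "gel mass inconsistent with fresh weights with/without gel"
                )

    def times(self) -> np.ndarray:
        return np.array([h.time for h in self.hits], dtype=float)


@dataclass(frozen=True)
class DryingSeries:
    """Fresh-weight checkpoints of the twin (unwired) sample."""

    sample_id: str
    checkpoints: tuple[tuple[float, float], ...]  # (time min, fw mg)
    dw: float  # mg

    def __post_init__(self):
        object.__setattr__(self, "checkpoints", tuple(tuple(c) for c in self.checkpoints))
        if self.dw <= 0:
            raise InvalidInputError("dry weight must be positive")
        t = [c[0] for c in self.checkpoints]
        if any(t2 <= t1 for t1, t2 in zip(t, t[1:])):
            raise InvalidInputError("checkpoint times must be strictly increasing")

    def times_min(self) -> np.ndarray:
        return np.array([c[0] for c in self.checkpoints], dtype=float)

    def fw_mg(self) -> np.ndarray:
        return np.array([c[1] for c in self.checkpoints], dtype=float)


@dataclass(frozen=True)
class UAETrajectory:
    """Per-checkpoint cumulative and relative cumulative UAE against RWC."""

    sample_id: str
    time_min: np.ndarray
    rwc: np.ndarray  # % dry mass
    cum_uae: np.ndarray  # counts
    rc_uae: np.ndarray  # % of final count
    silent: bool = False
    glassy: np.ndarray | None = None


def filter_hits(trace: AETrace, min_gap: float = DEFAULT_MIN_GAP) -> AETrace:
    """Debounce filter: drop hits closer than ``min_gap`` to the last kept hit.

    The gap is measured against the last *kept* hit, so a whole burst of
    reverberation following a real event is removed in one pass and the
    filter is idempotent. The strict reading of "< 1 s" keeps gaps of
    exactly ``min_gap``. The first hit is always kept.
    """
    if min_gap <= 0:
        raise InvalidInputError("min_gap must be positive")
    kept: list[AEHit] = []
    last = -np.inf
    for hit in trace.hits:
        if hit.time - last >= min_gap:
            kept.append(hit)
            last = hit.time
    return replace(trace, hits=tuple(kept))


def compute_trajectory(trace: AETrace, twin: DryingSeries) -> UAETrajectory:
    """Couple cumulative hit counts to the twin's drying checkpoints.

    At each checkpoint time t the cumulative count is the number of (kept)
    hits with arrival time <= t; RWC comes from the twin's fresh weight and
    dry weight; rcUAE normalizes by the final cumulative count. A trace
    whose hits outlast the twin series raises :class:`CoverageError`; a
    hitless trace yields an all-zero trajectory flagged silent.
    """
    t_cp = twin.times_min()
    if t_cp.size == 0:
        raise InvalidInputError("twin drying series has no checkpoints")
    hit_min = trace.times() / 60.0
    if hit_min.size and hit_min.max() > t_cp[-1]:
        raise CoverageError(
            f"twin series for {trace.sample_id!r} ends at {t_cp[-1]:.0f} min but hits "
            f"extend to {hit_min.max():.0f} min"
        )
    cum = np.searchsorted(hit_min, t_cp, side="right").astype(float)
    rwc = compute_rwc(twin.fw_mg(), twin.dw)
    silent = cum[-1] == 0
    if silent:
        warnings.warn(f"sample {trace.sample_id!r} emitted no hits", SilentSampleWarning, stacklevel=2)
        rc = np.zeros_like(cum)
    else:
        rc = cum / cum[-1] * 100.0
    return UAETrajectory(
        sample_id=trace.sample_id,
        time_min=t_cp,
        rwc=np.asarray(rwc, dtype=float),
        cum_uae=cum,
        rc_uae=rc,
        silent=bool(silent),
    )


def estimate_rwc_uae(
    trajectories: list[UAETrajectory],
    *,
    ci_level: float = 0.95,
    n_grid: int = 41,
) -> stats_core.BreakpointFit:
    """RWC at which emissions take off (RWC_UAE).

    Pools the (RWC, rcUAE) points of all non-silent trajectories with the
    sample as random-effect group and locates the breakpoint of the
    segmented random-intercept model. The breakpoint and its CI are on the
    RWC axis (% dry mass).
    """
    if len(trajectories) < 2:
        raise InvalidInputError("need at least 2 trajectories to estimate RWC_UAE")
    active = [t for t in trajectories if not t.silent]
    if not active:
        raise NoEmissionsError("all samples silent: no emissions to locate")
    rwc = np.concatenate([t.rwc for t in active])
    rc = np.concatenate([t.rc_uae for t in active])
    groups = np.concatenate([[t.sample_id] * len(t.rwc) for t in active])
    return stats_core.fit_segmented_mixed(rwc, rc, groups, ci_level=ci_level, n_grid=n_grid)


def characterize_energy_amplitude(
    traces: list[AETrace], *, ci_level: float = 0.95
) -> dict[str, stats_core.PolynomialFit]:
    """Cubic polynomial of absolute energy (aJ) on amplitude (dB).

    Hits are pooled per vitality class and fitted separately for living and
    devitalized samples. Returns a mapping vitality -> fit for the classes
    present.
    """
    out: dict[str, stats_core.PolynomialFit] = {}
    for vit in VITALITIES:
        hits = [h for tr in traces if tr.vitality == vit for h in tr.hits]
        if not hits:
            continue
        if len(hits) < 5:
            raise InvalidInputError(
                f"energy-amplitude fit needs at least 5 pooled hits for {vit!r} samples"
            )
        amp = np.array([h.amplitude for h in hits])
        en = np.array([h.energy for h in hits])
        out[vit] = stats_core.fit_polynomial_cubic(amp, en, ci_level=ci_level)
    if not out:
        raise InvalidInputError("no hits to characterize")
    return out


def rwc_at_times(twin: DryingSeries, times_min) -> np.ndarray:
    """RWC of the twin sample at arbitrary times, for per-hit stamps.

    Fresh weight is linearly interpolated in time between checkpoints;
    times outside the checkpoint span raise :class:`CoverageError`.
    """
    t = np.asarray(times_min, dtype=float)
    cp = twin.times_min()
    if t.size and (t.min() < cp[0] or t.max() > cp[-1]):
        raise CoverageError("requested times fall outside the drying-series span")
    fw = np.interp(t, cp, twin.fw_mg())
    return np.asarray(compute_rwc(fw, twin.dw), dtype=float)


def annotate_low_rwc_band(
    trajectory: UAETrajectory, band: tuple[float, float] = GLASSY_BAND
) -> UAETrajectory:
    """Mark checkpoints inside the glassy-transition RWC band (default 8-12%).

    Reporting annotation only; no numeric analysis depends on it.
    """
    lo, hi = band
    mask = (trajectory.rwc >= lo) & (trajectory.rwc <= hi)
    return replace(trajectory, glassy=mask)
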