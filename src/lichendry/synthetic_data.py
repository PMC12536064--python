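"""Synthetic inputs with known ground truth for every pipeline stage.

No public accession of the raw drying logs exists, so this module generates
inputs that emulate the *statistical* structure the analyses assume — not
the biophysics of a real thallus:

* pressure-volume isotherms with an apoplastic plateau, an exponentially
  declining water potential and an osmotic (1/pi linear in water loss)
  branch anchored to the five highest-water-loss points, calibrated so that
  the turgor-pressure zero crossing sits exactly at the harmonic
  combination ``psi_tlp = -|pi0| eps / (|pi0| + eps)`` of the osmotic (pi0)
  and elastic (eps) parameters;
* plateau-then-linear-decline Fv/Fm curves with Gaussian noise;
* acoustic-emission experiments: exponential drying of the twin sample,
  sparse homogeneous background hits, a Poisson burst switched on below a
  threshold RWC, and hit energies following a cubic function of amplitude
  with lognormal scatter.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .acoustic_events import AEHit, AETrace, DryingSeries
from .errors import InvalidInputError
from .fluorescence_response import FvFmCurve
from .stats_core import DEFAULT_SEED
from .water_relations import IsothermPoint, IsothermRecord

__all__ = [
    "PVTruth",
    "FvFmTruth",
    "AETruth",
    "gen_pv_isotherm",
    "gen_fvfm_curve",
    "gen_ae_experiment",
    "gen_ae_dataset",
    "attach_fluorescence",
]

#: default hardware acquisition settings recorded as trace metadata
AE_HARDWARE = {
    "preamp_db": 40,
    "threshold_db": 30,
    "peak_definition_us": 200,
    "hit_definition_us": 400,
    "hit_lockout_us": 2,
}


# --------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class PVTruth:
    """Ground truth of a synthetic pressure-volume isotherm.

    Defaults put the turgor-loss water potential at -6.0 MPa and the
    full-turgor RWC near 167% (dry-mass basis), the magnitudes typical of
    foliose lichen thalli.
    """

    pi0: float = -8.0  # MPa, osmotic parameter (< 0)
    epsilon: float = 24.0  # MPa, elastic parameter (> 0)
    apoplastic_fraction: float = 0.10  # share of total water in the apoplastic plateau
    ifw: float = 107.0  # mg, fresh weight at full turgor incl. apoplastic water
    dw: float = 40.0  # mg
    sigma_psi: float = 0.0  # MPa, Gaussian noise on water potential
    sigma_fw: float = 0.0  # mg, Gaussian noise on fresh weight
    psi_tlp_true: float = field(init=False)

    def __post_init__(self):
        if self.pi0 >= 0:
            raise InvalidInputError("pi0 must be negative")
        if self.epsilon <= 0:
            raise InvalidInputError("epsilon must be positive")
        if not 0 <= self.apoplastic_fraction < 0.3:
            raise InvalidInputError("apoplastic_fraction must lie in [0, 0.3)")
        if self.dw <= 0 or self.ifw <= self.dw:
            raise InvalidInputError("need ifw > dw > 0")
        a = abs(self.pi0)
        object.__setattr__(self, "psi_tlp_true", -a * self.epsilon / (a + self.epsilon))

    @property
    def rwc_tlp_true(self) -> float:
        """RWC (% dry mass) at the true turgor loss point."""
        design = _pv_design(self)
        fw_tlp = self.ifw - design["apo"] - design["wl_tlp"]
        return (fw_tlp - self.dw) / self.dw * 100.0


@dataclass(frozen=True)
class FvFmTruth:
    """Ground truth of a synthetic Fv/Fm response curve.

    Defaults mirror a plateau of 0.68 breaking at -8.7 MPa and reaching zero
    near -38 MPa.
    """

    breakpoint: float = -8.7  # MPa
    plateau: float = 0.68
    slope_after: float = 0.023  # Fv/Fm per MPa of further psi drop
    sigma: float = 0.03
    n: int = 150  # pooled points per species (~6 samples x 25 sequential readings)
    psi_min: float = -40.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not 0 <= self.plateau < 1:
            raise InvalidInputError("plateau must lie in [0, 1)")
        if self.breakpoint >= 0:
            raise InvalidInputError("breakpoint must be negative")


@dataclass(frozen=True)
class AETruth:
    """Ground truth of a synthetic acoustic-emission experiment.

    Defaults switch the burst on at 6% RWC (emissions essentially absent
    above it, apart from sparse background) with a monotone increasing cubic
    amplitude-to-energy map over the 30-60 dB range and a twin sample drying
    exponentially from 380% RWC with a 60 min half-life.
    """

    burst_rwc: float = 6.0  # % dry mass, onset of emissions
    burst_rate: float = 10.0  # hits/min at burst onset
    background_rate: float = 0.02  # hits/min over the whole recording
    cubic_coeffs: tuple[float, float, float, float] = (5.0, 0.1, 0.002, 0.0008)  # aJ per dB^k
    amp_range: tuple[float, float] = (30.0, 60.0)  # dB
    drying_halflife: float = 60.0  # min
    rwc_start: float = 380.0  # % dry mass
    seed: int = DEFAULT_SEED
    # bookkeeping parameters of the simulated experiment
    dw: float = 25.0  # mg, both samples
    gel_mass: float = 360.0  # mg of coupling gel
    rwc_end: float = 1.0  # % dry mass at which recording stops
    checkpoint_every: float = 30.0  # min
    energy_sigma: float = 0.4  # lognormal sd of the energy scatter
    amp_lift: float = 8.0  # dB of upward amplitude shift deep into the burst
    sample_id: str = "simA"
    species: str = "Simulated"
    vitality: str = "living"

    def __post_init__(self):
        if not self.burst_rwc < self.rwc_start:
            raise InvalidInputError("burst_rwc must be below rwc_start")
        if self.burst_rate < 0 or self.background_rate < 0:
            raise InvalidInputError("rates must be non-negative")
        if not 0 < self.rwc_end < self.burst_rwc:
            raise InvalidInputError("need 0 < rwc_end < burst_rwc")
        if self.drying_halflife <= 0 or self.checkpoint_every <= 0:
            raise InvalidInputError("half-life and checkpoint interval must be positive")


# --------------------------------------------------------------------------
# pressure-volume isotherms


#: number of highest-water-loss points defining the osmotic (1/pi) branch
_N_TAIL = 5
#: span of the osmotic tail as a fraction of the residual symplastic water
_TAIL_SPAN = 0.8
#: steepness of the exponential decline in units of 1/(residual symplastic water)
_B_SCALE = 1.5


def _pv_design(truth: PVTruth) -> dict:
    """Closed-form design of the synthetic PV curve.

    The emitted water potential follows one exponential decline,
    ``psi(wl) = -a exp(b wl)``; the five highest-water-loss points
    additionally define, through their reciprocal potentials, the osmotic
    line ``1/pi = m wl + c`` (the secant the elaboration recovers). Turgor
    is the difference ``psi - pi``, positive up to its zero crossing. The
    elastic parameter places that crossing at the symplastic water-loss
    fraction ``|pi0|/(|pi0| + eps)`` (stiffer thalli lose turgor earlier),
    and the amplitude ``a`` is calibrated so the water potential at the
    crossing equals ``psi_tlp_true`` exactly. Because scaling ``a`` scales
    the exponential and the secant line together, the crossing water loss
    is scale-free and the calibration is a single multiplication.
    """
    water = truth.ifw - truth.dw
    apo = truth.apoplastic_fraction * water
    w0 = water - apo
    x_t = abs(truth.pi0) / (abs(truth.pi0) + truth.epsilon)
    wl_t = x_t * w0
    s = w0 - wl_t
    b = _B_SCALE / s
    wl_tail = np.linspace(wl_t, wl_t + _TAIL_SPAN * s, _N_TAIL)
    # unit-amplitude secant of 1/psi through the tail
    m, c = np.polyfit(wl_tail, -np.exp(-b * wl_tail), 1)

    def turgor_unit(wl):
        return -np.exp(b * wl) - 1.0 / (m * wl + c)

    grid = np.linspace(0.0, wl_tail[-1], 4001)
    sign = turgor_unit(grid) <= 0
    i = int(np.argmax(sign))
    wl_tlp = float(brentq(turgor_unit, grid[i - 1], grid[i]))
    a = abs(truth.psi_tlp_true) / float(np.exp(b * wl_tlp))
    return {
        "a": a,
        "b": b,
        "slope": m / a,
        "intercept": c / a,
        "w0": w0,
        "apo": apo,
        "wl_tail": wl_tail,
        "wl_tlp": wl_tlp,
    }


def gen_pv_isotherm(
    truth: PVTruth = PVTruth(),
    n_points: int = 14,
    seed: int = DEFAULT_SEED,
) -> tuple[IsothermRecord, PVTruth]:
    """Generate one drying-ordered isotherm record with known truth.

    The emitted sequence starts with an apoplastic plateau (water potential
    inside (-0.30, 0]) when ``apoplastic_fraction > 0``, then follows the
    exponential decline from the first water loss at which it passes
    -0.31 MPa, ending with the five tail points that define the osmotic
    branch. Gaussian noise of sd ``sigma_psi`` / ``sigma_fw`` is added to
    the potentials / weights.
    """
    if n_points < 10:
        raise InvalidInputError("need n_points >= 10")
    rng = np.random.default_rng(seed)
    design = _pv_design(truth)
    a, b, apo = design["a"], design["b"], design["apo"]

    wl_s0 = max(np.log(0.310 / a) / b, 0.0)
    wl_tail = design["wl_tail"]
    if wl_s0 >= wl_tail[0]:
        raise InvalidInputError(
            "exclusion band swallows the whole pre-turgor-loss branch; "
            "|psi_tlp_true| too close to 0.30 MPa"
        )
    n_pre = n_points - _N_TAIL
    wl_pre = np.linspace(wl_s0, wl_tail[0], n_pre, endpoint=False)
    wl_all = np.concatenate([wl_pre, wl_tail])
    psi_all = -a * np.exp(b * wl_all)
    fw_all = truth.ifw - apo - wl_all

    points: list[IsothermPoint] = []
    t = 0.0
    if apo > 0:
        n_apo = 3
        wl_apo = np.linspace(0.0, apo, n_apo, endpoint=False)
        psi_apo = np.linspace(-0.02, -0.25, n_apo)
        for wa, pa in zip(wl_apo, psi_apo):
            points.append(
                IsothermPoint(
                    time=t,
                    psi=min(pa + rng.normal(0.0, truth.sigma_psi), -0.001),
                    fw=truth.ifw - wa + rng.normal(0.0, truth.sigma_fw),
                )
            )
            t += 30.0
    for wl_i, psi_i, fw_i in zip(wl_all, psi_all, fw_all):
        points.append(
            IsothermPoint(
                time=t,
                psi=min(psi_i + rng.normal(0.0, truth.sigma_psi), -0.001),
                fw=max(fw_i + rng.normal(0.0, truth.sigma_fw), truth.dw * 1.001),
            )
        )
        t += 30.0
    record = IsothermRecord(
        sample_id=f"pv-{seed}", species="Simulated", points=tuple(points), dw=truth.dw
    )
    return record, truth


# --------------------------------------------------------------------------
# Fv/Fm curves


def gen_fvfm_curve(truth: FvFmTruth = FvFmTruth()) -> tuple[FvFmCurve, FvFmTruth]:
    """Plateau-then-linear-decline Fv/Fm response with Gaussian noise.

    Water potentials are drawn uniformly over ``[psi_min, 0)``; above the
    breakpoint the response sits at the plateau, below it declines linearly
    at ``slope_after`` per MPa, truncated at zero. Values are clipped to
    [0, 1).
    """
    rng = np.random.default_rng(truth.seed)
    psi = np.sort(rng.uniform(truth.psi_min, -0.01, truth.n))
    clean = np.where(
        psi >= truth.breakpoint,
        truth.plateau,
        truth.plateau - truth.slope_after * (truth.breakpoint - psi),
    )
    clean = np.clip(clean, 0.0, None)
    fvfm = np.clip(clean + rng.normal(0.0, truth.sigma, truth.n), 0.0, 0.999)
    curve = FvFmCurve(psi=psi, fvfm=fvfm, sample_ids=tuple(f"fv-{truth.seed}" for _ in psi))
    return curve, truth


def attach_fluorescence(
    record: IsothermRecord,
    truth: FvFmTruth = FvFmTruth(),
    *,
    f0_level: float = 10000.0,
) -> IsothermRecord:
    """Stamp (F0, Fm) readings consistent with a plateau/decline Fv/Fm model
    onto an isotherm record, keeping F0 fixed and solving Fm = F0/(1 - Fv/Fm)."""
    rng = np.random.default_rng(truth.seed)
    new_points = []
    for p in record.points:
        clean = (
            truth.plateau
            if p.psi >= truth.breakpoint
            else truth.plateau - truth.slope_after * (truth.breakpoint - p.psi)
        )
        fvfm = float(np.clip(clean + rng.normal(0.0, truth.sigma), 0.0, 0.995))
        fm = f0_level / (1.0 - fvfm)
        new_points.append(replace(p, f0=f0_level, fm=fm))
    return replace(record, points=tuple(new_points))


# --------------------------------------------------------------------------
# acoustic-emission experiments


def gen_ae_experiment(truth: AETruth = AETruth()) -> tuple[AETrace, DryingSeries, AETruth]:
    """Simulate one monitored sample plus its twin drying series.

    The twin dries exponentially, ``FW(t) = DW + (FW0 - DW) 2^(-t/halflife)``,
    sampled every 30 min until RWC falls to ``rwc_end``. Background hits form
    a homogeneous Poisson process over the whole recording; burst hits a
    Poisson process active only while RWC <= ``burst_rwc``, with intensity
    proportional to the instantaneous drying rate (emissions per unit water
    lost, ``burst_rate`` hits/min at onset), so the expected cumulative
    burst count is linear in RWC below the onset. Burst amplitudes are
    lifted upward as RWC falls; energies follow the cubic
    amplitude-to-energy map with lognormal scatter.
    """
    rng = np.random.default_rng(truth.seed)
    h = truth.drying_halflife
    t_end = h * np.log2(truth.rwc_start / truth.rwc_end)
    n_cp = int(np.ceil(t_end / truth.checkpoint_every)) + 1
    if n_cp < 2:
        raise InvalidInputError("drying too fast for at least 2 checkpoints")
    t_cp = np.arange(n_cp, dtype=float) * truth.checkpoint_every
    t_last = t_cp[-1]

    fw0 = truth.dw * (1.0 + truth.rwc_start / 100.0)

    def rwc_at(t):
        return truth.rwc_start * 2.0 ** (-np.asarray(t, dtype=float) / h)

    def fw_at(t):
        return truth.dw * (1.0 + rwc_at(t) / 100.0)

    t_on = h * np.log2(truth.rwc_start / truth.burst_rwc)

    def poisson_times(rate, lo, hi):
        if rate <= 0 or hi <= lo:
            return np.empty(0)
        n = rng.poisson(rate * (hi - lo))
        return np.sort(rng.uniform(lo, hi, n))

    bg_t = poisson_times(truth.background_rate, 0.0, t_last)

    # inhomogeneous burst: intensity burst_rate * 2^(-(t - t_on)/halflife),
    # i.e. proportional to the drying rate, sampled by inverse transform
    if truth.burst_rate > 0 and t_last > t_on:
        decay_end = 2.0 ** (-(t_last - t_on) / h)
        total = truth.burst_rate * h / np.log(2.0) * (1.0 - decay_end)
        n_burst = rng.poisson(total)
        u = rng.uniform(0.0, 1.0, n_burst)
        burst_t = np.sort(t_on - h * np.log2(1.0 - u * (1.0 - decay_end)))
    else:
        burst_t = np.empty(0)

    lo, hi = truth.amp_range
    bg_amp = rng.uniform(lo, hi, bg_t.size)
    depth = 1.0 - rwc_at(burst_t) / truth.burst_rwc  # 0 at onset -> ~1 when dry
    burst_amp = rng.uniform(lo, hi, burst_t.size) + truth.amp_lift * depth

    t_all = np.concatenate([bg_t, burst_t])
    amp_all = np.concatenate([bg_amp, burst_amp])
    order = np.argsort(t_all)
    t_all, amp_all = t_all[order], amp_all[order]
    # enforce strictly increasing arrival times (ties get a microsecond nudge)
    for i in range(1, t_all.size):
        if t_all[i] <= t_all[i - 1]:
            t_all[i] = np.nextafter(t_all[i - 1], np.inf) + 1e-8

    energy = np.polynomial.polynomial.polyval(amp_all, np.asarray(truth.cubic_coeffs))
    energy = np.clip(energy, 1e-6, None) * np.exp(rng.normal(0.0, truth.energy_sigma, t_all.size))

    hits = tuple(
        AEHit(time=float(t * 60.0), amplitude=float(a), energy=float(e))
        for t, a, e in zip(t_all, amp_all, energy)
    )
    trace = AETrace(
        sample_id=truth.sample_id,
        species=truth.species,
        vitality=truth.vitality,
        hits=hits,
        gel_mass=truth.gel_mass,
        fw_with_gel=fw0 + truth.gel_mass,
        fw_without_gel=fw0,
        metadata=dict(AE_HARDWARE),
    )
    series = DryingSeries(
        sample_id=truth.sample_id,
        checkpoints=tuple((float(t), float(fw)) for t, fw in zip(t_cp, fw_at(t_cp))),
        dw=truth.dw,
    )
    return trace, series, truth


def gen_ae_dataset(
    n_samples: int = 4,
    truth: AETruth = AETruth(),
    seed: int = DEFAULT_SEED,
) -> tuple[list[AETrace], list[DryingSeries], list[AETruth]]:
    """A multi-sample experiment: independent replicates of ``truth`` with
    per-sample seeds spawned from ``seed`` and distinct sample ids."""
    seeds = np.random.SeedSequence(seed).generate_state(n_samples) % (2**31)
    traces, series, truths = [], [], []
    for i, s in enumerate(seeds):
        t_i = replace(truth, seed=int(s), sample_id=f"{truth.sample_id}{i + 1}")
        tr, dr, tt = gen_ae_experiment(t_i)
        traces.append(tr)
        series.append(dr)
        truths.append(tt)
    return traces, series, truths
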