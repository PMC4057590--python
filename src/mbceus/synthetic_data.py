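"""Synthetic generators for cine loops, strain pairs and growth cohorts.

The generators emulate the statistical structure that the downstream
quantification assumes, so the whole pipeline is testable without any
recorded exam:

* a gamma-variate bolus of circulating microbubbles after injection,
  washing out into a quasi-steady recirculating pool;
* a bound-microbubble pool accumulating proportionally to receptor
  density, destroyed (together with the in-plane circulating pool) by a
  1-second high-mechanical-index flash, after which only circulating
  bubbles replenish the imaging plane;
* multiplicative speckle noise and 8-bit log-compressed display;
* per-animal tumor-diameter trajectories under three treatment
  schedules (continuous placebo, transient drug interruption, definitive
  drug stop with rebound growth);
* paired tumor/reference-pad strain images.

Everything is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .compression import CompressionLaw, log_compress
from .containers import CineLoop, StrainPair, TumorPhantom, clip_times
from .errors import ParameterError

__all__ = [
    "KineticParams",
    "GrowthParams",
    "TreatmentSchedule",
    "simulate_circulating",
    "simulate_bound",
    "make_phantom",
    "render_cine",
    "simulate_growth_cohort",
    "simulate_strain_pair",
    "DEFAULT_CLIPS",
    "DIAMETER_ANISOTROPY",
]

#: Acquisition timeline: 30-s clip at injection, then a second 30-s clip
#: from 5 min 55 s, with the destructive flash at 6 min.
DEFAULT_CLIPS = ((0.0, 30.0), (355.0, 385.0))

#: Fixed height : width : thickness proportions used to report a volume
#: as a diameter triple.  The product of the three factors is 1, so the
#: half-ellipsoid volume formula recovers the simulated volume exactly.
DIAMETER_ANISOTROPY = (1.2, 1.0, 1.0 / 1.2)


@dataclass(frozen=True)
class KineticParams:
    """Microbubble kinetic and flash-timing parameters.

    The circulating pool follows a gamma-variate first pass
    ``A (t/t_p)^alpha exp(alpha (1 - t/t_p))`` (peak ``A`` at
    ``t_p``) plus a recirculating pool that builds up with time constant
    ``washout_tau`` once the first pass has cleared and is treated as
    constant for the remainder of the exam (terminal clearance is slower
    than the exam and is not modelled).  Binding is linear:
    ``bound(t) = rho k_on integral_0^t circulating``.
    """

    bolus_amplitude: float = 100.0  # a.u., first-pass peak
    bolus_peak_time: float = 8.0  # s
    bolus_shape: float = 2.5  # dimensionless alpha > 0
    washout_tau: float = 45.0  # s, first-pass -> systemic pool transition
    recirculation_fraction: float = 0.25  # late plateau as fraction of peak
    rho: float = 1.0  # receptor density, dimensionless per pixel
    k_on: float = 0.025  # 1/(a.u. s)
    replenish_tau: float = 2.0  # s, post-flash in-plane refill
    flash_onset: float = 360.0  # s
    flash_duration: float = 1.0  # s

    def __post_init__(self) -> None:
        for name in ("bolus_peak_time", "washout_tau", "replenish_tau", "flash_duration"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.bolus_shape > 0:
            raise ParameterError("bolus_shape must be > 0")
        if self.bolus_amplitude < 0:
            raise ParameterError("bolus_amplitude must be >= 0")
        if not 0 <= self.recirculation_fraction <= 1:
            raise ParameterError("recirculation_fraction must lie in [0, 1]")
        if self.rho < 0:
            raise ParameterError("receptor density rho must be >= 0")
        if self.k_on < 0:
            raise ParameterError("k_on must be >= 0")
        if not self.flash_onset > self.bolus_peak_time:
            raise ParameterError("flash must occur after the bolus peak")

    @property
    def flash_end(self) -> float:
        return self.flash_onset + self.flash_duration


def _check_time_grid(time_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ParameterError("time grid must be a non-empty 1-D array")
    if t[0] < 0:
        raise ParameterError("time grid starts at injection (t >= 0)")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("time grid must be strictly increasing")
    return t


def circulating_kernel(params: KineticParams, t: np.ndarray) -> np.ndarray:
    """Unflashed circulating concentration (a.u.) at times ``t``."""
    t = np.asarray(t, dtype=float)
    tt = np.clip(t, 0.0, None) / params.bolus_peak_time
    a = params.bolus_shape
    with np.errstate(invalid="ignore"):
        first_pass = np.where(tt > 0, tt**a * np.exp(a * (1.0 - tt)), 0.0)
    # recirculation appears only after the first pass has swept through
    delay = 2.0 * params.bolus_peak_time
    mixed = -np.expm1(-np.clip(t - delay, 0.0, None) / params.washout_tau)
    return params.bolus_amplitude * (first_pass + params.recirculation_fraction * mixed)


def simulate_circulating(
    params: KineticParams, time_grid, apply_flash: bool = True
) -> np.ndarray:
    """Circulating-microbubble curve (a.u.) on a time grid.

    With ``apply_flash`` the in-plane pool is zeroed during the
    destructive flash and relaxes back toward the unflashed trajectory
    with time constant ``replenish_tau`` (fresh bubbles flowing in from
    out-of-plane blood).
    """
    t = _check_time_grid(time_grid)
    c = circulating_kernel(params, t)
    if apply_flash:
        in_flash = (t >= params.flash_onset) & (t < params.flash_end)
        c[in_flash] = 0.0
        after = t >= params.flash_end
        c[after] *= -np.expm1(-(t[after] - params.flash_end) / params.replenish_tau)
    return c


def simulate_bound(
    time_grid,
    circulating: np.ndarray,
    rho: float,
    k_on: float,
    flash_onset: float | None = None,
) -> np.ndarray:
    """Bound-microbubble curve: linear accumulation, destroyed at flash.

    ``bound(t) = rho k_on * integral_0^t circulating(s) ds`` before the
    flash; the flash detaches and destroys the bound pool, which does
    not re-form within the exam (post-flash rebinding of the depleted
    targeted agent is negligible on this time scale).
    """
    if rho < 0:
        raise ParameterError("receptor density rho must be >= 0")
    if k_on < 0:
        raise ParameterError("k_on must be >= 0")
    t = _check_time_grid(time_grid)
    c = np.asarray(circulating, dtype=float)
    if c.shape != t.shape:
        raise ParameterError("circulating curve must match the time grid")
    integral = cumulative_trapezoid(c, t, initial=0.0)
    bound = rho * k_on * integral
    if flash_onset is not None:
        bound[t >= flash_onset] = 0.0
    return bound


def make_phantom(
    shape: tuple = (64, 64),
    tumor_radius: float = 20.0,
    necrotic_fraction: float = 0.0,
    rho: float = 1.0,
    pad_rows: int = 8,
    center: tuple | None = None,
) -> TumorPhantom:
    """Build a deterministic disc phantom.

    The necrotic core is the ``necrotic_fraction`` of tumor pixels
    closest to the tumor center (count rounded to the nearest pixel), so
    noise-free non-enhanced-area readings are exact by construction.
    The reference pad occupies the top ``pad_rows`` image rows.
    """
    if not 0 <= necrotic_fraction <= 1:
        raise ParameterError("necrotic fraction must lie in [0, 1]")
    h, w = shape
    if center is None:
        center = (h * 0.60, w * 0.5)
    rr, cc = np.mgrid[0:h, 0:w]
    dist2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    tumor = dist2 <= tumor_radius**2
    pad = np.zeros(shape, dtype=bool)
    pad[:pad_rows] = True
    pad &= ~tumor

    n_tumor = int(tumor.sum())
    n_necrotic = int(round(necrotic_fraction * n_tumor))
    necrotic = np.zeros(shape, dtype=bool)
    if n_necrotic:
        flat_idx = np.flatnonzero(tumor.ravel())
        order = np.argsort(dist2.ravel()[flat_idx], kind="stable")
        necrotic.ravel()[flat_idx[order[:n_necrotic]]] = True

    receptor = np.where(tumor & ~necrotic, float(rho), 0.0)
    return TumorPhantom(tumor, necrotic, pad, receptor)


def render_cine(
    phantom: TumorPhantom,
    params: KineticParams,
    law: CompressionLaw,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_rate_hz: float = 10.0,
    clips=DEFAULT_CLIPS,
    gain: float = 1.0,
    background_power: float = 1.0,
    pixel_size_mm: float = 0.1,
) -> CineLoop:
    """Render a log-compressed 8-bit cine loop of the phantom.

    Per-pixel echo power is ``background + gain (C(t) + B(t) rho_px)``
    on perfused tumor pixels and the background level elsewhere
    (necrotic core, surrounding tissue, pad).  Speckle is multiplicative
    lognormal noise with the stated sd and unit mean.  Frames inside the
    flash interval are rendered saturated, as on the scanner.
    """
    if noise_sd < 0:
        raise ParameterError("noise sd must be >= 0")
    times = clip_times(clips, frame_rate_hz)
    if not (times[0] <= params.flash_onset <= times[-1]):
        raise ParameterError(
            f"flash at {params.flash_onset} s lies outside the exam "
            f"({times[0]}-{times[-1]} s)"
        )
    circ = simulate_circulating(params, times)
    circ_unflashed = simulate_circulating(params, times, apply_flash=False)
    bound_unit = simulate_bound(
        times, circ_unflashed, rho=1.0, k_on=params.k_on, flash_onset=params.flash_onset
    )

    perf = phantom.perfused_mask
    T = len(times)
    power = np.full((T,) + phantom.shape, float(background_power))
    power[:, perf] += gain * circ[:, None]
    power[:, perf] += gain * np.outer(bound_unit, phantom.receptor_map[perf])

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(power.shape)
        power *= np.exp(noise_sd * z - 0.5 * noise_sd**2)

    frames = log_compress(power, law)
    in_flash = (times >= params.flash_onset) & (times < params.flash_end)
    frames[in_flash] = law.levels - 1

    meta = {
        "frame_rate_hz": frame_rate_hz,
        "clips": [list(c) for c in clips],
        "flash_onset_s": params.flash_onset,
        "flash_duration_s": params.flash_duration,
        "compression_law": law.to_dict(),
        "pixel_size_mm": pixel_size_mm,
        "gain": gain,
        "background_power": background_power,
    }
    return CineLoop(frames, times, meta)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Which study days (0-based, unit intervals) the drug is given.

    Group 1 is continuous placebo; group 2 is treated on days 0-4 and
    again on days 9-12 (transient interruption); group 3 is treated on
    days 0-4 only (definitive stop).
    """

    group_id: int
    drug_on_days: frozenset

    _CANONICAL = {
        1: frozenset(),
        2: frozenset(range(0, 5)) | frozenset(range(9, 13)),
        3: frozenset(range(0, 5)),
    }

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_on_days", frozenset(self.drug_on_days))
        if self.group_id in self._CANONICAL and self.drug_on_days != self._CANONICAL[self.group_id]:
            raise ParameterError(
                f"group {self.group_id} has a fixed schedule "
                f"{sorted(self._CANONICAL[self.group_id])}"
            )

    @classmethod
    def placebo(cls) -> "TreatmentSchedule":
        return cls(1, cls._CANONICAL[1])

    @classmethod
    def interrupted(cls) -> "TreatmentSchedule":
        return cls(2, cls._CANONICAL[2])

    @classmethod
    def stopped(cls) -> "TreatmentSchedule":
        return cls(3, cls._CANONICAL[3])

    def daily_rate(self, day: int, gp: "GrowthParams") -> float:
        """Exponential growth rate (1/day) during day ``[day, day+1)``."""
        if day in self.drug_on_days:
            return gp.growth_rate_on_drug
        if self.drug_on_days and day > max(self.drug_on_days):
            # after the last drug day the stop is permanent: rebound
            return gp.rebound_multiplier * gp.growth_rate_untreated
        return gp.growth_rate_untreated


@dataclass(frozen=True)
class GrowthParams:
    """Exponential tumor-growth model with lognormal animal noise.

    Defaults are sized so the three schedules reproduce the qualitative
    day-13-vs-day-5 response pattern of a sorafenib-interruption
    experiment: near-stasis on drug, ~80 % growth off drug, and
    off-drug rebound slightly above the untreated rate after a
    definitive stop.
    """

    baseline_volume: float = 150.0  # mm^3 at day 0
    growth_rate_untreated: float = 0.075  # 1/day
    growth_rate_on_drug: float = 0.005  # 1/day
    rebound_multiplier: float = 1.05  # >= 1, applied after permanent stop
    animal_noise_sd: float = 0.15  # log-scale, per-animal baseline
    measurement_noise_sd: float | None = None  # log-scale per reading; default sd/2

    def __post_init__(self) -> None:
        if self.baseline_volume <= 0:
            raise ParameterError("baseline volume must be > 0")
        if not self.growth_rate_on_drug < self.growth_rate_untreated:
            raise ParameterError("on-drug growth rate must be below the untreated rate")
        if self.rebound_multiplier < 1:
            raise ParameterError("rebound multiplier must be >= 1")
        if self.animal_noise_sd < 0:
            raise ParameterError("animal noise sd must be >= 0")

    @property
    def reading_sd(self) -> float:
        if self.measurement_noise_sd is not None:
            return self.measurement_noise_sd
        return 0.5 * self.animal_noise_sd


def volume_to_diameters(volume: float) -> tuple:
    """Report a volume as (height, width, thickness) in mm.

    Uses the fixed anisotropy proportions; the half-ellipsoid formula
    ``h w t / 2`` applied to the triple returns ``volume`` exactly.
    """
    d = (2.0 * volume) ** (1.0 / 3.0)
    ah, aw, at = DIAMETER_ANISOTROPY
    return (ah * d, aw * d, at * d)


def simulate_growth_cohort(
    gp: GrowthParams,
    schedules,
    n_per_group,
    days=(0, 5, 9, 11, 13),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal diameter triples on the measurement days.

    Returns a table with columns ``animal_id, group, day, height_mm,
    width_mm, thickness_mm``.  Implied volumes follow piecewise
    exponential growth at the schedule-dependent daily rate with a
    lognormal per-animal baseline effect and a smaller lognormal
    per-reading measurement error (half the animal sd, so zero animal
    noise implies exactly identical trajectories).
    """
    schedules = list(schedules)
    if not schedules:
        raise ParameterError("at least one treatment schedule is required")
    n_per_group = list(n_per_group)
    if len(n_per_group) != len(schedules):
        raise ParameterError("one group size per schedule required")
    if any(n < 1 for n in n_per_group):
        raise ParameterError("each group needs at least one animal")
    days = sorted(int(d) for d in days)

    rng = np.random.default_rng(seed)
    rows = []
    for sched, n in zip(schedules, n_per_group):
        # cumulative log-growth from day 0 to each measurement day
        max_day = days[-1]
        rates = np.array([sched.daily_rate(k, gp) for k in range(max_day)])
        cum = np.concatenate([[0.0], np.cumsum(rates)])
        for i in range(n):
            v0 = gp.baseline_volume * np.exp(rng.normal(0.0, gp.animal_noise_sd))
            for day in days:
                v = v0 * np.exp(cum[day])
                v *= np.exp(rng.normal(0.0, gp.reading_sd)) if gp.reading_sd > 0 else 1.0
                h, w, t = volume_to_diameters(v)
                rows.append(
                    {
                        "animal_id": f"g{sched.group_id}m{i + 1:02d}",
                        "group": sched.group_id,
                        "day": day,
                        "height_mm": h,
                        "width_mm": w,
                        "thickness_mm": t,
                    }
                )
    return pd.DataFrame(rows)


def simulate_strain_pair(
    true_ratio: float,
    noise_sd: float,
    phantom: TumorPhantom,
    seed: int = 0,
    n_replicates: int = 3,
    pad_strain: float = 1.0,
) -> StrainPair:
    """Simulate co-registered tumor/pad strain replicates.

    The pad region has constant strain ``pad_strain`` (its consistency
    is known and homogeneous); the tumor region has strain
    ``pad_strain * true_ratio`` plus zero-mean Gaussian pixel noise of
    the stated sd.  Replicates differ only by noise.
    """
    if not true_ratio > 0:
        raise ParameterError("true strain ratio must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = phantom.shape
    strains = np.full((n_replicates, h, w), float(pad_strain))
    tumor = phantom.tumor_mask
    for r in range(n_replicates):
        field = np.full(tumor.sum(), pad_strain * true_ratio)
        if noise_sd > 0:
            field = field + rng.normal(0.0, noise_sd, size=field.shape)
        strains[r][tumor] = field
    return StrainPair(strains, phantom.tumor_mask, phantom.pad_mask)
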