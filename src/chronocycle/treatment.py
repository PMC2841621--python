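"""Drug-induced death-rate time courses.

A cell-cycle phase-specific (CCS) drug is represented directly by the extra
death rate it induces in its target phase (no pharmacokinetic compartment:
concentration is identified with killing rate).  A chronomodulated course is
a train of truncated-Gaussian pulses, one per administration; the flat
(constant-infusion) control is normalised to deliver the same 24 h-integrated
hazard as one chronomodulated day.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.special import erf

from .model import CellCyclePreset, DeathRateProfile

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class Schedule:
    """One course of drug administration.

    ``start_time`` is the clock time (hours-of-day) of the first
    administration's peak; the course is anchored in absolute time on day
    ``first_day`` (default 3, i.e. after the 72 h transient), so the first
    pulse is centred at ``24*first_day + start_time``.  Subsequent pulses
    follow at ``interval`` hours; for non-24 h intervals their clock times
    drift as t0 + j*interval mod 24.
    """

    target_phase: str = "S"
    start_time: float = 4.0
    interval: float = 24.0
    n_admin: int = 5
    k_max: float = 0.06
    infusion_width: float = 2.3
    truncation: float = 2.5
    mode: str = "chrono"
    first_day: int = 3

    def __post_init__(self) -> None:
        if self.target_phase not in ("G1", "S", "G2M"):
            raise ValueError("target_phase must be G1, S or G2M")
        if not 0.0 <= self.start_time < 24.0:
            raise ValueError("start_time must be in [0, 24)")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.n_admin < 1:
            raise ValueError("n_admin must be >= 1")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.infusion_width <= 0 or self.truncation <= 0:
            raise ValueError("infusion_width and truncation must be > 0")
        if self.mode not in ("chrono", "flat"):
            raise ValueError("mode must be 'chrono' or 'flat'")

    def replace(self, **kw) -> "Schedule":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return Schedule(**d)

    @property
    def centers(self) -> np.ndarray:
        """Absolute times of the administration peaks."""
        t0 = 24.0 * self.first_day + self.start_time
        return t0 + self.interval * np.arange(self.n_admin)

    @property
    def pulse_area(self) -> float:
        """Integral of a single pulse (k_max times the unit-peak area)."""
        w, c = self.infusion_width, self.truncation
        eps = np.exp(-c * c / 2.0)
        gauss = w * np.sqrt(2.0 * np.pi) * erf(c / _SQRT2)
        return self.k_max * (gauss - 2.0 * c * w * eps) / (1.0 - eps)

    @property
    def support_radius(self) -> float:
        return self.truncation * self.infusion_width


def _pulse_shape(x, width: float, cutoff: float):
    """Unit-peak truncated Gaussian, continuous at the cutoff:
    (exp(-x^2/2w^2) - eps) / (1 - eps) on |x| <= c w, zero outside."""
    eps = np.exp(-cutoff * cutoff / 2.0)
    val = (np.exp(-x * x / (2.0 * width * width)) - eps) / (1.0 - eps)
    return np.where(np.abs(x) <= cutoff * width, val, 0.0)


def _pulse_cumulative(x, width: float, cutoff: float):
    """Antiderivative of the unit-peak truncated Gaussian, from -inf."""
    eps = np.exp(-cutoff * cutoff / 2.0)
    xc = np.clip(x, -cutoff * width, cutoff * width)
    gauss = width * np.sqrt(np.pi / 2.0) * (erf(xc / (width * _SQRT2))
                                            + erf(cutoff / _SQRT2))
    return (gauss - eps * (xc + cutoff * width)) / (1.0 - eps)


def chrono_death_rate(t, schedule: Schedule):
    """Chronomodulated drug-induced death rate at absolute time t (1/h).

    Sum over administrations of k_max times a unit-peak Gaussian of spread
    ``infusion_width`` truncated to zero beyond ``truncation`` spreads.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    w, c0 = schedule.infusion_width, schedule.truncation
    for c in schedule.centers:
        out = out + schedule.k_max * _pulse_shape(t - c, w, c0)
    return out if out.ndim else float(out)


def chrono_cumulative(t, schedule: Schedule):
    """Integral of ``chrono_death_rate`` from -inf to t, in closed form."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c in schedule.centers:
        out = out + schedule.k_max * _pulse_cumulative(
            t - c, schedule.infusion_width, schedule.truncation)
    return out if out.ndim else float(out)


def flat_equivalent_rate(schedule: Schedule) -> float:
    """Constant rate delivering one pulse's integrated hazard spread over 24 h."""
    return schedule.pulse_area / 24.0


def flat_death_rate(t, schedule: Schedule):
    """Flat-infusion death rate: k_flat over the course span [t_first, t_first + 24 n)."""
    t = np.asarray(t, dtype=float)
    t0 = schedule.centers[0]
    k = flat_equivalent_rate(schedule)
    out = np.where((t >= t0) & (t < t0 + 24.0 * schedule.n_admin), k, 0.0)
    return out if out.ndim else float(out)


def flat_cumulative(t, schedule: Schedule):
    t = np.asarray(t, dtype=float)
    t0 = schedule.centers[0]
    k = flat_equivalent_rate(schedule)
    out = k * np.clip(t - t0, 0.0, 24.0 * schedule.n_admin)
    return out if out.ndim else float(out)


def effective_death_rates(preset: CellCyclePreset,
                          schedule: Schedule | None) -> DeathRateProfile:
    """Basal apoptosis rates plus the schedule's drug component on its target phase."""
    profile = DeathRateProfile.basal(preset)
    if schedule is None or schedule.k_max == 0.0:
        return profile
    if schedule.mode == "chrono":
        rate = lambda t: chrono_death_rate(t, schedule)
        cum = lambda t: chrono_cumulative(t, schedule)
    else:
        rate = lambda t: flat_death_rate(t, schedule)
        cum = lambda t: flat_cumulative(t, schedule)
    profile.target = schedule.target_phase
    profile.drug_rate = rate
    profile.drug_cumulative = cum
    return profile


def periodic_death_rates(preset: CellCyclePreset, schedule: Schedule,
                         t_span: tuple[float, float]) -> DeathRateProfile:
    """Death profile for an idealised fully periodic course: one pulse per
    ``interval`` for every j such that the pulse intersects ``t_span``.

    Used by the analytic treatment-outcome machinery, which works one period
    at a time.
    """
    lo, hi = t_span
    r = schedule.support_radius
    j0 = int(np.floor((lo - r - schedule.start_time) / schedule.interval)) - 1
    j1 = int(np.ceil((hi + r - schedule.start_time) / schedule.interval)) + 1
    centers = schedule.start_time + schedule.interval * np.arange(j0, j1 + 1)
    w, c = schedule.infusion_width, schedule.truncation

    def rate(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for cj in centers:
            out = out + schedule.k_max * _pulse_shape(t - cj, w, c)
        return out

    def cum(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for cj in centers:
            out = out + schedule.k_max * _pulse_cumulative(t - cj, w, c)
        return out

    profile = DeathRateProfile.basal(preset)
    profile.target = schedule.target_phase
    profile.drug_rate = rate
    profile.drug_cumulative = cum
    return profile
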