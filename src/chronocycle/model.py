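"""Cell-cycle kinetics under circadian control.

The population is structured into four phases: G0/G1 (exponentially
distributed residence, exit rate kappa(t) toward S plus a permanent loss
rate gamma), then S, G2 and M with fixed (G2: clock-modulated) durations.
The circadian clock enters through two 24 h-periodic quantities: the G1->S
transition rate kappa(t) and the G2 duration T_G2(t).  Everything here is a
pure function of time and parameters; the delay-differential dynamics live
in :mod:`chronocycle.simulate`.

Time convention: absolute simulation time in hours, clock time = t mod 24,
0:00 = midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np

HOURS_PER_DAY = 24.0
_TWO_PI = 2.0 * np.pi

PHASES = ("G1", "S", "G2", "M")


@dataclass(frozen=True)
class CircadianInput:
    """Sinusoidal circadian reference oscillator C(t) = 1 + a cos(w (t - psi)).

    Parameters
    ----------
    amplitude_coeff : relative amplitude a, dimensionless, 0 <= a < 1.
    phase_shift : clock time psi (hours-of-day) of the daily maximum.
    period : hours; fixed at 24.
    """

    amplitude_coeff: float = 0.2
    phase_shift: float = 14.0
    period: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_coeff < 1.0:
            raise ValueError("amplitude_coeff must be in [0, 1)")
        if not 0.0 <= self.phase_shift < 24.0:
            raise ValueError("phase_shift must be in [0, 24)")
        if self.period != 24.0:
            raise ValueError("period is fixed at 24 h")


def circadian_modulation(t, circ: CircadianInput = CircadianInput()):
    """Circadian factor C(t), 24 h-periodic with unit mean and peak at psi."""
    t = np.asarray(t, dtype=float)
    w = _TWO_PI / circ.period
    out = 1.0 + circ.amplitude_coeff * np.cos(w * (t - circ.phase_shift))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CellCyclePreset:
    """All kinetic and circadian-coupling parameters for one cell population.

    Rates are per hour, durations in hours, modulation amplitudes are
    dimensionless relative amplitudes in [0, 1), modulation phases are clock
    times (hours-of-day) of the daily peak.
    """

    kappa_mean: float
    g1_loss_rate: float
    ts: float
    tg2_mean: float
    tm: float
    death_s: float = 0.001
    death_g2: float = 0.001
    death_m: float = 0.001
    kappa_mod_amp: float = 0.0
    kappa_mod_phase: float = 14.0
    g2_mod_amp: float = 0.0
    g2_mod_phase: float = 14.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("kappa_mean", "g1_loss_rate", "death_s", "death_g2", "death_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ts", "tg2_mean", "tm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("kappa_mod_amp", "g2_mod_amp"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("kappa_mod_phase", "g2_mod_phase"):
            if not 0.0 <= getattr(self, name) < 24.0:
                raise ValueError(f"{name} must be in [0, 24)")
        # |dT/dt| < 1 over the day, so that cohorts dividing later also
        # entered S later (the delayed argument stays ordered).
        slope = self.tg2_mean * self.g2_mod_amp * _TWO_PI / HOURS_PER_DAY
        if slope >= 1.0:
            raise ValueError(
                "G2 modulation violates delay monotonicity: "
                f"max |dT/dt| = {slope:.3f} >= 1"
            )

    def replace(self, **kw) -> "CellCyclePreset":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return CellCyclePreset(**d)


def g1s_transition_rate(t, preset: CellCyclePreset,
                        circ: CircadianInput | None = None):
    """G1->S transition rate kappa(t) = kappa_mean (1 + a_k cos(w (t - t_k)))."""
    period = circ.period if circ is not None else HOURS_PER_DAY
    t = np.asarray(t, dtype=float)
    w = _TWO_PI / period
    out = preset.kappa_mean * (
        1.0 + preset.kappa_mod_amp * np.cos(w * (t - preset.kappa_mod_phase))
    )
    return out if out.ndim else float(out)


def g2_duration(t, preset: CellCyclePreset):
    """Clock-modulated G2 duration T_G2(t) > 0 (multiplicative modulation)."""
    t = np.asarray(t, dtype=float)
    w = _TWO_PI / HOURS_PER_DAY
    out = preset.tg2_mean * (
        1.0 + preset.g2_mod_amp * np.cos(w * (t - preset.g2_mod_phase))
    )
    return out if out.ndim else float(out)


def sgm_total_delay(t_div, preset: CellCyclePreset):
    """Total S+G2+M transit time T(t_div) attributed to the cohort dividing at t_div."""
    g2 = g2_duration(t_div, preset)
    return preset.ts + g2 + preset.tm


def entry_time(t_div, preset: CellCyclePreset):
    """S-entry time of the cohort dividing at t_div: t_div - T(t_div).

    Strictly increasing in t_div whenever the preset satisfies the
    delay-monotonicity invariant (enforced at construction).
    """
    t_div = np.asarray(t_div, dtype=float)
    out = t_div - sgm_total_delay(t_div, preset)
    return out if out.ndim else float(out)


def division_time(t_entry, preset: CellCyclePreset,
                  bracket_width: float | None = None) -> float:
    """Invert ``entry_time``: the division time of the cohort entering S at t_entry.

    Scalar root-find; for array work the simulator inverts a tabulated
    entry-time grid instead.
    """
    from scipy.optimize import brentq

    tmin = preset.ts + preset.tg2_mean * (1 - preset.g2_mod_amp) + preset.tm
    tmax = preset.ts + preset.tg2_mean * (1 + preset.g2_mod_amp) + preset.tm
    if bracket_width is not None:
        tmin, tmax = tmin - bracket_width, tmax + bracket_width
    f = lambda td: entry_time(td, preset) - t_entry
    return brentq(f, t_entry + tmin - 1e-9, t_entry + tmax + 1e-9, xtol=1e-12)


@dataclass
class DeathRateProfile:
    """Per-phase death rates: constant basal apoptosis plus an optional
    drug-induced component attached to exactly one target phase.

    ``drug_rate``/``drug_cumulative`` are vectorised functions of absolute
    time; the cumulative is an antiderivative of the rate (its zero point is
    irrelevant, only differences are used).  ``target`` is one of
    ``"G1"``, ``"S"``, ``"G2M"`` or ``None``.
    """

    base_rates: dict = field(default_factory=lambda: {p: 0.0 for p in PHASES})
    target: str | None = None
    drug_rate: Callable | None = None
    drug_cumulative: Callable | None = None

    def _targets(self, phase: str) -> bool:
        if self.target is None or self.drug_rate is None:
            return False
        return phase in (("G2", "M") if self.target == "G2M" else (self.target,))

    def rate(self, phase: str, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.base_rates.get(phase, 0.0))
        if self._targets(phase):
            out = out + self.drug_rate(t)
        return out if out.ndim else float(out)

    def cumulative(self, phase: str, t):
        """Integral of the phase death rate from time 0 to t (vectorised)."""
        t = np.asarray(t, dtype=float)
        out = self.base_rates.get(phase, 0.0) * t
        if self._targets(phase):
            out = out + self.drug_cumulative(t)
        return out if out.ndim else float(out)

    @classmethod
    def basal(cls, preset: CellCyclePreset) -> "DeathRateProfile":
        return cls(base_rates={"G1": 0.0, "S": preset.death_s,
                               "G2": preset.death_g2, "M": preset.death_m})


def stage_survival(t_div, preset: CellCyclePreset, death: DeathRateProfile):
    """Fraction sigma(t_div) in (0, 1] of the cohort dividing at t_div that
    survived its S, G2 and M transit.

    The cohort entered S at e = t_div - T(t_div); the phase windows are
    S: [e, e+T_S], G2: [e+T_S, t_div-T_M], M: [t_div-T_M, t_div], and each
    phase-specific death rate is integrated over its own window.
    """
    t_div = np.asarray(t_div, dtype=float)
    e = t_div - sgm_total_delay(t_div, preset)
    s_end = e + preset.ts
    m_start = t_div - preset.tm
    hazard = (
        death.cumulative("S", s_end) - death.cumulative("S", e)
        + death.cumulative("G2", m_start) - death.cumulative("G2", s_end)
        + death.cumulative("M", t_div) - death.cumulative("M", m_start)
    )
    out = np.exp(-hazard)
    return out if np.ndim(out) else float(out)
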