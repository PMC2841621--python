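"""Treatment responses and the outcome score E.

The response of a population to a course is the ratio of treated to
untreated total cell number, evaluated 7 days (168 h) after the first
administration, both runs sharing kinetics, initial state, transient and
step size.  The outcome score E = R_H - R_C balances host tolerance (R_H
high) against anti-tumor efficacy (R_C low); it is the Taylor limit of any
smooth score that increases with host survival and decreases with tumor
survival, and larger E means a better trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CellCyclePreset, CircadianInput
from .simulate import integrate_g1, reconstruct_compartments
from .treatment import Schedule, effective_death_rates

RESPONSE_HORIZON = 168.0  # hours after the first administration


@dataclass(frozen=True)
class OutcomeResult:
    r_host: float
    r_tumor: float
    score: float
    start_time: float
    interval: float


@dataclass
class ScanGrid:
    """A labelled 1-D or 2-D grid of outcome/response values."""

    axis1_name: str
    axis1: np.ndarray
    values: np.ndarray
    axis2_name: str | None = None
    axis2: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (len(self.axis1),) if self.axis2 is None \
            else (len(self.axis1), len(self.axis2))
        if tuple(np.shape(self.values)) != expected:
            raise ValueError("value matrix dimensions do not match axes")

    def to_frame(self) -> pd.DataFrame:
        if self.axis2 is None:
            return pd.DataFrame({self.axis1_name: self.axis1,
                                 "value": self.values})
        return pd.DataFrame(self.values,
                            index=pd.Index(self.axis1, name=self.axis1_name),
                            columns=pd.Index(self.axis2, name=self.axis2_name))


def batched_responses(preset: CellCyclePreset,
                      circ: CircadianInput | None,
                      schedules: list[Schedule],
                      dt: float = 0.01,
                      horizon: float = RESPONSE_HORIZON) -> np.ndarray:
    """Responses R for many schedules of one population in a single pass.

    R = N_treated / N_untreated at first administration + ``horizon``; the
    untreated reference is integrated in the same batch (last column).
    """
    profiles = [effective_death_rates(preset, s) for s in schedules]
    profiles.append(effective_death_rates(preset, None))
    t_first = np.array([s.centers[0] for s in schedules])
    t_eval = t_first + horizon
    t_end = float(np.ceil((t_eval.max() + dt) / dt)) * dt
    run = integrate_g1(preset, profiles, t_end=t_end, dt=dt, circ=circ)
    n_s, n_g2, n_m = reconstruct_compartments(run)
    total = run.n_g1 + n_s + n_g2 + n_m
    treated = np.array([np.interp(t_eval[b], run.times, total[:, b])
                        for b in range(len(schedules))])
    ref = np.interp(t_eval, run.times, total[:, -1])
    return treated / ref


def response(preset: CellCyclePreset,
             circ: CircadianInput | None,
             schedule: Schedule,
             dt: float = 0.01,
             horizon: float = RESPONSE_HORIZON) -> float:
    """Normalized cell number R in (0, 1]: treated over untreated total,
    ``horizon`` hours after the first administration."""
    return float(batched_responses(preset, circ, [schedule], dt=dt,
                                   horizon=horizon)[0])


def outcome_score(r_host: float, r_tumor: float, form: str = "difference") -> float:
    """Outcome E; ``difference`` gives E = R_H - R_C (default), ``log`` the
    log-ratio log(R_H/R_C).  Antisymmetric under swapping the arguments."""
    if r_host <= 0 or r_tumor <= 0:
        raise ValueError("responses must be > 0")
    if form == "difference":
        return r_host - r_tumor
    if form == "log":
        return float(np.log(r_host) - np.log(r_tumor))
    raise ValueError("form must be 'difference' or 'log'")


@dataclass
class TimingScan:
    """E, R_H, R_C over administration start time, plus extrema/plateaus."""

    start_times: np.ndarray
    e: np.ndarray
    r_host: np.ndarray
    r_tumor: np.ndarray
    best: float | None
    worst: float | None
    flat: bool
    best_plateau: tuple | None = None
    worst_plateau: tuple | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start_time": self.start_times, "E": self.e,
                             "R_H": self.r_host, "R_C": self.r_tumor})

    def summary(self) -> dict:
        return {"best": self.best, "worst": self.worst, "flat": self.flat,
                "best_plateau": self.best_plateau,
                "worst_plateau": self.worst_plateau}


def _plateau(times: np.ndarray, values: np.ndarray, idx: int,
             tol: float = 1e-3) -> tuple | None:
    """Clock-time range around ``idx`` over which adjacent values vary < tol."""
    n = len(times)
    lo = idx
    while abs(values[(lo - 1) % n] - values[lo % n]) < tol and (idx - lo) < n:
        lo -= 1
    hi = idx
    while abs(values[(hi + 1) % n] - values[hi % n]) < tol and (hi - idx) < n:
        hi += 1
    if lo == idx and hi == idx:
        return None
    return (times[lo % n], times[hi % n])


def scan_treatment_time(host: CellCyclePreset,
                        tumor: CellCyclePreset,
                        circ: CircadianInput | None,
                        schedule_template: Schedule,
                        grid_step: float = 0.5,
                        dt: float = 0.01,
                        score_form: str = "difference") -> TimingScan:
    """Outcome E over first-administration clock time, interval fixed at 24 h.

    Returns the grid with argmax/argmin; if E is flat (k_max = 0 or
    variation below the plateau tolerance everywhere) the extrema are
    flagged undefined.
    """
    if abs(24.0 / grid_step - round(24.0 / grid_step)) > 1e-9:
        raise ValueError("grid_step must divide 24")
    starts = np.arange(0.0, 24.0, grid_step)
    schedules = [schedule_template.replace(start_time=float(t0), interval=24.0)
                 for t0 in starts]
    r_h = batched_responses(host, circ, schedules, dt=dt)
    r_c = batched_responses(tumor, circ, schedules, dt=dt)
    e = np.array([outcome_score(h, c, form=score_form) for h, c in zip(r_h, r_c)])
    flat = bool(e.max() - e.min() < 1e-3)
    if flat:
        return TimingScan(starts, e, r_h, r_c, None, None, True)
    i_best, i_worst = int(np.argmax(e)), int(np.argmin(e))
    return TimingScan(starts, e, r_h, r_c,
                      float(starts[i_best]), float(starts[i_worst]), False,
                      _plateau(starts, e, i_best), _plateau(starts, e, i_worst),
                      metadata={"grid_step": grid_step, "dt": dt,
                                "host": host.label, "tumor": tumor.label})
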