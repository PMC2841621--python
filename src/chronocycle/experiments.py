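"""Reproduction-scale computational experiments and preset calibration.

Scans of treatment timing against S-phase duration and against
inter-administration interval, the best/worst-times table for the three drug
target phases crossed with the two tumor phenotypes, and the bounded
optimisation that fixes the shipped presets from daily S-phase-fraction
targets.  Figures are produced as data (CSV grids + JSON summaries);
plotting is left to the user.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import CellCyclePreset, CircadianInput
from .outcome import ScanGrid, batched_responses, outcome_score, scan_treatment_time
from .simulate import phase_fractions, simulate
from .tato import (TatoPrediction, circular_distance, outcome_extrema,
                   periodic_growth_contribution, s_phase_extrema)
from .treatment import Schedule

TARGET_PHASES = ("G1", "S", "G2M")


def _manifest(**kw) -> dict:
    doc = {}
    for key, val in kw.items():
        if isinstance(val, CellCyclePreset):
            text = json.dumps(vars(val), sort_keys=True, default=float)
            doc[key] = {"label": val.label,
                        "sha1": hashlib.sha1(text.encode()).hexdigest(),
                        "params": json.loads(text)}
        elif isinstance(val, Schedule):
            doc[key] = vars(val).copy()
        elif isinstance(val, np.ndarray):
            doc[key] = val.tolist()
        else:
            doc[key] = val
    return doc


# ---------------------------------------------------------------------------
# S-phase-duration vs administration-time scan

def scan_duration_vs_time(preset_base: CellCyclePreset,
                          circ: CircadianInput | None,
                          schedule_template: Schedule,
                          ts_grid,
                          time_grid,
                          dt: float = 0.02) -> dict:
    """Host response to an S-phase drug over (T_S, start time).

    For each S-phase duration the full-simulation response and the TATO
    integral are evaluated over administration time; both grids are min-max
    normalised to [0, 1], and the closed-form extrema curves are attached.
    """
    ts_grid = np.asarray(ts_grid, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    sim = np.empty((len(ts_grid), len(time_grid)))
    tat = np.empty_like(sim)
    for i, ts in enumerate(ts_grid):
        preset = preset_base.replace(ts=float(ts))
        schedules = [schedule_template.replace(start_time=float(t0), interval=24.0)
                     for t0 in time_grid]
        sim[i] = batched_responses(preset, circ, schedules, dt=dt)
        tat[i] = periodic_growth_contribution(
            preset, circ, schedule_template.replace(interval=24.0),
            time_grid, n_quad=1024)

    def norm(m):
        lo, hi = m.min(), m.max()
        return (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)

    extrema = pd.DataFrame({
        "ts": ts_grid,
        "max_kill": [(s_phase_extrema(preset_base.kappa_mod_phase, ts).worst_time
                      if abs(ts % 24.0) > 1e-9 else np.nan) for ts in ts_grid],
        "max_spare": [(s_phase_extrema(preset_base.kappa_mod_phase, ts).best_time
                       if abs(ts % 24.0) > 1e-9 else np.nan) for ts in ts_grid],
    })
    grid_kwargs = dict(axis1_name="ts", axis1=ts_grid,
                       axis2_name="start_time", axis2=time_grid)
    return {
        "simulation": ScanGrid(values=norm(sim), **grid_kwargs),
        "tato": ScanGrid(values=norm(tat), **grid_kwargs),
        "extrema": extrema,
        "manifest": _manifest(preset=preset_base, schedule=schedule_template,
                              dt=dt, ts_grid=ts_grid, time_grid=time_grid),
    }


# ---------------------------------------------------------------------------
# interval vs start-time scan

def scan_interval_vs_start(host: CellCyclePreset,
                           tumor: CellCyclePreset,
                           circ: CircadianInput | None,
                           schedule_template: Schedule,
                           interval_grid,
                           start_grid,
                           dt: float = 0.02,
                           normalized: bool = True) -> dict:
    """Outcome over (first-day start time, inter-administration interval).

    The administered quantity and infusion profile are identical at every
    interval (n_admin fixed); only the timing changes.  With
    ``normalized`` the responses are min-max scaled over the whole grid
    before differencing.  Returns the E grid, the per-interval
    timing amplitude (max - min over start), and the global best/worst.
    """
    interval_grid = np.asarray(interval_grid, dtype=float)
    start_grid = np.asarray(start_grid, dtype=float)
    r_h = np.empty((len(interval_grid), len(start_grid)))
    r_c = np.empty_like(r_h)
    for i, interval in enumerate(interval_grid):
        schedules = [schedule_template.replace(start_time=float(t0),
                                               interval=float(interval))
                     for t0 in start_grid]
        r_h[i] = batched_responses(host, circ, schedules, dt=dt)
        r_c[i] = batched_responses(tumor, circ, schedules, dt=dt)
    if normalized:
        def scale(m):
            lo, hi = m.min(), m.max()
            return (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)
        e = scale(r_h) - scale(r_c)
    else:
        e = r_h - r_c
    amplitude = e.max(axis=1) - e.min(axis=1)
    i_best = np.unravel_index(np.argmax(e), e.shape)
    i_worst = np.unravel_index(np.argmin(e), e.shape)
    grid_kwargs = dict(axis1_name="interval", axis1=interval_grid,
                       axis2_name="start_time", axis2=start_grid)
    return {
        "E": ScanGrid(values=e, **grid_kwargs),
        "R_H": ScanGrid(values=r_h, **grid_kwargs),
        "R_C": ScanGrid(values=r_c, **grid_kwargs),
        "amplitude": pd.Series(amplitude, index=interval_grid, name="amplitude"),
        "best": {"interval": float(interval_grid[i_best[0]]),
                 "start_time": float(start_grid[i_best[1]]), "E": float(e[i_best])},
        "worst": {"interval": float(interval_grid[i_worst[0]]),
                  "start_time": float(start_grid[i_worst[1]]), "E": float(e[i_worst])},
        "manifest": _manifest(host=host, tumor=tumor, schedule=schedule_template,
                              dt=dt, interval_grid=interval_grid,
                              start_grid=start_grid),
    }


# ---------------------------------------------------------------------------
# best/worst table

@dataclass
class BestWorstTable:
    """Best and worst administration times per target phase and tumor, from
    full simulation and from the analytic outcome prediction."""

    rows: pd.DataFrame
    scans: dict = field(default_factory=dict)

    def max_sim_tato_discrepancy(self) -> float:
        return float(max(circular_distance(r.best_sim, r.best_tato)
                         for r in self.rows.itertuples()))

    def max_fast_slow_spread(self) -> float:
        out = 0.0
        for phase in self.rows.phase.unique():
            sub = self.rows[self.rows.phase == phase].set_index("tumor")
            out = max(out, circular_distance(sub.loc["fast", "best_sim"],
                                             sub.loc["slow", "best_sim"]))
        return float(out)


def best_worst_table(host: CellCyclePreset,
                     tumor_fast: CellCyclePreset,
                     tumor_slow: CellCyclePreset,
                     circ: CircadianInput | None,
                     schedule_template: Schedule,
                     grid_step: float = 0.5,
                     dt: float = 0.01,
                     phases=TARGET_PHASES) -> BestWorstTable:
    """Scan E over start time for each target phase x tumor phenotype and
    pair the simulated extrema with the analytic prediction."""
    rows, scans = [], {}
    for phase in phases:
        template = schedule_template.replace(target_phase=phase, interval=24.0)
        for name, tumor in (("fast", tumor_fast), ("slow", tumor_slow)):
            scan = scan_treatment_time(host, tumor, circ, template,
                                       grid_step=grid_step, dt=dt)
            pred = outcome_extrema(host, tumor, circ, template)
            rows.append({"phase": phase, "tumor": name,
                         "best_sim": scan.best, "worst_sim": scan.worst,
                         "best_tato": pred.best_time, "worst_tato": pred.worst_time,
                         "best_plateau": scan.best_plateau,
                         "worst_plateau": scan.worst_plateau})
            scans[(phase, name)] = scan
    return BestWorstTable(rows=pd.DataFrame(rows), scans=scans)


# ---------------------------------------------------------------------------
# preset calibration

@dataclass(frozen=True)
class CalibrationTarget:
    """Daily S-phase-fraction behaviour one preset must reproduce."""

    frac_min: float
    frac_max: float
    peak_time: float | None = None  # clock time of the daily S-fraction peak


def s_fraction_stats(preset: CellCyclePreset,
                     circ: CircadianInput | None = None,
                     dt: float = 0.02,
                     window: tuple[float, float] = (72.0, 144.0)) -> dict:
    """Daily min/max of the S-phase fraction and the clock time of its peak,
    measured on the post-transient part of an untreated run."""
    traj = simulate(preset, circ=circ, t_end=window[1], dt=dt)
    fr = phase_fractions(traj)
    sel = (fr.time >= window[0]) & (fr.time <= window[1])
    fs = fr.frac_s[sel].to_numpy()
    tt = fr.time[sel].to_numpy()
    i = int(np.argmax(fs))
    # quadratic refinement of the peak clock time
    if 0 < i < len(fs) - 1:
        denom = fs[i - 1] - 2 * fs[i] + fs[i + 1]
        shift = 0.5 * (fs[i - 1] - fs[i + 1]) / denom if denom != 0 else 0.0
        peak = (tt[i] + shift * dt) % 24.0
    else:
        peak = tt[i] % 24.0
    return {"min": float(fs.min()), "max": float(fs.max()),
            "peak_time": float(peak)}


def _residuals(stats: dict, target: CalibrationTarget) -> float:
    res = ((stats["min"] - target.frac_min) / 0.01) ** 2 \
        + ((stats["max"] - target.frac_max) / 0.01) ** 2
    if target.peak_time is not None:
        res += (circular_distance(stats["peak_time"], target.peak_time) / 0.25) ** 2
    return res


def calibrate_preset(start: CellCyclePreset,
                     target: CalibrationTarget,
                     circ: CircadianInput | None = None,
                     dt: float = 0.02,
                     tol: float = 1.0,
                     maxiter: int = 200) -> tuple[CellCyclePreset, dict]:
    """Tune (kappa_mean, kappa_mod_amp, kappa_mod_phase) by bounded
    Nelder-Mead against the simulated S-fraction statistics.

    Deterministic (fixed start, fixed optimizer settings, no randomness).
    If the starting preset already meets the target within ``tol`` the
    optimizer is skipped, so calibration is idempotent.  Raises if the final
    residual exceeds ``tol``.
    """
    stats0 = s_fraction_stats(start, circ, dt=dt)
    if _residuals(stats0, target) < tol:
        return start, {"residual": _residuals(stats0, target), "stats": stats0,
                       "converged": True, "skipped": True}

    def build(x):
        kap, amp, phase = x
        return start.replace(kappa_mean=float(kap),
                             kappa_mod_amp=float(np.clip(amp, 0.0, 0.95)),
                             kappa_mod_phase=float(phase % 24.0))

    def objective(x):
        if not (1e-4 <= x[0] <= 1.0 and 0.0 <= x[1] < 0.95):
            return 1e6
        return _residuals(s_fraction_stats(build(x), circ, dt=dt), target)

    x0 = np.array([start.kappa_mean, start.kappa_mod_amp, start.kappa_mod_phase])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-3, "maxiter": maxiter})
    preset = build(res.x)
    stats = s_fraction_stats(preset, circ, dt=dt)
    resid = _residuals(stats, target)
    if resid > tol:
        raise RuntimeError(
            f"calibration failed for {start.label!r}: residual {resid:.2f} "
            f"(stats {stats}, target {target})")
    return preset, {"residual": resid, "stats": stats, "converged": True,
                    "skipped": False, "n_eval": int(res.nfev)}


def calibrate_presets(specs: dict,
                      circ: CircadianInput | None = None,
                      out_dir=None,
                      dt: float = 0.02) -> dict:
    """Calibrate several presets; ``specs`` maps label -> (start_preset,
    CalibrationTarget).  Optionally writes YAML files with the calibration
    report attached."""
    from .presets import save_preset

    out = {}
    for label, (start, target) in specs.items():
        preset, report = calibrate_preset(start, target, circ=circ, dt=dt)
        preset = preset.replace(label=label)
        out[label] = (preset, report)
        if out_dir is not None:
            path = Path(out_dir) / f"{label}.yaml"
            save_preset(preset, path, extra={"calibration": {
                "target": vars(target), "residual": report["residual"],
                "stats": report["stats"]}})
    return out
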