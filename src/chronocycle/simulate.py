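"""Integration of the delayed cell-population balance equations.

The model is linear, so the whole population follows from the G0/G1 count
alone.  We integrate the flux formulation

    dN_G1/dt = -(kappa(t) + gamma + d_drug,G1(t)) N_G1(t)
               + 2 sigma(t) F(t - T(t)),

where F(u) = kappa(u) N_G1(u) is the S-entry flux, T(t) the S+G2+M transit
time of the cohort dividing at t, and sigma(t) its transit survival
(phase-specific death rates integrated over each phase window).  The factor
2 is the doubling at division.  The S, G2 and M compartments are then
reconstructed as survival-weighted integrals of the recorded S-entry flux
over each phase's occupancy window — equivalent to carrying three more delay
equations, without the redundant state.

Scheme: method of steps, fixed-step classical RK4 with cubic (4-point
Lagrange) interpolation of the stored flux history; constant history equal
to the initial state for t < 0.  Everything is deterministic: identical
inputs give bit-identical trajectories.

The integrator is batched: many treatment schedules (e.g. a whole scan of
administration times) are integrated in one pass, sharing the kinetics and
time grid, with per-column death-rate profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (CellCyclePreset, CircadianInput, DeathRateProfile,
                    g1s_transition_rate, sgm_total_delay)
from .treatment import Schedule, effective_death_rates


@dataclass(frozen=True)
class PopulationState:
    """Cell counts in the four phases (non-negative)."""

    n_g1: float = 1.0
    n_s: float = 0.0
    n_g2: float = 0.0
    n_m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_g1", "n_s", "n_g2", "n_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.n_g1 + self.n_s + self.n_g2 + self.n_m


@dataclass
class Trajectory:
    """Time series of the four phase compartments for one run."""

    times: np.ndarray
    n_g1: np.ndarray
    n_s: np.ndarray
    n_g2: np.ndarray
    n_m: np.ndarray
    s_entry_flux: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.n_g1 + self.n_s + self.n_g2 + self.n_m

    def to_frame(self) -> pd.DataFrame:
        total = self.total
        return pd.DataFrame({
            "time": self.times, "n_g1": self.n_g1, "n_s": self.n_s,
            "n_g2": self.n_g2, "n_m": self.n_m, "total": total,
            "frac_g1": self.n_g1 / total, "frac_s": self.n_s / total,
            "frac_g2m": (self.n_g2 + self.n_m) / total,
        })

    def write_csv(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(".json").write_text(
            json.dumps(self.metadata, indent=2, default=str))


# ---------------------------------------------------------------------------
# batched integrator core

@dataclass
class BatchRun:
    """Raw result of one batched integration (shared grid, B death profiles)."""

    preset: CellCyclePreset
    dt: float
    t_full: np.ndarray          # (m + n + 1,) grid including history
    m_hist: int                 # index of t = 0 in t_full
    flux: np.ndarray            # (m + n + 1, B) S-entry flux on the grid
    n_g1: np.ndarray            # (n + 1, B) G1 counts for t >= 0
    profiles: list

    @property
    def times(self) -> np.ndarray:
        return self.t_full[self.m_hist:]


def _lagrange_weights(s: np.ndarray) -> np.ndarray:
    """Cubic Lagrange weights on nodes {-1, 0, 1, 2} for fraction s in [0, 1)."""
    w = np.empty(s.shape + (4,))
    w[..., 0] = -s * (s - 1.0) * (s - 2.0) / 6.0
    w[..., 1] = (s - 1.0) * (s + 1.0) * (s - 2.0) / 2.0
    w[..., 2] = -s * (s + 1.0) * (s - 2.0) / 2.0
    w[..., 3] = s * (s + 1.0) * (s - 1.0) / 6.0
    return w


def integrate_g1(preset: CellCyclePreset,
                 profiles: list,
                 t_end: float,
                 dt: float = 0.01,
                 n_g1_init: float = 1.0,
                 circ: CircadianInput | None = None) -> BatchRun:
    """Integrate the G1 balance equation for B death-rate profiles at once.

    All profiles share the preset's kinetics; they may differ in their drug
    component (target phase, timing, shape).  Raises on negative state, on a
    step too large for the shortest phase, and on delay-monotonicity
    violations (guarded at preset construction).
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 h")
    if dt > preset.tm / 4.0:
        raise ValueError(f"dt={dt} too large for the shortest phase (T_M={preset.tm})")
    n = int(round(t_end / dt))
    if abs(n * dt - t_end) > 1e-9:
        raise ValueError("t_end must be a multiple of dt")
    B = len(profiles)

    t_max_delay = preset.ts + preset.tg2_mean * (1.0 + preset.g2_mod_amp) + preset.tm
    m = int(np.ceil(t_max_delay / dt)) + 4
    t_full = (np.arange(m + n + 1) - m) * dt

    # --- precomputation on the half-step grid ------------------------------
    tau = 0.5 * dt * np.arange(2 * n + 1)            # stage times
    kappa_tau = g1s_transition_rate(tau, preset, circ)

    # sigma(t_div): transit survival per profile; death rates are known
    # functions of time, so this is independent of the state.
    delay_tau = sgm_total_delay(tau, preset)
    e_tau = tau - delay_tau
    s_end = e_tau + preset.ts
    m_start = tau - preset.tm
    sigma = np.empty((2 * n + 1, B))
    loss_g1 = np.zeros((2 * n + 1, B))
    for b, prof in enumerate(profiles):
        hz = (prof.cumulative("S", s_end) - prof.cumulative("S", e_tau)
              + prof.cumulative("G2", m_start) - prof.cumulative("G2", s_end)
              + prof.cumulative("M", tau) - prof.cumulative("M", m_start))
        sigma[:, b] = np.exp(-hz)
        if prof._targets("G1"):
            loss_g1[:, b] = prof.drug_rate(tau)
    a_tau = -(kappa_tau[:, None] + preset.g1_loss_rate + loss_g1)

    # delayed-argument interpolation tables (shared across the batch)
    pos = e_tau / dt + m                             # fractional grid position
    j0 = np.floor(pos).astype(np.intp)
    if np.any(j0 < 1):
        raise RuntimeError("history buffer too short for the delay")
    wts = _lagrange_weights(pos - j0)

    # --- history and state -------------------------------------------------
    flux = np.zeros((m + n + 1, B))
    kap_full = g1s_transition_rate(t_full, preset, circ)
    flux[: m + 1, :] = (kap_full[: m + 1] * n_g1_init)[:, None]
    n_g1 = np.empty((n + 1, B))
    n_g1[0, :] = n_g1_init

    def f_delayed(k: int) -> np.ndarray:
        j = j0[k]
        return wts[k] @ flux[j - 1: j + 3, :]

    state = np.full(B, float(n_g1_init))
    two_sigma = 2.0 * sigma
    fd_right = f_delayed(0)
    for i in range(n):
        k0, k1, k2 = 2 * i, 2 * i + 1, 2 * i + 2
        b0 = two_sigma[k0] * fd_right
        fd_mid = f_delayed(k1)
        b1 = two_sigma[k1] * fd_mid
        fd_right = f_delayed(k2)
        b2 = two_sigma[k2] * fd_right
        a0, a1, a2 = a_tau[k0], a_tau[k1], a_tau[k2]
        r1 = a0 * state + b0
        r2 = a1 * (state + 0.5 * dt * r1) + b1
        r3 = a1 * (state + 0.5 * dt * r2) + b1
        r4 = a2 * (state + dt * r3) + b2
        state = state + (dt / 6.0) * (r1 + 2.0 * r2 + 2.0 * r3 + r4)
        n_g1[i + 1, :] = state
        flux[m + i + 1, :] = kappa_tau[k2] * state
    if np.any(n_g1 < 0):
        raise RuntimeError("negative G1 state: integration failure")
    return BatchRun(preset=preset, dt=dt, t_full=t_full, m_hist=m,
                    flux=flux, n_g1=n_g1, profiles=profiles)


def _interp_columns(c: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of columns of c at fractional row positions."""
    j = np.clip(np.floor(pos).astype(np.intp), 0, c.shape[0] - 2)
    f = (pos - j)[:, None]
    return c[j, :] * (1.0 - f) + c[j + 1, :] * f


def reconstruct_compartments(run: BatchRun):
    """S, G2 and M counts on the output grid, as survival-weighted integrals
    of the recorded S-entry flux over each phase's occupancy window.

    A cohort entering S at u is in S on [u, u+T_S], in G2 until its division
    time v(u) minus T_M, and in M until v(u), where v solves v - T(v) = u.
    Returns arrays of shape (n + 1, B) matching ``run.n_g1``.
    """
    preset, dt, m = run.preset, run.dt, run.m_hist
    t_full = run.t_full
    t_out = t_full[m:]
    B = run.flux.shape[1]
    ts, tm = preset.ts, preset.tm

    # division time of the cohort entering at u, via the tabulated inverse of
    # the (strictly increasing) entry-time map e(v) = v - T(v)
    v_tab = np.arange(t_full[0],
                      t_full[-1] + tm + preset.tg2_mean * 2 + ts + 4 * dt, dt)
    e_tab = v_tab - sgm_total_delay(v_tab, preset)
    v_of_u = np.interp(t_full, e_tab, v_tab)

    e_out = t_out - sgm_total_delay(t_out, preset)          # e(t)
    t_shift = t_out + tm
    e_shift = t_shift - sgm_total_delay(t_shift, preset)    # e(t + T_M)

    n_s = np.empty((t_out.size, B))
    n_g2 = np.empty((t_out.size, B))
    n_m = np.empty((t_out.size, B))
    pos_s = (t_out - ts - t_full[0]) / dt
    pos_t = (t_out - t_full[0]) / dt
    pos_eo = (e_out - t_full[0]) / dt
    pos_es = (e_shift - t_full[0]) / dt
    for b, prof in enumerate(run.profiles):
        d_s = prof.cumulative("S", t_full)
        d_s_shift = prof.cumulative("S", t_full + ts)
        d_g2_shift = prof.cumulative("G2", t_full + ts)
        g2_exit = v_of_u - tm
        d_g2_exit = prof.cumulative("G2", g2_exit)
        d_m_exit = prof.cumulative("M", g2_exit)

        f = run.flux[:, b]
        c_s = _cumtrapz(f * np.exp(d_s), dt)
        c_g2 = _cumtrapz(f * np.exp(d_s - d_s_shift + d_g2_shift), dt)
        c_m = _cumtrapz(f * np.exp(d_s - d_s_shift + d_g2_shift
                                   - d_g2_exit + d_m_exit), dt)
        cs = np.column_stack([c_s, c_g2, c_m])
        at_t = _interp_columns(cs, pos_t)      # at t
        at_s = _interp_columns(cs, pos_s)      # at t - T_S
        at_eo = _interp_columns(cs, pos_eo)    # at e(t)
        at_es = _interp_columns(cs, pos_es)    # at e(t + T_M)
        n_s[:, b] = np.exp(-prof.cumulative("S", t_out)) * (at_t[:, 0] - at_s[:, 0])
        n_g2[:, b] = np.exp(-prof.cumulative("G2", t_out)) * (at_s[:, 1] - at_es[:, 1])
        n_m[:, b] = np.exp(-prof.cumulative("M", t_out)) * (at_es[:, 2] - at_eo[:, 2])
    return n_s, n_g2, n_m


def _cumtrapz(y: np.ndarray, dx: float) -> np.ndarray:
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * dx * (y[1:] + y[:-1]), out=out[1:])
    return out


# ---------------------------------------------------------------------------
# public single-run interface

def simulate(preset: CellCyclePreset,
             circ: CircadianInput | None = None,
             schedule: Schedule | None = None,
             t_end: float = 240.0,
             dt: float = 0.01,
             initial: PopulationState | None = None) -> Trajectory:
    """Integrate one population under an optional treatment.

    Initial conditions default to all cells in G0/G1, with a constant
    pre-history (N_G1(t) = N_G1(0) for t < 0).  Under that convention the
    reconstructed S/G2/M compartments are already populated at t = 0 by the
    history's entry flux; like every history detail this washes out within
    the transient, which callers should discard before reading off any
    quantity.  Non-zero S/G2/M initial masses are rejected — start in G1
    and let the transient distribute the population.
    """
    initial = initial or PopulationState()
    if initial.n_s or initial.n_g2 or initial.n_m:
        raise ValueError("initial mass outside G0/G1 is not supported; "
                         "start in G1 and discard the transient")
    profile = effective_death_rates(preset, schedule)
    run = integrate_g1(preset, [profile], t_end=t_end, dt=dt,
                       n_g1_init=initial.n_g1, circ=circ)
    n_s, n_g2, n_m = reconstruct_compartments(run)
    meta = {"preset": preset.label or "unnamed", "dt": dt, "t_end": t_end,
            "schedule": None if schedule is None else vars(schedule).copy()}
    return Trajectory(times=run.times, n_g1=run.n_g1[:, 0],
                      n_s=n_s[:, 0], n_g2=n_g2[:, 0], n_m=n_m[:, 0],
                      s_entry_flux=run.flux[run.m_hist:, 0], metadata=meta)


def phase_fractions(traj: Trajectory) -> pd.DataFrame:
    """Per-time fractions of cells in G1, S and G2+M (summing to 1)."""
    total = traj.total
    if np.any(total <= 0):
        raise ValueError("zero total population in trajectory")
    return pd.DataFrame({
        "time": traj.times,
        "frac_g1": traj.n_g1 / total,
        "frac_s": traj.n_s / total,
        "frac_g2m": (traj.n_g2 + traj.n_m) / total,
    })


def growth_rate(traj: Trajectory, window) -> float:
    """Least-squares slope of log(total) over ``window``.

    ``window`` is either a (t0, t1) pair or a length in hours (taken at the
    end of the trajectory).  For a periodically modulated exponential the
    estimate is phase-independent when the window spans a multiple of 24 h.
    """
    if np.isscalar(window):
        t1 = traj.times[-1]
        t0 = t1 - float(window)
    else:
        t0, t1 = window
    if t0 < traj.times[0] - 1e-9 or t1 > traj.times[-1] + 1e-9:
        raise ValueError("window outside trajectory")
    sel = (traj.times >= t0 - 1e-9) & (traj.times <= t1 + 1e-9)
    t = traj.times[sel]
    y = np.log(traj.total[sel])
    t = t - t.mean()
    return float(np.dot(t, y - y.mean()) / np.dot(t, t))


# ---------------------------------------------------------------------------
# clock-off (asynchronous) oracles

def characteristic_growth_rate(preset: CellCyclePreset) -> float:
    """Exponential rate of the clock-off model: the unique real root of

        lambda + kappa + gamma = 2 sigma0 kappa exp(-lambda T),

    with sigma0 the basal transit survival and T the mean transit time."""
    kap, gam = preset.kappa_mean, preset.g1_loss_rate
    t_tot = preset.ts + preset.tg2_mean + preset.tm
    sigma0 = np.exp(-(preset.death_s * preset.ts
                      + preset.death_g2 * preset.tg2_mean
                      + preset.death_m * preset.tm))

    def g(lam):
        return lam + kap + gam - 2.0 * sigma0 * kap * np.exp(-lam * t_tot)

    lo, hi = -1.0, 1.0
    while g(lo) > 0:
        lo *= 2.0
    while g(hi) < 0:
        hi *= 2.0
    return brentq(g, lo, hi, xtol=1e-14, rtol=1e-15)


def asynchronous_fractions(preset: CellCyclePreset) -> dict:
    """Steady phase fractions of the clock-off renewal process, closed form.

    On the exponential attractor N_G1 = G e^{lambda t}, each downstream
    compartment is the entry flux kappa G e^{lambda t} filtered through its
    transit: occupancy factors (1 - e^{-(lambda+d) L}) / (lambda + d) with
    the survival of the already-completed phases in front.
    """
    lam = characteristic_growth_rate(preset)
    kap = preset.kappa_mean

    def occ(rate, length):
        a = lam + rate
        if abs(a) < 1e-12:
            return length
        return (1.0 - np.exp(-a * length)) / a

    w_s = kap * occ(preset.death_s, preset.ts)
    w_g2 = (kap * np.exp(-(lam + preset.death_s) * preset.ts)
            * occ(preset.death_g2, preset.tg2_mean))
    w_m = (kap * np.exp(-(lam + preset.death_s) * preset.ts
                        - (lam + preset.death_g2) * preset.tg2_mean)
           * occ(preset.death_m, preset.tm))
    total = 1.0 + w_s + w_g2 + w_m
    return {"G1": 1.0 / total, "S": w_s / total,
            "G2": w_g2 / total, "M": w_m / total, "growth_rate": lam}
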