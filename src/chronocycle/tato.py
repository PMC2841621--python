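"""Analytic treatment-outcome prediction (TATO).

For a 24 h-periodic hazard, the circadian contribution of a treatment to a
population's growth rate is a period-averaged product of two zero-mean
oscillations: the transit-survival fraction of each cohort and the G1->S
transition rate at that cohort's S entry,

    I(t0) = (1/24) integral_0^24  s~(u; t0) kappa~(u) du,

where u runs over cohort S-entry times, s(u; t0) is the fraction of the
cohort entering S at u that survives its S+G2+M transit under one
administration per day at clock time t0, and the tildes strip the period
means.  I > 0 raises the growth rate (the hazard spares the crest of the
entry flux), I < 0 lowers it; its extrema over t0 locate the most sparing
and most killing administration times.

For a sinusoidal transition rate peaking at t_kappa and an S-phase-specific
drug, the extrema are available in closed form: the kill is largest when the
administration falls halfway through the S transit of the cohorts entering
at the kappa peak (t0 = t_kappa + T_S/2) and smallest 12 h later; for
T_S > 24 h both flip by 12 h, and at T_S = 24 h timing has no effect.

The module also covers non-24 h courses (phase averaging over the course)
and the clock-free resonance analysis of the refilling sensitive fraction
(Lambert-W stationary point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import lambertw

from .model import (CellCyclePreset, CircadianInput, g1s_transition_rate,
                    sgm_total_delay)
from .treatment import Schedule, periodic_death_rates

_TWO_PI = 2.0 * np.pi
OMEGA = _TWO_PI / 24.0


def circular_distance(a: float, b: float, period: float = 24.0) -> float:
    """Shortest distance between two clock times, in [0, period/2]."""
    d = abs(a - b) % period
    return min(d, period - d)


@dataclass(frozen=True)
class TatoPrediction:
    """Best (most sparing) and worst (most killing) administration clock
    times for one population, with the peak-to-trough amplitude of the
    perturbation integral over start time."""

    best_time: float
    worst_time: float
    amplitude: float
    target_phase: str
    method: str = "numeric"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not (0.0 <= self.best_time < 24.0 and 0.0 <= self.worst_time < 24.0):
                raise ValueError("times must be in [0, 24)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def to_dict(self) -> dict:
        return {"target_phase": self.target_phase, "best": self.best_time,
                "worst": self.worst_time, "amplitude": self.amplitude,
                "method": self.method, "degenerate": self.degenerate}


# ---------------------------------------------------------------------------
# the perturbation integral

def _division_times(u: np.ndarray, preset: CellCyclePreset) -> np.ndarray:
    """Division time v(u) of cohorts entering S at u (tabulated inverse)."""
    if preset.g2_mod_amp == 0.0:
        return u + preset.ts + preset.tg2_mean + preset.tm
    vmax = float(np.max(u)) + preset.ts + preset.tg2_mean * 2 + preset.tm + 1.0
    v_tab = np.linspace(float(np.min(u)), vmax, 4096)
    e_tab = v_tab - sgm_total_delay(v_tab, preset)
    return np.interp(u, e_tab, v_tab)


def _entry_survival(u: np.ndarray, preset: CellCyclePreset, profile) -> np.ndarray:
    """Transit survival of the cohort entering S at u, vectorised."""
    v = _division_times(u, preset)
    s_end = u + preset.ts
    m_start = v - preset.tm
    hz = (profile.cumulative("S", s_end) - profile.cumulative("S", u)
          + profile.cumulative("G2", m_start) - profile.cumulative("G2", s_end)
          + profile.cumulative("M", v) - profile.cumulative("M", m_start))
    return np.exp(-hz)


def periodic_growth_contribution(preset: CellCyclePreset,
                                 circ: CircadianInput | None,
                                 schedule: Schedule,
                                 start_time,
                                 n_quad: int = 4096,
                                 untreated_profile=None):
    """The perturbation integral I(start_time) for a 24 h-interval course.

    Computed by composite trapezoidal quadrature over one period (spectrally
    accurate for the smooth periodic integrand).  ``start_time`` may be an
    array; the quadrature is shared.  For a G1-targeted drug the hazard acts
    on the G0/G1 pool directly and the integral weighs the drug oscillation
    by the untreated periodic G1 profile (see :func:`g1_growth_contribution`).
    """
    if abs(schedule.interval - 24.0) > 1e-9:
        raise ValueError("the single-day periodic integral requires interval = 24 h")
    if schedule.target_phase == "G1":
        return g1_growth_contribution(preset, circ, schedule, start_time,
                                      untreated_profile=untreated_profile)
    t0s = np.atleast_1d(np.asarray(start_time, dtype=float))
    u = np.arange(n_quad) * (24.0 / n_quad)
    kap = g1s_transition_rate(u, preset, circ)
    k_tilde = kap - preset.kappa_mean
    out = np.empty(t0s.shape)
    t_lo = -(preset.ts + preset.tg2_mean * 2 + preset.tm + 26.0)
    for i, t0 in enumerate(t0s):
        prof = periodic_death_rates(preset, schedule.replace(start_time=t0 % 24.0),
                                    (t_lo, 50.0))
        s = _entry_survival(u, preset, prof)
        s_tilde = s - s.mean()
        out[i] = np.mean(s_tilde * k_tilde)
    return out if np.ndim(start_time) else float(out[0])


def untreated_periodic_g1(preset: CellCyclePreset,
                          circ: CircadianInput | None = None,
                          dt: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Clock-time grid and detrended periodic G0/G1 profile p(t) of the
    untreated population (one post-transient day, exponential trend removed)."""
    from .simulate import Trajectory, growth_rate, simulate

    traj = simulate(preset, circ=circ, t_end=144.0, dt=dt)
    lam = growth_rate(traj, (96.0, 144.0))
    sel = (traj.times >= 96.0) & (traj.times < 120.0)
    t = traj.times[sel]
    p = traj.n_g1[sel] * np.exp(-lam * t)
    return t % 24.0, p


def g1_growth_contribution(preset: CellCyclePreset,
                           circ: CircadianInput | None,
                           schedule: Schedule,
                           start_time,
                           untreated_profile=None):
    """Perturbation integral for a G1-targeted drug.

    The drug removes G0/G1 cells at rate d(t); to first order the growth
    rate shifts by -<d(t) p(t)> / <p> per period, with p the untreated
    periodic G1 profile.  The zero-mean part over administration time t0 is

        I(t0) = -(1/24) integral_0^24 d~(t - t0) p~(t)/<p> dt.
    """
    if untreated_profile is None:
        untreated_profile = untreated_periodic_g1(preset, circ)
    tc, p = untreated_profile
    order = np.argsort(tc)
    tc, p = tc[order], p[order]
    p_tilde = p / p.mean() - 1.0
    t0s = np.atleast_1d(np.asarray(start_time, dtype=float))
    sched0 = schedule.replace(start_time=0.0)
    out = np.empty(t0s.shape)
    for i, t0 in enumerate(t0s):
        prof = periodic_death_rates(preset, sched0, (-30.0, 50.0))
        d = prof.drug_rate((tc - t0) % 24.0)
        d_tilde = d - d.mean()
        out[i] = -np.mean(d_tilde * p_tilde)
    return out if np.ndim(start_time) else float(out[0])


# ---------------------------------------------------------------------------
# closed-form and numeric extrema

def s_phase_extrema(t_kappa: float, ts: float) -> TatoPrediction:
    """Closed-form extrema for an S-phase drug under sinusoidal modulation.

    Kill is maximal halfway through the S transit of the cohorts entering at
    the transition-rate peak; sparing is maximal 12 h later.  Durations
    above 24 h flip both by 12 h; ts = 24 h is degenerate (no timing
    effect).  The two times are always 12 h apart.
    """
    if ts <= 0:
        raise ValueError("ts must be > 0")
    if abs(ts % 24.0) < 1e-12 and ts > 0:
        return TatoPrediction(best_time=0.0, worst_time=12.0, amplitude=0.0,
                              target_phase="S", method="closed_form",
                              degenerate=True)
    shift = 12.0 if ts > 24.0 else 0.0
    worst_for_cells = (t_kappa + ts / 2.0 + shift) % 24.0
    best_for_cells = (worst_for_cells + 12.0) % 24.0
    return TatoPrediction(best_time=best_for_cells, worst_time=worst_for_cells,
                          amplitude=2.0 * abs(np.sin(OMEGA * ts / 2.0)),
                          target_phase="S", method="closed_form")


def phase_extrema(target_phase: str,
                  preset: CellCyclePreset,
                  circ: CircadianInput | None,
                  schedule: Schedule,
                  grid_step: float = 0.25,
                  n_quad: int = 2048) -> TatoPrediction:
    """Best/worst administration clock times for one population.

    S-phase targets use the closed-form rule (with the numerically evaluated
    amplitude); G2/M and G1 targets locate the extrema of the perturbation
    integral on a ``grid_step`` grid.  A flat integral (amplitude below
    1e-10) is flagged degenerate.
    """
    sched = schedule.replace(target_phase=target_phase, interval=24.0)
    t0s = np.arange(0.0, 24.0, grid_step)
    vals = periodic_growth_contribution(preset, circ, sched, t0s, n_quad=n_quad)
    amp = float(vals.max() - vals.min())
    # the G1 route rests on a simulated periodic profile, whose numerical
    # noise floor is far above the quadrature's
    flat_tol = 1e-7 if target_phase == "G1" else 1e-10
    if amp < flat_tol:
        return TatoPrediction(best_time=0.0, worst_time=0.0, amplitude=amp,
                              target_phase=target_phase, method="numeric",
                              degenerate=True)
    if target_phase == "S":
        closed = s_phase_extrema(preset.kappa_mod_phase, preset.ts)
        return TatoPrediction(best_time=closed.best_time,
                              worst_time=closed.worst_time, amplitude=amp,
                              target_phase="S", method="closed_form")
    best = float(t0s[np.argmax(vals)])
    worst = float(t0s[np.argmin(vals)])
    return TatoPrediction(best_time=best, worst_time=worst, amplitude=amp,
                          target_phase=target_phase, method="numeric")


# ---------------------------------------------------------------------------
# outcome-level prediction (host vs tumor)

def _mean_hazard_growth_shift(preset: CellCyclePreset,
                              circ: CircadianInput | None,
                              schedule: Schedule,
                              n_quad: int = 2048) -> tuple[float, float, float]:
    """(lambda_untreated, lambda_treated_mean, dlambda/dI) from the
    period-averaged balance  lambda + kappa + gamma + <d_G1> =
    2 e^{-lambda T} (kappa <sigma> + I)."""
    from scipy.optimize import brentq

    kap, gam = preset.kappa_mean, preset.g1_loss_rate
    t_tot = preset.ts + preset.tg2_mean + preset.tm
    u = np.arange(n_quad) * (24.0 / n_quad)
    t_lo = -(preset.ts + preset.tg2_mean * 2 + preset.tm + 26.0)
    prof = periodic_death_rates(preset, schedule, (t_lo, 50.0))
    sig_mean = float(np.mean(_entry_survival(u, preset, prof)))
    d_g1 = float(np.mean(prof.drug_rate(u))) if prof._targets("G1") else 0.0

    from .model import DeathRateProfile
    sig0 = float(np.mean(_entry_survival(u, preset, DeathRateProfile.basal(preset))))

    def solve(sig, extra_loss):
        g = lambda lam: lam + kap + gam + extra_loss - 2 * sig * kap * np.exp(-lam * t_tot)
        lo, hi = -2.0, 2.0
        while g(lo) > 0:
            lo *= 2
        while g(hi) < 0:
            hi *= 2
        return brentq(g, lo, hi, xtol=1e-14)

    lam_u = solve(sig0, 0.0)
    lam_t = solve(sig_mean, d_g1)
    if schedule.target_phase == "G1":
        dlam_di = 1.0
    else:
        ex = np.exp(-lam_t * t_tot)
        dlam_di = 2 * ex / (1.0 + 2 * ex * kap * sig_mean * t_tot)
    return lam_u, lam_t, dlam_di


def outcome_extrema(host: CellCyclePreset,
                    tumor: CellCyclePreset,
                    circ: CircadianInput | None,
                    schedule: Schedule,
                    grid_step: float = 0.25,
                    n_quad: int = 2048) -> TatoPrediction:
    """Analytic best/worst administration times for the outcome E = R_H - R_C.

    Each response is approximated by its TATO form
    R_X(t0) ~ Rbar_X exp(beta_X I~_X(t0)), with Rbar_X from the
    period-averaged hazard and beta_X = (dlambda/dI) x (hazard-active span);
    the predicted outcome curve is maximised/minimised on a ``grid_step``
    grid of start times.
    """
    span = 24.0 * schedule.n_admin
    t0s = np.arange(0.0, 24.0, grid_step)
    curves = []
    for preset in (host, tumor):
        sched = schedule.replace(interval=24.0)
        vals = periodic_growth_contribution(preset, circ, sched, t0s, n_quad=n_quad)
        lam_u, lam_t, dlam_di = _mean_hazard_growth_shift(preset, circ, sched,
                                                          n_quad=n_quad)
        rbar = np.exp((lam_t - lam_u) * span)
        curves.append(rbar * np.exp(dlam_di * span * (vals - vals.mean())))
    e_hat = curves[0] - curves[1]
    amp = float(e_hat.max() - e_hat.min())
    if amp < 1e-12:
        return TatoPrediction(0.0, 0.0, amp, schedule.target_phase,
                              method="numeric", degenerate=True)
    return TatoPrediction(best_time=float(t0s[np.argmax(e_hat)]),
                          worst_time=float(t0s[np.argmin(e_hat)]),
                          amplitude=amp, target_phase=schedule.target_phase,
                          method="numeric")


# ---------------------------------------------------------------------------
# amplitude as a function of the sensitive-phase duration

def _pulse_first_harmonic(schedule: Schedule) -> float:
    """|First Fourier coefficient| of the daily pulse train (one pulse/24 h)."""
    from .treatment import _pulse_shape

    w, c, k = schedule.infusion_width, schedule.truncation, schedule.k_max
    val, _ = quad(lambda x: k * _pulse_shape(x, w, c) * np.cos(OMEGA * x),
                  -c * w, c * w, epsabs=1e-12)
    return abs(val) / 24.0


def outcome_amplitude(ts: float, circ: CircadianInput | None = None,
                      schedule: Schedule | None = None,
                      kappa_mean: float = 1.0,
                      kappa_mod_amp: float = 1.0) -> float:
    """Peak-to-trough amplitude of the (linearised) perturbation integral as
    a function of the sensitive-phase duration ts.

    For a sinusoidal transition rate only the first harmonic of the hazard
    survives the period average, giving amplitude proportional to
    |sin(pi ts / 24)|: symmetric about ts = 12 on (0, 24), vanishing at
    ts = 0 and ts = 24, maximal at ts = 12 (located here by numerical
    optimisation when requested via :func:`most_sensitive_duration`).
    """
    if ts < 0:
        raise ValueError("ts must be >= 0")
    schedule = schedule or Schedule()
    h1 = _pulse_first_harmonic(schedule)
    a_k = kappa_mean * kappa_mod_amp
    return float(2.0 * a_k * h1 * 2.0 * abs(np.sin(OMEGA * ts / 2.0)) / OMEGA)


def most_sensitive_duration(circ: CircadianInput | None = None,
                            schedule: Schedule | None = None) -> float:
    """S-phase duration in (0, 24) maximising the timing amplitude."""
    res = minimize_scalar(lambda ts: -outcome_amplitude(ts, circ, schedule),
                          bounds=(0.5, 23.5), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


# ---------------------------------------------------------------------------
# non-24 h schedules

def equivalent_start_time(interval: float, n_admin: int, t_star: float) -> float:
    """First-day start time making a course at ``interval`` equivalent to a
    24 h-interval course at phase ``t_star``.

    The n administrations fall at clock times t0 + j (interval - 24); their
    mean phase equals t_star when t0 = t_star - (n-1)(interval-24)/2, so the
    start advances by (n-1)/2 hours per hour of interval above 24 h.
    Outside |interval - 24| < 24/n the clock phases wrap and the mean phase
    is undefined; a warning flags that regime.
    """
    if n_admin < 1:
        raise ValueError("n_admin must be >= 1")
    if abs(interval - 24.0) >= 24.0 / n_admin:
        warnings.warn("interval outside the phase-averaging validity range; "
                      "mean administration phase is undefined", stacklevel=2)
    return (t_star - (n_admin - 1) * (interval - 24.0) / 2.0) % 24.0


def uniform_phase_intervals(n_admin: int) -> tuple[float, float]:
    """The two intervals flanking 24 h at which the n administration clock
    times are uniformly spread over the day (outcome insensitive to start)."""
    if n_admin < 2:
        raise ValueError("n_admin must be >= 2")
    return (24.0 * (1.0 - 1.0 / n_admin), 24.0 * (1.0 + 1.0 / n_admin))


# ---------------------------------------------------------------------------
# clock-free resonance analysis

def clock_free_sensitive_fraction(t, ts: float, kappa_mean: float):
    """Sensitive (S-phase) fraction of the clock-free model after an
    administration at t = 0 kills every S-phase cell.

    Valid on 0 <= t <= 2 ts (exact piecewise solution of the refill:
    before ts the pool refills from G1 with no exits; after ts the first
    post-kill cohorts exit and divide).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 2 * ts + 1e-9):
        raise ValueError("closed-form refill is valid on [0, 2 ts]")
    k = kappa_mean
    r = np.exp(-k * ts)
    x = k * np.clip(t - ts, 0.0, None)
    early = 1.0 - np.exp(-k * t)
    late = 1.0 - np.exp(-x) * (r + 2.0 * x) / (2.0 - np.exp(-x))
    out = np.where(t <= ts, early, late)
    return out if out.ndim else float(out)


def clock_free_min_sensitive_time(ts: float, kappa_mean: float,
                                  check_tol: float = 1e-6) -> float:
    """Elapsed time t* after a total S-phase kill at which the sensitive
    fraction is minimal — the resonance interval that spares refilled cells.

    Located by numerical minimisation of the refilling sensitive fraction on
    (ts, 2 ts); the result satisfies the Lambert-W stationarity identity

        x = (2 - r)/2 + W0(-e^{-(2-r)/2} / 2),   r = e^{-kappa ts},

    with x = kappa (t* - ts), to ``check_tol`` (verified; a violation or a
    boundary minimum raises).
    """
    if ts <= 0 or kappa_mean <= 0:
        raise ValueError("ts and kappa_mean must be > 0")
    res = minimize_scalar(
        lambda t: clock_free_sensitive_fraction(t, ts, kappa_mean),
        bounds=(ts, 2.0 * ts), method="bounded", options={"xatol": 1e-10})
    t_star = float(res.x)
    if min(t_star - ts, 2.0 * ts - t_star) < 1e-7:
        raise RuntimeError("no interior minimum of the sensitive fraction")
    r = np.exp(-kappa_mean * ts)
    arg = -np.exp(-(2.0 - r) / 2.0) / 2.0
    x_w = (2.0 - r) / 2.0 + float(np.real(lambertw(arg)))
    t_w = ts + x_w / kappa_mean
    if abs(t_w - t_star) > check_tol:
        raise RuntimeError(
            f"stationarity identity violated: |{t_w} - {t_star}| > {check_tol}")
    return t_star
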