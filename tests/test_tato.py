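"""Analytic treatment-outcome prediction: integrals, closed forms, resonance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from chronocycle.model import CellCyclePreset
from chronocycle.tato import (circular_distance, clock_free_min_sensitive_time,
                              clock_free_sensitive_fraction,
                              equivalent_start_time, most_sensitive_duration,
                              outcome_amplitude, periodic_growth_contribution,
                              phase_extrema, s_phase_extrema,
                              uniform_phase_intervals)
from chronocycle.treatment import Schedule, periodic_death_rates

from conftest import random_clocked_preset


def _s_sched(k_max=0.2, width=2.3):
    return Schedule(target_phase="S", start_time=0.0, k_max=k_max,
                    infusion_width=width, first_day=0)


class TestPerturbationIntegral:
    def test_zero_when_clock_off(self, plain_preset):
        vals = periodic_growth_contribution(plain_preset, None, _s_sched(),
                                            np.arange(0, 24, 3.0), n_quad=512)
        assert np.allclose(vals, 0.0, atol=1e-15)

    def test_no_timing_effect_at_ts_24(self):
        p = CellCyclePreset(kappa_mean=0.05, g1_loss_rate=0.0, ts=24.0,
                            tg2_mean=3, tm=1, kappa_mod_amp=0.3,
                            kappa_mod_phase=10.0)
        vals = periodic_growth_contribution(p, None, _s_sched(),
                                            np.arange(0, 24, 2.0), n_quad=1024)
        assert vals.max() - vals.min() < 1e-10

    def test_matches_riemann_oracle(self):
        """Adaptive path vs a 1e5-point Riemann sum on random presets."""
        from chronocycle.model import g1s_transition_rate
        from chronocycle.tato import _entry_survival

        rng = np.random.default_rng(42)
        sched = _s_sched()
        for _ in range(5):
            p = random_clocked_preset(rng)
            t0 = float(rng.uniform(0, 24))
            val = periodic_growth_contribution(p, None, sched, t0)
            u = np.arange(100_000) * (24.0 / 100_000)
            prof = periodic_death_rates(
                p, sched.replace(start_time=t0),
                (-(p.ts + p.tg2_mean * 2 + p.tm + 26.0), 50.0))
            s = _entry_survival(u, p, prof)
            kt = g1s_transition_rate(u, p) - p.kappa_mean
            oracle = np.mean((s - s.mean()) * kt)
            assert val == pytest.approx(oracle, abs=1e-8)


class TestSPhaseExtremaRule:
    def test_reference_case(self):
        pred = s_phase_extrema(14.0, 8.0)
        assert pred.worst_time == pytest.approx(18.0)   # max kill
        assert pred.best_time == pytest.approx(6.0)     # max sparing

    @given(t_kappa=st.floats(0, 24, exclude_max=True),
           ts=st.floats(0.5, 23.5))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_extrema_always_12h_apart(self, t_kappa, ts):
        pred = s_phase_extrema(t_kappa, ts)
        assert circular_distance(pred.best_time, pred.worst_time) == \
            pytest.approx(12.0, abs=1e-9)

    def test_degenerate_at_24h(self):
        assert s_phase_extrema(14.0, 24.0).degenerate

    def test_numeric_extrema_match_closed_form(self):
        """Numeric argmax/argmin of the integral vs the sinusoidal rule,
        within 0.5 h for moderate modulation amplitudes."""
        sched = _s_sched()
        t0s = np.arange(0.0, 24.0, 0.25)
        for t_kappa, ts, amp in [(9.0, 8.0, 0.3), (14.0, 12.0, 0.2),
                                 (4.0, 18.0, 0.25)]:
            p = CellCyclePreset(kappa_mean=0.05, g1_loss_rate=0.01, ts=ts,
                                tg2_mean=3, tm=1, kappa_mod_amp=amp,
                                kappa_mod_phase=t_kappa)
            vals = periodic_growth_contribution(p, None, sched, t0s,
                                                n_quad=1024)
            rule = s_phase_extrema(t_kappa, ts)
            assert circular_distance(
                float(t0s[np.argmax(vals)]), rule.best_time) <= 0.5
            assert circular_distance(
                float(t0s[np.argmin(vals)]), rule.worst_time) <= 0.5

    def test_mod_24_periodicity_in_duration(self):
        """A 24 h-periodic hazard cannot distinguish T_S from T_S - 24: the
        numerically located extrema for T_S = 30 coincide with T_S = 6 and
        therefore sit 12 h away from the naive t_kappa + T_S/2 line."""
        sched = _s_sched()
        t0s = np.arange(0.0, 24.0, 0.25)
        args = {}
        for ts in (6.0, 30.0):
            p = CellCyclePreset(kappa_mean=0.05, g1_loss_rate=0.01, ts=ts,
                                tg2_mean=3, tm=1, kappa_mod_amp=0.25,
                                kappa_mod_phase=14.0)
            vals = periodic_growth_contribution(p, None, sched, t0s,
                                                n_quad=1024)
            args[ts] = float(t0s[np.argmin(vals)])
        assert circular_distance(args[30.0], args[6.0]) <= 0.25
        naive_continuation = (14.0 + 30.0 / 2.0) % 24.0
        assert circular_distance(args[30.0], naive_continuation) == \
            pytest.approx(12.0, abs=0.5)
        assert s_phase_extrema(14.0, 30.0).worst_time == pytest.approx(
            s_phase_extrema(14.0, 6.0).worst_time, abs=1e-9)


class TestPhaseExtrema:
    def test_degenerate_without_modulation(self, plain_preset):
        pred = phase_extrema("G1", plain_preset, None, _s_sched())
        assert pred.degenerate

    @pytest.mark.parametrize("target", ["S", "G2M"])
    def test_agrees_with_numeric_integral(self, clocked_preset, target):
        sched = _s_sched()
        pred = phase_extrema(target, clocked_preset, None, sched,
                             grid_step=0.25, n_quad=1024)
        t0s = np.arange(0.0, 24.0, 0.25)
        vals = periodic_growth_contribution(
            clocked_preset, None, sched.replace(target_phase=target), t0s,
            n_quad=1024)
        assert circular_distance(pred.best_time,
                                 float(t0s[np.argmax(vals)])) <= 0.5
        assert circular_distance(pred.worst_time,
                                 float(t0s[np.argmin(vals)])) <= 0.5


class TestOutcomeAmplitude:
    def test_vanishes_at_24h(self):
        assert outcome_amplitude(24.0) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_about_12(self):
        for ts in np.arange(1.0, 12.0, 1.0):
            assert outcome_amplitude(ts) == pytest.approx(
                outcome_amplitude(24.0 - ts), abs=1e-8)

    @pytest.mark.parametrize("ts", [4.0, 8.0, 12.0, 16.0, 20.0])
    def test_positive_inside_the_day(self, ts):
        assert outcome_amplitude(ts) > 0

    def test_matches_linearised_quadrature_oracle(self):
        """Closed-form first-harmonic amplitude vs brute-force linearised
        integral over a fine start-time grid."""
        from chronocycle.model import DeathRateProfile

        sched = _s_sched(k_max=1.0)
        ts = 8.0
        t0s = np.arange(0.0, 24.0, 0.1)
        u = np.arange(8192) * (24.0 / 8192)
        kt = np.cos((2 * np.pi / 24.0) * u)  # unit sinusoidal rate oscillation
        vals = np.empty(t0s.shape)
        for i, t0 in enumerate(t0s):
            prof = periodic_death_rates(
                CellCyclePreset(kappa_mean=1.0, g1_loss_rate=0.0, ts=ts,
                                tg2_mean=3, tm=1, death_s=0.0, death_g2=0.0,
                                death_m=0.0),
                sched.replace(start_time=t0), (-60.0, 50.0))
            hz = prof.cumulative("S", u + ts) - prof.cumulative("S", u)
            hz_tilde = hz - hz.mean()
            vals[i] = np.mean(-hz_tilde * kt)  # linearised survival
        oracle = vals.max() - vals.min()
        assert outcome_amplitude(ts, schedule=sched) == pytest.approx(
            oracle, rel=1e-4)

    def test_most_sensitive_duration_is_half_day(self):
        assert most_sensitive_duration() == pytest.approx(12.0, abs=1e-5)


class TestCourseAveraging:
    def test_24h_interval_identity(self):
        assert equivalent_start_time(24.0, 5, 7.25) == pytest.approx(7.25)

    def test_two_hour_advance_per_interval_hour(self):
        t24 = equivalent_start_time(24.0, 5, 2.0)
        t25 = equivalent_start_time(25.0, 5, 2.0)
        assert (t24 - t25) % 24.0 == pytest.approx(2.0)

    def test_outside_validity_flagged(self):
        with pytest.warns(UserWarning, match="validity"):
            equivalent_start_time(30.0, 5, 2.0)

    def test_uniform_phase_intervals(self):
        assert uniform_phase_intervals(5) == pytest.approx((19.2, 28.8))
        assert uniform_phase_intervals(2) == pytest.approx((12.0, 36.0))

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_clock_times_equispaced(self, n):
        for interval in uniform_phase_intervals(n):
            clock = np.sort((interval * np.arange(n)) % 24.0)
            gaps = np.diff(np.append(clock, clock[0] + 24.0))
            assert np.allclose(gaps, 24.0 / n, atol=1e-9)


class TestClockFreeResonance:
    def test_sensitive_pool_empty_right_after_kill(self):
        assert clock_free_sensitive_fraction(0.0, 8.0, 0.05) == 0.0

    @pytest.mark.parametrize("ts,kappa", [(8.0, 0.05), (12.0, 0.1),
                                          (20.0, 0.02)])
    def test_minimum_satisfies_lambert_identity(self, ts, kappa):
        """Numerical minimisation vs the independent root of the
        stationarity equation exp(-x) = 2 - r - 2x."""
        t_star = clock_free_min_sensitive_time(ts, kappa)
        r = np.exp(-kappa * ts)
        x_root = brentq(lambda x: np.exp(-x) - (2.0 - r - 2.0 * x),
                        1e-12, (2.0 - r) / 2.0, xtol=1e-14)
        assert t_star == pytest.approx(ts + x_root / kappa, abs=1e-6)

    def test_minimum_is_interior_and_after_refill(self):
        t_star = clock_free_min_sensitive_time(10.0, 0.06)
        assert 10.0 < t_star < 20.0
        f_star = clock_free_sensitive_fraction(t_star, 10.0, 0.06)
        probe = clock_free_sensitive_fraction(
            np.array([t_star - 1.0, t_star + 1.0]), 10.0, 0.06)
        assert np.all(f_star < probe)

    def test_intervals_up_to_ts_leave_no_surviving_divider(self, plain_preset):
        """Administrations that kill every S-phase cell, repeated at an
        interval <= T_S: each cohort's S window contains a kill, so the
        transit survival vanishes for every division time in the course."""
        from chronocycle.model import stage_survival

        sched = Schedule(target_phase="S", start_time=0.0, interval=8.0,
                         n_admin=40, k_max=50.0, infusion_width=0.2,
                         first_day=0)
        prof = periodic_death_rates(plain_preset, sched, (-40.0, 400.0))
        t_div = np.linspace(40.0, 300.0, 601)
        assert np.max(stage_survival(t_div, plain_preset, prof)) < 1e-6


class TestSignConsistency:
    def test_integral_sign_predicts_growth_rate_shift(self):
        """I(t0) > 0 iff the simulated growth rate under the periodic course
        exceeds the mean-hazard characteristic prediction."""
        from scipy.optimize import brentq as _brentq

        from chronocycle.simulate import growth_rate, simulate
        from chronocycle.tato import _entry_survival

        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(10):
            p = random_clocked_preset(rng)
            t0 = float(rng.uniform(0, 24))
            sched = Schedule(target_phase="S", start_time=t0, interval=24.0,
                             n_admin=14, k_max=0.05, first_day=0)
            i_val = periodic_growth_contribution(p, None, sched, t0,
                                                 n_quad=1024)
            u = np.arange(1024) * (24.0 / 1024)
            prof = periodic_death_rates(
                p, sched, (-(p.ts + p.tg2_mean * 2 + p.tm + 26.0), 50.0))
            sig_mean = float(np.mean(_entry_survival(u, p, prof)))
            t_tot = p.ts + p.tg2_mean + p.tm
            lam_mean = _brentq(
                lambda lam: lam + p.kappa_mean + p.g1_loss_rate
                - 2 * sig_mean * p.kappa_mean * np.exp(-lam * t_tot),
                -1.0, 1.0, xtol=1e-14)
            traj = simulate(p, schedule=sched, t_end=336.0, dt=0.05)
            lam_sim = growth_rate(traj, (240.0, 336.0))
            if abs(i_val) < 1e-6:
                continue  # too close to call at simulation accuracy
            checked += 1
            assert (i_val > 0) == (lam_sim > lam_mean), \
                f"I={i_val:.2e}, lam_sim-lam_mean={lam_sim - lam_mean:.2e}"
        assert checked >= 7
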