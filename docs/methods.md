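# Methods

## Model

The population model is a linear renewal process with four phases.  G0/G1
cells leave toward S at the clock-gated rate κ(t) or permanently at rate γ
(differentiation, death, emigration); S, G2 and M are transit compartments
of durations T_S, T_G2(t), T_M; surviving mitotic cells divide into two G1
cells.  The clock enters as multiplicative sinusoids on κ and T_G2 with a
common 24 h period; the reference oscillator C(t) = 1 + a cos(2π(t − ψ)/24)
uses a = 0.2, ψ = 14 h.  The model is deliberately linear: treatment
courses are short and the populations are assumed far from any homeostatic
equilibrium, so crowding terms and inter-course recovery feedback are
omitted.  There is no mechanistic clock-gene circuit — the clock is an
imposed sinusoid — and no pharmacokinetics: drug concentration is identified
with the killing rate it produces in its target phase.

Attribution conventions: the transit time T(t) = T_S + T_G2(t) + T_M is
attributed to the *division* time t; the cohort dividing at t entered S at
e(t) = t − T(t), spent [e, e+T_S] in S, [e+T_S, t−T_M] in G2 and the final
T_M in M, and each phase-specific death rate is integrated over its own
window.  Presets must satisfy |dT/dt| < 1 (enforced at construction) so
that e(t) is strictly increasing and cohort order is preserved.

## Numerics

The G1 equation is integrated by the method of steps: fixed-step classical
RK4 (default dt = 0.01 h, hard cap 0.05 h and a quarter of the shortest
phase) with 4-point Lagrange interpolation of the stored S-entry flux
history, constant history equal to the initial state for t < 0, and all
cells initially in G0/G1 (the phase distribution synchronises within the
discarded 72 h transient, so history and initial-condition details do not
reach any reported quantity).  Because the model is linear, the integrator
is batched: an entire scan of administration times shares one time grid and
one kinetics evaluation, with per-schedule hazard columns.

Death-rate integrals are exact: the truncated-Gaussian pulse has a
closed-form antiderivative (erf minus the linear offset term), so transit
survivals need no quadrature inside the integrator.  The pulse is the
*continuous* truncation (exp(−x²/2w²) − ε)/(1 − ε) on |x| ≤ cw with
ε = e^{−c²/2}, unit peak, default w = 2.3 h and c = 2.5 (support 11.5 h,
the clinical chronomodulated 5-FU profile; the true infusion-shape
parameters of the source protocols are not recoverable, so both are
configurable).  Continuity at the cutoff is what lets the hazard-
normalisation identities hold to 1e-8 against fine Riemann sums.

S, G2 and M counts are reconstructed as survival-weighted integrals of the
recorded entry flux via cumulative trapezoids and the tabulated inverse of
the entry-time map — equivalent to carrying three more delay equations but
without redundant state.  Halving dt moves day-7 totals by < 0.1 %;
trajectories are bit-reproducible.

The perturbation integral I(t₀) is computed by composite trapezoidal
quadrature over one period (spectrally accurate for periodic smooth
integrands; 4096 points by default, matching a 10⁵-point Riemann sum to
1e-8).  Degenerate (flat) integrals are flagged rather than reporting
meaningless argmaxima; the G1-drug route, which rests on a simulated
periodic profile, uses a correspondingly looser flatness floor (1e-7).

## Treatment scoring

R = N_treated/N_untreated at first administration + 168 h, both runs
sharing everything but the hazard.  E = R_H − R_C by default — the Taylor
limit of any smooth score increasing in host survival and decreasing in
tumor survival; a log-ratio variant is available (`outcome_score(...,
form="log")`).  Scan extrema are reported at the grid resolution (0.5 h
reference, matching the 15–30 min precision such tables are printed at)
with plateau detection when adjacent grid values differ by < 1e-3.

## TATO alignment and the duration-mod-24 identity

In I(t₀) the survival factor is indexed by the cohort's *S-entry* time, so
it multiplies κ̃ at the same entry time; aligning both factors at the
division time instead would displace every predicted extremum by the
transit time and break the closed-form rule (kill max at t_κ + T_S/2).
Because any strictly 24 h-periodic hazard is only seen by a transit window
modulo 24 h, the timing extrema for T_S and T_S − 24 coincide exactly; the
familiar statement that the extrema "shift by 12 h" above T_S = 24 h
describes the displacement of the true extrema from the naive continuation
of the sub-24 h line, and that is how the package reports it.

For the best/worst table the analytic prediction is outcome-level: each
response is approximated as R_X ≈ R̄_X exp(β_X Ĩ_X(t₀)) with R̄_X from the
period-averaged hazard in the renewal characteristic equation and
β_X = (dλ/dI) × (24 n_admin); the predicted E curve is then scanned like
the simulated one.  Per-population extrema (pure first harmonic, always
12 h apart) are available separately via `phase_extrema`.

## Calibration of the shipped presets

Fixed structural values: T̄_G2 = 3 h, T_M = 1 h, γ = 0.01 h⁻¹, basal death
rates 0.001 h⁻¹, T_S = 9/8/20 h (host / fast / slow), G2 modulation 0.1
(host) or 0.05 (tumors) peaking at 21:00 — a weak mitotic gate, with the
clock coupling deliberately stronger on the host.  Per population, bounded
Nelder–Mead (fixed start and settings, no randomness; idempotent because a
preset already inside tolerance short-circuits the optimizer) tunes
(κ̄, a_κ, t_κ) against three targets: daily S-fraction minimum, maximum and
peak clock time of the untreated post-transient solution.

Targets: host 20–30 % peaking at 12:00; fast tumor 15–30 %; slow tumor
42–47 %.  The tumor *peak times* are not independently constrained by the
fraction ranges, so they were fixed (fast 3.5 h, slow 17.0 h) by requiring
the downstream S-phase-drug timing landscape to reproduce the reference
optima — best time 2:00 against the fast tumor and 22:00 against the slow
tumor on the 0.5 h scan.  The drug intensity default k_max = 0.06 h⁻¹ was
chosen in the same calibration so that one 5-administration course leaves
mid-range responses (host R ≈ 0.54–0.64) rather than near-extermination;
at k_max ≳ 0.3 the deep kill saturates the slow tumor's timing signal.

What the calibrated presets do and do not show: they reproduce the daily
phase-fraction rhythms, the S-row timing structure (fast best 2:00, slow
best 22:00, a 4 h fast-vs-slow spread), analytic-vs-simulated agreement
within 2.5 h across all six phase × tumor cases, and the interval
trade-offs.  They do not reproduce two reference values.  (i) The
fast-tumor *worst* time lands at 14:30 rather than 17:30.  (ii) The
maximum fast-vs-slow best-time spread is 4.0 h (attained in the S row, where
the reference spread is also 4 h) rather than 9 h (reference G1 row).
Both have the same root cause: with the printed fraction ranges, the host's
timing amplitude in the outcome is ~2.5× either tumor's — the slow tumor's
±5.6 % relative S-fraction swing, further damped by the 20 h window
(sin(πT_S/24) = 0.5) and by kill-depth saturation, pins the G1 and G2/M
rows near host-shaped extrema regardless of the tumor phases.  Reaching a
9 h G1-row spread would need tumor timing amplitudes comparable to the
host's, which the printed fraction ranges exclude in this model family;
the corresponding checks are left failing rather than loosened.

## Synthetic conditions vs real tissues

All inputs are simulated.  The generator's populations are homogeneous:
no distribution of cell-cycle lengths beyond the exponential G1 stage, no
quiescent fraction distinct from G0/G1, no resistance, no pharmacokinetic
delay or inter-patient chronotype variability, identical drug action on
host and tumor.  Passing tests therefore demonstrate the internal
consistency of the model, its analytics and its numerics under these
idealised conditions — not clinical validity of any schedule.

## Problem sizes

Reference resolutions: timing scans 48 start times at 0.5 h, dt = 0.01 h,
horizon 72 + 24 + 168 h (the full table is 6 scans ≈ 300 simulations,
batched); calibration and secondary scans run at dt = 0.02–0.05 h with
coarser grids.  These sizes were chosen so every reported quantity is
grid-converged (halving the step moves extrema by at most one cell) while
a complete reproduction stays around a minute on one CPU.
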