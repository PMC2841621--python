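"""Resonance intervals of the clock-free model.

Ignore the circadian clock and let each administration kill every S-phase
cell.  Intervals up to T_S let no cell complete S alive (maximal kill);
the most sparing interval is where the refilled sensitive fraction is
minimal, a Lambert-W stationary point.
"""

import numpy as np

from chronocycle import clock_free_min_sensitive_time
from chronocycle.tato import clock_free_sensitive_fraction

ts, kappa = 8.0, 0.05
t_star = clock_free_min_sensitive_time(ts, kappa)
print(f"T_S = {ts} h, kappa = {kappa}/h")
print(f"most sparing re-administration time t* = {t_star:.3f} h after a kill")

for t in np.arange(1.0, 2 * ts + 0.5, 1.0):
    bar = "#" * int(200 * clock_free_sensitive_fraction(t, ts, kappa))
    print(f"  t = {t:4.1f} h  sensitive fraction "
          f"{clock_free_sensitive_fraction(t, ts, kappa):.4f} {bar}")
# The sensitive pool refills from G1, overshoots once the first post-kill
# cohorts divide, and dips at t*: dosing there repeatedly spares the
# population; dosing at any interval <= T_S repeatedly exterminates it.
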