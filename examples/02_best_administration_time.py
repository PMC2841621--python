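"""Scan the outcome E = R_H - R_C over the administration clock time.

One course = five daily chronomodulated administrations of an S-phase drug;
responses are treated/untreated cell-number ratios 7 days after the first
administration.  Coarse settings keep this quick; the reference resolution
is grid_step=0.5, dt=0.01.
"""

from chronocycle import Schedule, load_preset, scan_treatment_time

host = load_preset("host")
tumor = load_preset("tumor_fast")
schedule = Schedule(target_phase="S", k_max=0.06)

scan = scan_treatment_time(host, tumor, None, schedule,
                           grid_step=1.0, dt=0.02)
for t0, e, rh, rc in zip(scan.start_times[::3], scan.e[::3],
                         scan.r_host[::3], scan.r_tumor[::3]):
    print(f"start {t0:5.1f} h   E {e:+.3f}   R_H {rh:.3f}   R_C {rc:.3f}")
print(f"\nbest administration time {scan.best:.1f} h, worst {scan.worst:.1f} h")
# E > 0 means the host is spared more than the tumor. For this fast-growing
# tumor the best time is around 2:00 at night and the worst mid-afternoon.
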