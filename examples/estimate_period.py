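"""Estimate the cardiac period from a noisy quasi-periodic trace.

A 250 ms beat sampled at 0.1 ms for 20 cycles with 5% noise is recovered to
a few hundredths of a millisecond — inside the ±0.3 ms phase-lock window δ.
"""

import numpy as np

from cardiomorph import sync

true_period = 250.0  # ms
dt = 0.1  # ms
t = np.arange(0, 20 * true_period, dt)
rng = np.random.default_rng(0)
trace = np.sin(2 * np.pi * t / true_period) + rng.normal(0, 0.05, t.size)

est = sync.estimate_period(trace, dt, t_range=(150, 600), delta=0.3)
print(f"estimated period: {est.period:.4f} ms (true {true_period})")
print(f"beat-to-beat residual: {est.residual:.4f} ms (delta = {est.delta} ms)")
print(f"phase locked: {est.phase_locked}")

# bin 60 frames spanning three cycles into 20 canonical phases
times = np.arange(60) * (3 * est.period / 60)
bins = sync.bin_phases(times, est.period, 20)
print("frames per phase bin:", np.bincount(bins, minlength=20).tolist())
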