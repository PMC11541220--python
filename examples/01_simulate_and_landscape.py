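"""Simulate a three-state trapping trace and recover its energy landscape.

A single trapped serum-albumin monomer switches between native (N), fast (F)
and expanded (E) conformations; each state shifts the mean transmission
voltage through the nanoaperture.  We generate 100 s of a 100 kHz trace from
a designed ground truth (dG_NF = 1.0 k_BT, dG_FE = 0.5 k_BT, saddles at 3.5
and 4.0 k_BT), then run histogram -> Lucy-Richardson PSF deconvolution ->
Boltzmann inversion and read the thermodynamics off the landscape.
"""

import numpy as np

import trapscape as ts

spec = ts.design_three_state_spec(delta_g_nf=1.0, delta_g_fe=0.5,
                                  barrier_nf=3.5, barrier_fe=3.0,
                                  temperature=312.0)
acq = ts.AcquisitionSpec(duration=100.0, seed=42)
trace, truth = ts.simulate_trace(spec, acq)
print(f"simulated {trace.duration:.0f} s at {trace.sampling_rate:.0f} Hz "
      f"({trace.samples.size} samples), T = {trace.temperature} K")

report = ts.analyze_trace(trace, seed=1)
feats = report.features

print(f"\nrecovered {feats.n_states} states")
print("minima positions (V):", np.round(feats.minima_position, 4))
print("minima energies (k_BT):", np.round(feats.minima_energy, 3))
print("saddle energies (k_BT):", np.round(feats.saddle_energy, 3))
print(f"dG_NF = {feats.delta_g(0):.3f} k_BT (ground truth 1.0)")
print(f"dG_FE = {feats.delta_g(1):.3f} k_BT (ground truth 0.5)")
print(f"saddle heights = {np.round(feats.barrier_heights, 3)} (truth [3.5, 4.0])")
print("\nDeviations from truth reflect the finite trace: a 100 s trace holds")
print("only a few dozen N dwells, so state occupancies (hence dG) still")
print("fluctuate by several tenths of a k_BT; the 1000 s runs used for")
print("acceptance tighten the recovery to < 0.2 k_BT.")
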