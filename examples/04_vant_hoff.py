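"""Enthalpy-entropy decomposition of the N-F transition across temperature.

dG(T) for the N->F opening is constructed to follow a line dH - T dS (here
dH = 134.375 kcal/mol, dS = 0.43 kcal/mol/K, crossing zero mid-range, the
entropy-dominated regime reported for serum albumin); per-temperature traces
are analyzed independently and the van 't Hoff fit recovers dH and dS.
"""

import numpy as np

import trapscape as ts

dh_true, ds_true = 134.375, 0.43
temps = np.arange(310.0, 316.0, 1.0)
rng = np.random.default_rng(11)

entries = []
for t in temps:
    dg_kt = ts.kcal_to_kt(dh_true - ds_true * t, t)
    spec = ts.design_three_state_spec(delta_g_nf=dg_kt, delta_g_fe=0.5,
                                      temperature=t)
    trace, _ = ts.simulate_trace(spec, ts.AcquisitionSpec(duration=120.0),
                                 seed=rng)
    rep = ts.analyze_trace(trace, seed=rng, validate=False)
    entries.append({"temperature": t, "features": rep.features,
                    "residence": rep.residence})
    print(f"T = {t:.0f} K: dG_NF = {rep.features.delta_g(0):+.3f} k_BT = "
          f"{ts.kt_to_kcal(rep.features.delta_g(0), t):+.3f} kcal/mol")

series = ts.assemble_series(entries)
nf = series[series.transition == "NF"]
fit = ts.fit_enthalpy_entropy(nf.temperature_K.to_numpy(),
                              nf.delta_g_kcal_mol.to_numpy())
print(f"\ndH = {fit.delta_h:.1f} +- {fit.delta_h_se:.1f} kcal/mol "
      f"(construction {dh_true})")
print(f"dS = {fit.delta_s:.3f} +- {fit.delta_s_se:.3f} kcal/(mol K) "
      f"(construction {ds_true})")
print("\nA near-linear dG(T) with a large positive dS means the opening is")
print("entropy-driven: heating tilts the landscape toward the expanded forms.")
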