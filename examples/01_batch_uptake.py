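"""Batch uptake: from measured concentrations to adsorption capacity.

A 4.5 mL mixture holds 0.3 mg of adsorbent (300 uL of a 1 mg/mL
suspension). The drug concentration drops from 0.533 mg/mL to an
equilibrium value of 0.2797 mg/mL; the mass balance q = V (C0 - C) / m
turns that depletion into a loading per gram of carrier.
"""
from nanosorb import (
    BatchExperiment,
    capacity_at_equilibrium,
    concentration_from_absorbance,
    fit_calibration,
)

# calibrate the spectrophotometer on synthetic standards at 484 nm
standards = [(0.0, 0.002), (0.1, 0.182), (0.2, 0.361), (0.4, 0.722), (0.6, 1.081)]
curve = fit_calibration(standards)
print(f"standard curve: A = {curve.slope:.4f} C + {curve.intercept:.4f} "
      f"(R^2 = {curve.r_squared:.5f})")

# back-calculate the equilibrium concentration from a measured absorbance
ce = concentration_from_absorbance(curve, 0.505)
print(f"equilibrium concentration from A = 0.505: {ce:.4f} mg/mL")

exp = BatchExperiment(total_volume=4.5, adsorbent_mass=3e-4,
                      initial_concentration=0.533, measured_concentration=0.2797)
qe = capacity_at_equilibrium(exp)
print(f"equilibrium capacity: {qe:.1f} mg/g")
print("-> about 3800 mg of drug per gram of oxidized nanotubes: the "
      "plateau loading of the acid-treated carrier.")
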