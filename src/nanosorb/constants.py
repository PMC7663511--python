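"""Physical constants and study defaults shared across the package."""

#: Gas constant in kJ mol^-1 K^-1 (Temkin slope RT/b is reported in kJ mol^-1).
R_GAS_KJ = 8.314e-3

#: Default equilibrium temperature for isotherm work, K.
DEFAULT_TEMPERATURE_K = 298.15

#: Shaking times of the kinetic experiment, minutes.
SAMPLING_TIMES_MIN = (1.0, 3.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)

#: C-C bond length in graphitic carbon, nm.
CC_BOND_NM = 0.142

#: Default simulation box (x, y, z) in nm; the nanotube runs along y.
DEFAULT_BOX_NM = (20.0, 80.0, 20.0)

#: Default nanotube length, nm.
DEFAULT_TUBE_LENGTH_NM = 20.0

#: Wall diameters of the three-wall nanotube, nm (innermost first).
MWCNT_DIAMETERS_NM = (6.42, 7.12, 7.83)

#: Doxorubicin molar masses, g mol^-1 (free base / hydrochloride salt).
DOX_MOLAR_MASS_FREE_BASE = 543.52
DOX_MOLAR_MASS_HCL = 579.98

#: Carbon molar mass, g mol^-1.
CARBON_MOLAR_MASS = 12.011

#: Adsorbate:adsorbent mass ratio used for molecule-count fixtures.
DOX_CNT_MASS_RATIO = 4.0
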