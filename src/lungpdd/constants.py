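"""Physical constants and elemental data used across the package.

Values follow CODATA-2018; elemental mean excitation energies I follow the
ICRU-37 recommendations (as used by ESTAR).
"""

ELECTRON_REST_MEV = 0.51099895  # electron rest energy, MeV
CLASSICAL_E_RADIUS_CM = 2.8179403262e-13  # classical electron radius, cm
RE2_CM2 = CLASSICAL_E_RADIUS_CM**2
THOMSON_CM2 = 6.6524587321e-25  # Thomson cross section, cm^2
AVOGADRO = 6.02214076e23  # 1/mol
# 2*pi*re^2*me*c^2*NA in MeV cm^2 per mol: the Bethe-formula prefactor
# (multiply by Z/A and 1/beta^2)
BETHE_K = 0.1535374  # MeV cm^2/g per (Z/A)

# element symbol -> (Z, A [g/mol], I [eV])
ELEMENTS = {
    "H": (1, 1.008, 19.2),
    "Li": (3, 6.941, 40.0),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "F": (9, 18.998, 115.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
}

# TLD-100 chip: 3.0 x 3.0 x 0.9 mm face-on; the Monte Carlo scoring cylinder
# has the same cross-sectional area (pi r^2 = 0.09 cm^2).
CHIP_FACE_CM2 = 0.09
CHIP_THICKNESS_CM = 0.09
CHIP_RADIUS_CM = 0.16925687506432687  # sqrt(0.09/pi)

PAIR_THRESHOLD_MEV = 2 * ELECTRON_REST_MEV
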