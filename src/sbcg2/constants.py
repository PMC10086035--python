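"""Physical constants and unit conventions.

Internal units throughout the package: length in Angstrom, mass in amu,
charge in elementary charge e, energy in kcal/mol, temperature in Kelvin,
time in femtoseconds.

With this unit system, accelerations computed as force/mass carry a
conversion factor: 1 kcal/mol/A per amu equals ``MD_ACC`` A/fs^2.  The
harmonic angular frequency sqrt(K/mu) (K in kcal/mol/A^2, mu in amu) is in
units of 1/AKMA_TIME_FS radians per femtosecond.
"""

# Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

# Coulomb constant, kcal mol^-1 A e^-2
COULOMB = 332.0636

# (kcal/mol/A)/amu -> A/fs^2 :  4184 J/mol / (1e-10 m) / (1e-3 kg/mol) scaled
MD_ACC = 4.184e-4

# AKMA time unit in femtoseconds: sqrt(1 amu A^2 / (kcal/mol)) expressed in fs
AKMA_TIME_FS = 1.0 / MD_ACC**0.5  # = 48.8882...

# Element -> atomic mass (amu).  Unknown elements are an error upstream.
ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

# Element -> van der Waals radius (A), Bondi-style values.
ELEMENT_VDW = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NA": 2.27, "MG": 1.73, "P": 1.80, "S": 1.80, "CL": 1.75, "K": 2.75,
    "CA": 2.31, "MN": 2.05, "FE": 2.04, "CO": 2.00, "NI": 1.97,
    "CU": 1.96, "ZN": 2.01, "SE": 1.90, "BR": 1.85, "I": 1.98,
}

# Default hydrophobicity rule: carbon and sulfur atoms count as hydrophobic.
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})
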