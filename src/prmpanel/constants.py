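"""Physical constants for peptide mass and hydropathy calculations.

Monoisotopic residue masses (Da) for the 20 standard amino acids, the mass
of water and of a proton, and the Kyte–Doolittle hydropathy scale used by
the heuristic detectability/retention surrogate.
"""

# Monoisotopic residue (not free amino acid) masses, Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MASS = 1.007276

STANDARD_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASS)

# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5,
    "V": 4.2,
    "L": 3.8,
    "F": 2.8,
    "C": 2.5,
    "M": 1.9,
    "A": 1.8,
    "G": -0.4,
    "T": -0.7,
    "S": -0.8,
    "W": -0.9,
    "Y": -1.3,
    "P": -1.6,
    "H": -3.2,
    "E": -3.5,
    "Q": -3.5,
    "D": -3.5,
    "N": -3.5,
    "K": -3.9,
    "R": -4.5,
}
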