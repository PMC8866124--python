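"""Physical constants shared across the package.

Gyromagnetic ratios are the CODATA/IUPAC values, kept to at least five
significant digits.  Van der Waals radii are the Bondi set.
"""

from __future__ import annotations

import math

# Gyromagnetic ratios, rad s^-1 T^-1.
GAMMA = {
    "1H": 267.52218744e6,
    "1HN": 267.52218744e6,
    "15N": -27.126180e6,
    "13C": 67.282840e6,
}

#: |gamma_X / gamma_1H| for the nuclei the package models.
GAMMA_RATIO = {k: abs(v / GAMMA["1H"]) for k, v in GAMMA.items()}

PLANCK_HBAR = 1.054571817e-34  # J s
MU_0 = 4.0e-7 * math.pi  # T^2 m^3 J^-1

#: Bondi van der Waals radii, Angstrom, keyed by element symbol.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}

#: Default van der Waals radius for elements not in the table, Angstrom.
VDW_DEFAULT = 1.70

#: Probe cutoff used for pocket gridding, Angstrom (van der Waals radius of H).
HYDROGEN_CUTOFF = 1.09
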