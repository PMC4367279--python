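"""Small in-package datasets: printed parameter tables for medin fibrils.

These are the published benchmark numbers the analyses are anchored to —
measured ¹³C shifts of the three labelled residues of medin fibrils, the
ThT kinetic parameters of wild-type and D25N medin, and the experimental
REDOR pulse-train settings.  Raw instrument data are not redistributed;
synthetic stand-ins are produced by :mod:`fibrilstack.synth`.
"""
from __future__ import annotations

from .types import ShiftEntry, ShiftTable

#: Amyloid-promoting C-terminal fragment Med(42-49).
MEDIN_FRAGMENT = "NFGSVQFV"
MEDIN_FRAGMENT_START = 42

#: Measured ¹³C shifts (ppm) of medin fibrils uniformly labelled at
#: Ala13, Asp25 and Lys30 (DARR, 10-ms mixing).  The last Lys30 side-chain
#: carbon (42.5 ppm) is encoded as CE, lysine's terminal carbon.
_MEDIN_SHIFTS = [
    ("Ala", 13, "C'", 175.7), ("Ala", 13, "CA", 51.2), ("Ala", 13, "CB", 22.9),
    ("Asp", 25, "C'", 173.8), ("Asp", 25, "CA", 53.4), ("Asp", 25, "CB", 41.3),
    ("Asp", 25, "CG", 173.2),
    ("Lys", 30, "C'", 175.1), ("Lys", 30, "CA", 55.7), ("Lys", 30, "CB", 36.8),
    ("Lys", 30, "CG", 25.2), ("Lys", 30, "CD", 29.7), ("Lys", 30, "CE", 42.5),
]

#: β-sheet reference means (ppm) for the three labelled residue types:
#: {aa: {atom: ppm}} — the literature values quoted alongside the measured
#: shifts.
SHEET_REFERENCE = {
    "Ala": {"C'": 175.7, "CA": 51.4, "CB": 21.6},
    "Asp": {"C'": 174.1, "CA": 53.2, "CB": 42.9},
    "Lys": {"C'": 174.8, "CA": 55.5, "CB": 34.7},
}

#: ThT kinetic parameters (mean, with standard errors of the fits):
#: plateau fluorescence in RFU, elongation rate in h⁻¹, and the sigmoid
#: inflection times (h) consistent with the reported lag times.
THT_PARAMS = {
    "WT": {"max_fluorescence": 716.07, "max_fluorescence_se": 1.92,
           "rate": 1.28, "rate_se": 0.04, "r_squared": 0.985,
           "t_inflection": 28.5625},
    "D25N": {"max_fluorescence": 567.31, "max_fluorescence_se": 2.56,
             "rate": 1.43, "rate_se": 0.08, "r_squared": 0.951,
             "t_inflection": 27.40},
}

#: FSR REDOR experimental settings: MAS rate (Hz) and π-pulse train lengths.
FSR_SETUP = {"mas_rate": 7400.0, "pulse_trains": (82, 122), "correction_f": 0.25}

#: Distance bounds (Å) bracketing the observed Asp25 Cγ–Lys30 Nζ dephasing.
SALT_BRIDGE_BOUNDS = (3.2, 3.8)

#: Tryptophan emission components (center nm, FWHM nm): solvent-exposed
#: red component and buried blue component.
TRP_COMPONENTS = ((359.0, 60.0), (327.0, 40.0))


def medin_shift_table() -> ShiftTable:
    """The measured shift table for the three labelled medin residues."""
    return ShiftTable([ShiftEntry(*row) for row in _MEDIN_SHIFTS])
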