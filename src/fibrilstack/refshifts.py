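"""Reference ¹³C chemical shifts and carbon bond topology.

Per-residue mean backbone/Cβ shifts for the helix, sheet and coil classes
drive both shift prediction for spectrum simulation and secondary-structure
classification of observed shifts.  The coil column holds random-coil
reference values (ppm, DSS-referenced); helix and sheet columns are
derived from the coil values via the canonical secondary-shift offsets
(helix: C′ +1.9, Cα +2.6, Cβ −0.6; sheet: C′ −1.9, Cα −1.4, Cβ +2.2),
except for Ala, Asp and Lys whose sheet means are the tabulated
literature values used to benchmark fibril shifts.  Side-chain carbons
beyond Cβ always take coil reference values.

The secondary-shift sign convention holds throughout: for every residue
type, helix Cα > coil Cα > sheet Cα.
"""
from __future__ import annotations

from .errors import DomainError

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

SS_CLASSES = ("helix", "sheet", "coil")


def one_letter(residue: str) -> str:
    """Normalise a 1- or 3-letter residue code to its 1-letter form."""
    r = residue.strip().upper()
    if len(r) == 1 and r in AA1_TO_3:
        return r
    if r in AA3_TO_1:
        return AA3_TO_1[r]
    raise DomainError(f"unknown residue code {residue!r}")


# Random-coil backbone and Cbeta means, ppm: {aa: (C', CA, CB)}.
# Gly has no Cbeta (None).
COIL_BACKBONE: dict[str, tuple[float, float, float | None]] = {
    "A": (177.7, 52.8, 19.2),
    "R": (176.3, 56.0, 30.9),
    "N": (175.2, 53.1, 38.9),
    "D": (176.5, 54.6, 41.1),
    "C": (174.6, 58.2, 28.0),
    "Q": (176.0, 55.7, 29.4),
    "E": (176.6, 56.6, 29.9),
    "G": (174.9, 45.1, None),
    "H": (174.1, 55.0, 29.0),
    "I": (176.4, 61.1, 38.8),
    "L": (177.6, 55.1, 42.4),
    "K": (176.8, 56.7, 32.9),
    "M": (176.3, 55.4, 32.9),
    "F": (175.8, 57.7, 39.6),
    "P": (177.3, 63.3, 32.1),
    "S": (174.6, 58.3, 63.8),
    "T": (174.7, 61.8, 69.8),
    "W": (176.1, 57.5, 29.6),
    "Y": (175.9, 57.9, 38.8),
    "V": (176.3, 62.2, 32.9),
}

# Secondary-shift offsets applied to the coil means: (dC', dCA, dCB).
_HELIX_OFFSET = (1.9, 2.6, -0.6)
_SHEET_OFFSET = (-1.9, -1.4, 2.2)

# Literature sheet means for the residues with directly tabulated values.
_SHEET_OVERRIDE: dict[str, tuple[float, float, float]] = {
    "A": (175.7, 51.4, 21.6),
    "D": (174.1, 53.2, 42.9),
    "K": (174.8, 55.5, 34.7),
}

# Random-coil side-chain carbon shifts beyond Cbeta, ppm.
COIL_SIDECHAIN: dict[str, dict[str, float]] = {
    "R": {"CG": 27.1, "CD": 43.2},
    "N": {"CG": 176.8},
    "D": {"CG": 179.2},
    "Q": {"CG": 33.7, "CD": 179.9},
    "E": {"CG": 36.1, "CD": 183.0},
    "H": {"CG": 130.6, "CD2": 119.8, "CE1": 136.3},
    "I": {"CG1": 27.2, "CG2": 17.4, "CD1": 13.0},
    "L": {"CG": 26.9, "CD1": 24.6, "CD2": 23.8},
    "K": {"CG": 24.9, "CD": 29.0, "CE": 41.9},
    "M": {"CG": 32.0, "CE": 16.9},
    "F": {"CG": 138.9, "CD1": 131.5, "CD2": 131.5, "CE1": 130.9, "CE2": 130.9,
          "CZ": 129.4},
    "P": {"CG": 27.2, "CD": 49.9},
    "T": {"CG2": 21.5},
    "W": {"CG": 110.8, "CD1": 126.4, "CD2": 128.3, "CE2": 138.5, "CE3": 120.5,
          "CZ2": 114.2, "CZ3": 121.3, "CH2": 123.8},
    "Y": {"CG": 129.3, "CD1": 132.8, "CD2": 132.8, "CE1": 117.9, "CE2": 117.9,
          "CZ": 156.8},
    "V": {"CG1": 20.7, "CG2": 20.6},
}


def class_means() -> dict[str, dict[str, dict[str, float]]]:
    """Mean C′/Cα/Cβ shifts per residue and secondary-structure class.

    Returns {aa1: {class: {atom: ppm}}}, complete for the 20 standard
    residues (Gly omits Cβ).
    """
    means: dict[str, dict[str, dict[str, float]]] = {}
    for aa, (co, ca, cb) in COIL_BACKBONE.items():
        per_class: dict[str, dict[str, float]] = {}
        per_class["coil"] = {"C'": co, "CA": ca}
        per_class["helix"] = {"C'": co + _HELIX_OFFSET[0], "CA": ca + _HELIX_OFFSET[1]}
        if aa in _SHEET_OVERRIDE:
            s_co, s_ca, s_cb = _SHEET_OVERRIDE[aa]
            per_class["sheet"] = {"C'": s_co, "CA": s_ca}
        else:
            per_class["sheet"] = {"C'": co + _SHEET_OFFSET[0], "CA": ca + _SHEET_OFFSET[1]}
        if cb is not None:
            per_class["coil"]["CB"] = cb
            per_class["helix"]["CB"] = cb + _HELIX_OFFSET[2]
            per_class["sheet"]["CB"] = (_SHEET_OVERRIDE[aa][2] if aa in _SHEET_OVERRIDE
                                        else cb + _SHEET_OFFSET[2])
        means[aa] = per_class
    return means


# Directly bonded carbon-carbon pairs per residue type (symmetric; listed
# once).  Bonds through heteroatoms (Met S, His/Trp/Arg N) do not couple
# carbons and are omitted, so e.g. Met CE appears only as a diagonal peak.
CARBON_TOPOLOGY: dict[str, list[tuple[str, str]]] = {
    "G": [("C'", "CA")],
    "A": [("C'", "CA"), ("CA", "CB")],
    "S": [("C'", "CA"), ("CA", "CB")],
    "C": [("C'", "CA"), ("CA", "CB")],
    "T": [("C'", "CA"), ("CA", "CB"), ("CB", "CG2")],
    "V": [("C'", "CA"), ("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "L": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "I": [("C'", "CA"), ("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "M": [("C'", "CA"), ("CA", "CB"), ("CB", "CG")],
    "P": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")],
    "F": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
          ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "Y": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
          ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "W": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
          ("CD2", "CE3"), ("CD2", "CE2"), ("CE2", "CZ2"), ("CE3", "CZ3"),
          ("CZ2", "CH2"), ("CZ3", "CH2")],
    "D": [("C'", "CA"), ("CA", "CB"), ("CB", "CG")],
    "E": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")],
    "N": [("C'", "CA"), ("CA", "CB"), ("CB", "CG")],
    "Q": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")],
    "K": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE")],
    "R": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")],
    "H": [("C'", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD2")],
}


def bonded_pairs(residue: str) -> list[tuple[str, str]]:
    """Directly bonded carbon pairs for a residue (1- or 3-letter code)."""
    return list(CARBON_TOPOLOGY[one_letter(residue)])
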