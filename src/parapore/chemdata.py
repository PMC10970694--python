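"""Internal chemistry tables: van der Waals radii, formal charges, masses.

Radii follow the Bondi element set, which is also close to the radii HOLE
uses by default; downstream geometry (pore profiling, SASA) only needs the
set to be internally consistent.
"""
from __future__ import annotations

import logging

log = logging.getLogger("parapore")

# Bondi vdW radii, Å
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "NA": 2.27,
    "CL": 1.75,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
}
DEFAULT_VDW = 1.70

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
}
DEFAULT_MASS = 12.011

# Backbone atom names for amino acids (hydrogens included when present).
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "H1", "H2", "H3"}
)

STANDARD_AA = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Residue-level formal charges at neutral pH; HIS treated as neutral.
RESIDUE_CHARGES: dict[str, int] = {"ARG": +1, "LYS": +1, "ASP": -1, "GLU": -1}

# Monatomic ion residues: residue name -> (element, formal charge)
ION_RESIDUES: dict[str, tuple[str, int]] = {
    "NA": ("NA", +1),
    "SOD": ("NA", +1),
    "CL": ("CL", -1),
    "CLA": ("CL", -1),
    "K": ("K", +1),
    "POT": ("K", +1),
    "MG": ("MG", +2),
}

# The single side-chain atom that carries the residue's formal charge in the
# per-atom bookkeeping (the choice is conventional; residue sums are what matter).
CHARGE_BEARING_ATOM: dict[str, str] = {
    "ARG": "CZ",
    "LYS": "NZ",
    "ASP": "CG",
    "GLU": "CD",
}

# Heavy atoms of the charged side-chain group, used for "electrostatic
# interaction" persistence counting (4 Å cutoff).
CHARGED_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

_warned_elements: set[str] = set()


def vdw_radius(element: str) -> float:
    """Bondi vdW radius for *element*; unknown elements fall back to 1.70 Å."""
    el = element.upper()
    r = VDW_RADII.get(el)
    if r is None:
        if el not in _warned_elements:
            log.warning("unknown element %r: using vdW radius %.2f Å", element, DEFAULT_VDW)
            _warned_elements.add(el)
        return DEFAULT_VDW
    return r


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


def infer_element(atom_name: str, residue_name: str) -> str:
    """Guess the element from PDB atom/residue names when the element column
    is blank.  Ion residues map by residue name; otherwise the first
    alphabetic character of the atom name (digits-first names are hydrogens).
    """
    res = residue_name.strip().upper()
    if res in ION_RESIDUES:
        return ION_RESIDUES[res][0]
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        return "H"
    return name[0].upper()


def formal_charge_for_atom(residue_name: str, atom_name: str) -> int:
    """Formal charge carried by this atom under the residue-level convention."""
    res = residue_name.strip().upper()
    if res in ION_RESIDUES:
        return ION_RESIDUES[res][1]
    if RESIDUE_CHARGES.get(res) and CHARGE_BEARING_ATOM.get(res) == atom_name.strip().upper():
        return RESIDUE_CHARGES[res]
    return 0
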