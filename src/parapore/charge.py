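"""Pore electrostatic fingerprint from pore-lining residue lists.

A paracellular pore lined by a tetrameric scaffold presents each lining
residue (roughly) four times; summing the formal charges of the listed
residues times their multiplicity — excluding residues whose charge is
shielded by persistent salt-bridge partners — gives the pore's net-charge
fingerprint, the first-order predictor of charge selectivity: a strongly
positive pore attracts anions, a negative one cations.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .chemdata import ONE_TO_THREE, RESIDUE_CHARGES

__all__ = [
    "PoreLiningSpec", "formal_charge", "pore_net_charge", "charge_ladder",
    "CLDN10A_PORE_LINING", "CLDN10B_PORE_LINING",
]

log = logging.getLogger("parapore")


def formal_charge(residue_name: str) -> int:
    """Formal side-chain charge of a residue at neutral pH, by 3-letter name:
    ARG/LYS +1, ASP/GLU −1, HIS (and everything else) 0."""
    res = residue_name.strip().upper()
    if len(res) == 3 and (res in RESIDUE_CHARGES or res in ONE_TO_THREE.values()):
        return RESIDUE_CHARGES.get(res, 0)
    log.warning("unknown residue name %r: assuming formal charge 0", residue_name)
    return 0


def _parse_residue(token: str) -> tuple[str, int]:
    """Parse 'K139' or 'LYS139' into (3-letter name, number)."""
    token = token.strip()
    i = 0
    while i < len(token) and token[i].isalpha():
        i += 1
    name, num = token[:i].upper(), int(token[i:])
    if len(name) == 1:
        name = ONE_TO_THREE.get(name, name)
    return name, num


@dataclass(frozen=True)
class PoreLiningSpec:
    """Residues lining one pore of a given claudin subtype.

    ``multiplicity`` is how many copies of each listed residue face the pore
    (4 for the tetrameric scaffold; interlocking-neighbour contributions also
    appear four times per pore).  ``shielded`` residues are excluded from the
    net sum (their charge is neutralised by persistent partners).
    """

    name: str
    residues: tuple[str, ...]
    multiplicity: int = 4
    shielded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be ≥ 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PoreLiningSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            residues=tuple(d["residues"]),
            multiplicity=int(d.get("multiplicity", 4)),
            shielded=tuple(d.get("shielded", ())),
        )


def charge_ladder(spec: PoreLiningSpec) -> list[dict]:
    """Per-residue charge contributions along the pore (shielded residues
    listed with zero contribution)."""
    ladder = []
    shielded = {_parse_residue(s) for s in spec.shielded}
    for token in spec.residues:
        name, num = _parse_residue(token)
        q = formal_charge(name)
        is_shielded = (name, num) in shielded
        ladder.append(
            {
                "residue": f"{name}{num}",
                "charge": q,
                "multiplicity": spec.multiplicity,
                "shielded": is_shielded,
                "contribution": 0 if is_shielded else q * spec.multiplicity,
            }
        )
    return ladder


def pore_net_charge(spec: PoreLiningSpec) -> int:
    """Net pore charge: Σ over non-shielded listed residues of
    formal_charge × multiplicity (elementary charges)."""
    return sum(entry["contribution"] for entry in charge_ladder(spec))


def fingerprint_json(spec: PoreLiningSpec) -> str:
    return json.dumps(
        {
            "species": spec.name,
            "net_charge": pore_net_charge(spec),
            "ladder": charge_ladder(spec),
        },
        indent=2,
    )


#: CLDN10a middle-pore lining (anion-selective subtype): the listed residues
#: face the pore 4× each; K153/E155 are mutually shielded and excluded.
CLDN10A_PORE_LINING = PoreLiningSpec(
    name="CLDN10a",
    residues=("K29", "R33", "N54", "H60", "R62", "K69",
              "E143", "D146", "K139", "E151"),
    multiplicity=4,
    shielded=("K153", "E155"),
)

#: CLDN10b middle-pore lining (cation-selective subtype); K155/E157 shielded.
CLDN10B_PORE_LINING = PoreLiningSpec(
    name="CLDN10b",
    residues=("K31", "D36", "D56", "N62", "K64", "D73",
              "E145", "D148", "K141", "E153"),
    multiplicity=4,
    shielded=("K155", "E157"),
)
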