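"""Shared fixtures: programmatically built toy structures and trajectories."""
from __future__ import annotations

import numpy as np
import pytest

from parapore.model import AtomRecord, Frame, Topology, Trajectory, classify_atom


def make_atom(
    atom_id: int,
    name: str = "CA",
    resname: str = "ALA",
    resnum: int = 1,
    chain: str = "A",
    element: str | None = None,
    vdw: float = 1.7,
    charge: int = 0,
) -> AtomRecord:
    el = element or (name[0] if name[0].isalpha() else "C")
    bb, sc = classify_atom(name, resname)
    return AtomRecord(atom_id, name, el, resname, resnum, chain, vdw, bb, sc, charge)


def backbone_residue(atom_id0: int, resnum: int, chain: str, origin, resname="GLY",
                     direction=(3.8, 0.0, 0.0)):
    """Four backbone atoms (N, CA, C, O) of one residue laid out along
    *direction* from *origin*; returns (records, coords, next_atom_id)."""
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float) / np.linalg.norm(direction)
    offsets = {"N": 0.0, "CA": 1.2, "C": 2.4, "O": 3.0}
    records, coords = [], []
    aid = atom_id0
    for name, off in offsets.items():
        records.append(make_atom(aid, name, resname, resnum, chain))
        coords.append(origin + off * d)
        aid += 1
    return records, coords, aid


def random_oligomer(rng: np.random.Generator, n_chains=5, n_res=10, atoms_per_res=3,
                    n_frames=5, spread=20.0):
    """Random multi-chain, multi-frame toy system for oracle comparisons."""
    records, aid = [], 1
    names = ["N", "CA", "CB", "CG", "O"][:atoms_per_res]
    chains = [chr(ord("A") + c) for c in range(n_chains)]
    resnames = ["ALA", "ARG", "GLU", "LYS", "SER"]
    for c, chain in enumerate(chains):
        for r in range(1, n_res + 1):
            resname = resnames[(c + r) % len(resnames)]
            for name in names:
                records.append(make_atom(aid, name, resname, r, chain))
                aid += 1
    topo = Topology(records)
    frames = [
        Frame(time=float(t), coords=rng.uniform(-spread, spread, size=(topo.n_atoms, 3)))
        for t in range(n_frames)
    ]
    return Trajectory(topo, frames)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def oligomer(rng):
    return random_oligomer(rng)
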