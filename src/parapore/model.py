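"""Core data model: atoms, topologies, frames, trajectories and selections.

Conventions used throughout the package:

* all coordinates are in Å;
* the pore axis is +x (geometry operations take the axis as a parameter
  defaulting to +x); the membrane normal is z;
* times are in ns; frames are uniformly spaced (tolerance 1e-6 ns), so every
  time statistic can be reported as a fraction of frames.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chemdata import BACKBONE_ATOMS, STANDARD_AA, atomic_mass
from .errors import EmptySelectionWarning, SelectionError, ShapeError

STRIDE_TOL_NS = 1e-6


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership and per-atom chemistry."""

    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    vdw_radius: float
    is_backbone: bool
    is_sidechain: bool
    formal_charge: int = 0

    @property
    def mass(self) -> float:
        return atomic_mass(self.element)


def classify_atom(atom_name: str, residue_name: str) -> tuple[bool, bool]:
    """(is_backbone, is_sidechain) for an atom of a (possibly non-standard)
    residue.  Non-amino-acid residues (ions, pseudo-atoms) are neither."""
    if residue_name.strip().upper() not in STANDARD_AA:
        return False, False
    bb = atom_name.strip().upper() in BACKBONE_ATOMS
    return bb, not bb


@dataclass(frozen=True)
class Residue:
    """A view of one residue of a Topology: its identity and atom indices."""

    chain_id: str
    number: int
    name: str
    atom_indices: tuple[int, ...]

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}"


class Topology:
    """Ordered atom metadata.  The atom order is the canonical coordinate
    order of every Frame of a Trajectory built on this topology."""

    def __init__(self, atoms: Iterable[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in seen:
                raise ShapeError(
                    f"duplicate atom (chain {a.chain_id!r}, residue "
                    f"{a.residue_number}, atom {a.atom_name!r}) in topology"
                )
            if a.vdw_radius <= 0:
                raise ShapeError(f"non-positive vdW radius on atom {a.atom_id}")
            seen.add(key)
        # vectorised views used by selections and geometry
        self.chain_ids = np.array([a.chain_id for a in self.atoms], dtype=object)
        self.residue_numbers = np.array([a.residue_number for a in self.atoms], dtype=np.int64)
        self.residue_names = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.atom_names = np.array([a.atom_name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element for a in self.atoms], dtype=object)
        self.vdw_radii = np.array([a.vdw_radius for a in self.atoms], dtype=np.float64)
        self.backbone_mask = np.array([a.is_backbone for a in self.atoms], dtype=bool)
        self.sidechain_mask = np.array([a.is_sidechain for a in self.atoms], dtype=bool)
        self.formal_charges = np.array([a.formal_charge for a in self.atoms], dtype=np.int64)
        self.masses = np.array([a.mass for a in self.atoms], dtype=np.float64)

        self._residues: list[Residue] = []
        self._residue_index: dict[tuple[str, int], Residue] = {}
        cur_key: tuple[str, int] | None = None
        cur_idx: list[int] = []
        cur_name = ""
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_number)
            if key != cur_key:
                if cur_key is not None:
                    self._push_residue(cur_key, cur_name, cur_idx)
                cur_key, cur_idx, cur_name = key, [], a.residue_name
            cur_idx.append(i)
        if cur_key is not None:
            self._push_residue(cur_key, cur_name, cur_idx)

    def _push_residue(self, key: tuple[str, int], name: str, idx: list[int]) -> None:
        res = Residue(key[0], key[1], name, tuple(idx))
        if key in self._residue_index:
            # non-contiguous residue: merge atom indices, keep order
            old = self._residue_index[key]
            res = Residue(key[0], key[1], old.name, old.atom_indices + res.atom_indices)
            self._residues[self._residues.index(old)] = res
        else:
            self._residues.append(res)
        self._residue_index[key] = res

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self) -> list[Residue]:
        return list(self._residues)

    def residue(self, chain_id: str, number: int) -> Residue:
        try:
            return self._residue_index[(chain_id, number)]
        except KeyError:
            raise SelectionError(
                f"residue {number} of chain {chain_id!r} not found"
            ) from None

    def index_of(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        res = self.residue(chain_id, residue_number)
        for i in res.atom_indices:
            if self.atoms[i].atom_name == atom_name:
                return i
        raise SelectionError(
            f"atom {atom_name!r} not found in {res.name}{residue_number} "
            f"(chain {chain_id!r})"
        )

    def subset(self, indices: Sequence[int]) -> "Topology":
        return Topology([self.atoms[i] for i in indices])

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return f"<Topology: {self.n_atoms} atoms, {len(self._residues)} residues, chains {self.chains}>"


@dataclass
class Frame:
    """One coordinate set: time (ns), per-atom xyz in Å, optional box."""

    time: float
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"frame coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("frame contains non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


class Trajectory:
    """A topology plus time-ordered frames at uniform stride.

    ``x_unwrap_offset`` (optional, shape (n_frames, n_atoms)) carries the
    periodic-wrap bookkeeping of the synthetic generator: adding it to the
    stored x coordinate gives the unwrapped x used by displacement sums.
    """

    def __init__(
        self,
        topology: Topology,
        frames: Sequence[Frame],
        x_unwrap_offset: np.ndarray | None = None,
    ):
        self.topology = topology
        self.frames = list(frames)
        if not self.frames:
            raise ShapeError("trajectory must contain at least one frame")
        for i, f in enumerate(self.frames):
            if f.n_atoms != topology.n_atoms:
                raise ShapeError(
                    f"frame {i} has {f.n_atoms} atoms, topology has {topology.n_atoms}"
                )
        times = np.array([f.time for f in self.frames], dtype=np.float64)
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ShapeError("frame times must be strictly increasing")
            if np.max(dt) - np.min(dt) > STRIDE_TOL_NS:
                raise ShapeError(
                    "non-uniform frame stride: time-fraction statistics assume "
                    "uniform frame weighting"
                )
        self._times = times
        if x_unwrap_offset is not None:
            x_unwrap_offset = np.asarray(x_unwrap_offset, dtype=np.float64)
            if x_unwrap_offset.shape != (len(self.frames), topology.n_atoms):
                raise ShapeError("x_unwrap_offset must be (n_frames, n_atoms)")
        self.x_unwrap_offset = x_unwrap_offset

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self._times

    @property
    def stride(self) -> float:
        if len(self._times) < 2:
            return 0.0
        return float(self._times[1] - self._times[0])

    def coords(self) -> np.ndarray:
        """All coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])

    def unwrapped_axis_coords(self, axis: int = 0) -> np.ndarray:
        """Per-frame per-atom coordinate along *axis* with wraps undone.

        Preference order: explicit wrap bookkeeping (synthetic runs);
        minimum-image continuity using the box length along the axis;
        otherwise the raw coordinate.
        """
        x = np.stack([f.coords[:, axis] for f in self.frames])
        if axis == 0 and self.x_unwrap_offset is not None:
            return x + self.x_unwrap_offset
        box = self.frames[0].box
        if box is not None and box[axis] > 0:
            period = float(box[axis])
            dx = np.diff(x, axis=0)
            dx -= period * np.round(dx / period)
            return np.concatenate([x[:1], x[:1] + np.cumsum(dx, axis=0)])
        return x

    def __len__(self) -> int:
        return self.n_frames

    def __repr__(self) -> str:
        return (
            f"<Trajectory: {self.n_frames} frames x {self.topology.n_atoms} atoms, "
            f"stride {self.stride:g} ns>"
        )


@dataclass(frozen=True)
class Selection:
    """A structured, order-stable atom predicate.

    All criteria are conjunctive; ``None`` means "no constraint".  Residue
    numbers may be given as an inclusive range, an explicit set, or both.
    """

    chains: frozenset[str] | None = None
    resnum_range: tuple[int, int] | None = None
    resnums: frozenset[int] | None = None
    resnames: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    backbone: bool | None = None  # True: backbone only; False: side chain only

    def resolve(self, topology: Topology) -> np.ndarray:
        """Matching atom indices, sorted ascending (a pure function of
        (expression, topology)).  Zero matches → EmptySelectionWarning."""
        mask = np.ones(topology.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(topology.chain_ids, list(self.chains))
        if self.resnum_range is not None:
            lo, hi = self.resnum_range
            mask &= (topology.residue_numbers >= lo) & (topology.residue_numbers <= hi)
        if self.resnums is not None:
            mask &= np.isin(topology.residue_numbers, list(self.resnums))
        if self.resnames is not None:
            mask &= np.isin(topology.residue_names, list(self.resnames))
        if self.atom_names is not None:
            mask &= np.isin(topology.atom_names, list(self.atom_names))
        if self.backbone is True:
            mask &= topology.backbone_mask
        elif self.backbone is False:
            mask &= topology.sidechain_mask
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            warnings.warn(
                f"selection {self!r} matched zero atoms", EmptySelectionWarning,
                stacklevel=2,
            )
        return idx

    def matches(self, atom: AtomRecord) -> bool:
        """Scalar predicate equivalent of :meth:`resolve` (reference path)."""
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.resnum_range is not None and not (
            self.resnum_range[0] <= atom.residue_number <= self.resnum_range[1]
        ):
            return False
        if self.resnums is not None and atom.residue_number not in self.resnums:
            return False
        if self.resnames is not None and atom.residue_name not in self.resnames:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.backbone is True and not atom.is_backbone:
            return False
        if self.backbone is False and not atom.is_sidechain:
            return False
        return True

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse a simple textual selection.

        Clauses joined by ``and``: ``chain A,B`` — ``resid 59:63`` or
        ``resid 12,13`` — ``resname BNK,ENT`` — ``name CA,CB`` —
        ``backbone`` / ``sidechain``.  Example::

            Selection.parse("chain A and resid 59:63 and backbone")
        """
        sel = cls()
        text = text.strip()
        if not text or text.lower() == "all":
            return sel
        for clause in [c.strip() for c in text.split(" and ")]:
            parts = clause.split(None, 1)
            kw = parts[0].lower()
            if kw == "backbone" and len(parts) == 1:
                sel = replace(sel, backbone=True)
            elif kw == "sidechain" and len(parts) == 1:
                sel = replace(sel, backbone=False)
            elif kw in {"chain", "resname", "name", "resid"} and len(parts) == 2:
                vals = [v for v in parts[1].replace(",", " ").split() if v]
                if kw == "chain":
                    sel = replace(sel, chains=frozenset(vals))
                elif kw == "resname":
                    sel = replace(sel, resnames=frozenset(vals))
                elif kw == "name":
                    sel = replace(sel, atom_names=frozenset(vals))
                else:  # resid
                    nums: set[int] = set()
                    rng: tuple[int, int] | None = None
                    for v in vals:
                        if ":" in v:
                            lo, hi = v.split(":")
                            rng = (int(lo), int(hi))
                        else:
                            nums.add(int(v))
                    sel = replace(
                        sel,
                        resnum_range=rng,
                        resnums=frozenset(nums) if nums else None,
                    )
            else:
                raise SelectionError(f"cannot parse selection clause {clause!r}")
        return sel


def resolve_window(window, n_frames: int) -> range:
    """Normalise a window specifier to a range of frame indices.

    Accepted forms: ``None`` (all frames), a ``range``, an ``(start, stop)``
    tuple (half-open), ``"last:F"`` with fraction F in (0, 1], or
    ``"frames:A:B"`` (half-open, 0-based).  The conventional analysis window
    is the last half of the run (``"last:0.5"``).
    """
    if window is None:
        return range(n_frames)
    if isinstance(window, range):
        out = window
    elif isinstance(window, tuple):
        out = range(window[0], window[1])
    elif isinstance(window, str):
        spec = window.strip().lower()
        if spec.startswith("last:"):
            frac = float(spec.split(":", 1)[1])
            if not 0 < frac <= 1:
                raise ShapeError(f"window fraction must be in (0, 1]: {window!r}")
            start = n_frames - max(1, int(round(frac * n_frames)))
            out = range(start, n_frames)
        elif spec.startswith("frames:"):
            _, a, b = spec.split(":")
            out = range(int(a), int(b))
        else:
            raise ShapeError(f"cannot parse window {window!r}")
    else:
        raise ShapeError(f"cannot parse window {window!r}")
    if out.start < 0 or out.stop > n_frames or len(out) == 0:
        raise ShapeError(
            f"window {window!r} is empty or outside the trajectory (n_frames={n_frames})"
        )
    return out
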