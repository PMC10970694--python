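"""Scalar and time-series interface metrics.

* backbone hydrogen-bond counts between two strand segments;
* named atom-pair distance series averaged over equivalent interfaces;
* persistence-thresholded contact (salt-bridge-like) pair counts;
* Shrake–Rupley solvent-accessible surface area, optionally normalised per
  side-chain heavy-atom;
* backbone RMSD with optimal rigid superposition (Kabsch).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import ConfigError, ParameterError, SelectionError
from .model import Frame, Selection, Topology, Trajectory, resolve_window

__all__ = [
    "HBondCriterion", "count_backbone_hbonds", "atom_pair_distance_series",
    "PairDistanceSeries", "persistent_pair_count", "PersistenceResult",
    "sasa", "SasaResult", "backbone_rmsd", "fibonacci_sphere",
]


# --------------------------------------------------------------------------
# hydrogen bonds

@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond definition.

    With explicit hydrogens: donor–acceptor (N…O) distance ≤
    ``donor_acceptor_max`` and D–H…A angle ≥ ``angle_min`` (120° default).
    Heavy-atom-only fallback: N…O distance plus C(=O)…N angle at the
    acceptor ≥ ``angle_min`` (100° default).  These are the common
    literature criteria; both parameters are explicit because published
    analyses rarely state the suite defaults they used.
    """

    donor_acceptor_max: float = 3.5
    angle_min: float | None = None
    heavy_atom_only: bool = True

    def __post_init__(self) -> None:
        if self.donor_acceptor_max <= 0:
            raise ParameterError("donor_acceptor_max must be positive")
        if self.angle_min is not None and not 0 <= self.angle_min <= 180:
            raise ParameterError("angle_min must be within [0, 180] degrees")

    @property
    def resolved_angle_min(self) -> float:
        if self.angle_min is not None:
            return self.angle_min
        return 100.0 if self.heavy_atom_only else 120.0


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _backbone_polar(topology: Topology, idx: np.ndarray):
    """(N indices, O indices) among backbone atoms of a selection."""
    names = topology.atom_names[idx]
    n_idx = idx[(names == "N")]
    o_idx = idx[(names == "O") | (names == "OXT")]
    return n_idx, o_idx


def count_backbone_hbonds(
    frame: Frame,
    topology: Topology,
    segA: Selection,
    segB: Selection,
    crit: HBondCriterion = HBondCriterion(),
) -> int:
    """Backbone N–H…O=C hydrogen bonds between two segments (both
    directions).  See :class:`HBondCriterion` for the geometry."""
    ia, ib = segA.resolve(topology), segB.resolve(topology)
    count = 0
    for don_seg, acc_seg in ((ia, ib), (ib, ia)):
        n_idx, _ = _backbone_polar(topology, don_seg)
        _, o_idx = _backbone_polar(topology, acc_seg)
        if n_idx.size == 0 and o_idx.size == 0:
            raise SelectionError("segment contains no backbone N or O atoms")
        for n in n_idx:
            for o in o_idx:
                if not _is_hbond(frame, topology, int(n), int(o), crit):
                    continue
                count += 1
    return count


def _is_hbond(frame: Frame, topology: Topology, n: int, o: int,
              crit: HBondCriterion) -> bool:
    coords = frame.coords
    d_no = float(np.linalg.norm(coords[n] - coords[o]))
    if d_no > crit.donor_acceptor_max:
        return False
    amin = crit.resolved_angle_min
    atom_n = topology.atoms[n]
    atom_o = topology.atoms[o]
    if crit.heavy_atom_only:
        # angle at the acceptor O between O→C (its carbonyl C) and O→N
        try:
            c = topology.index_of(atom_o.chain_id, atom_o.residue_number, "C")
        except SelectionError:
            return True  # no carbonyl carbon present: distance-only
        ang = _angle_deg(coords[c] - coords[o], coords[n] - coords[o])
        return ang >= amin
    # explicit-hydrogen mode: any amide H on the donor N
    res = topology.residue(atom_n.chain_id, atom_n.residue_number)
    h_atoms = [i for i in res.atom_indices
               if topology.atoms[i].atom_name in ("H", "HN", "H1", "H2", "H3")]
    for h in h_atoms:
        ang = _angle_deg(coords[n] - coords[h], coords[o] - coords[h])
        if ang >= amin:
            return True
    return False


# --------------------------------------------------------------------------
# atom-pair distance series

@dataclass
class PairDistanceSeries:
    """Per-frame mean distance over a set of equivalent atom pairs, plus
    per-pair time means and SDs over the analysed window."""

    times: np.ndarray
    per_frame_mean: np.ndarray
    per_pair: np.ndarray  # (n_frames, n_pairs)
    pair_labels: list[str]
    pair_means: np.ndarray
    pair_sds: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.per_frame_mean.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_pair, columns=self.pair_labels)
        df.insert(0, "time_ns", self.times)
        df["mean"] = self.per_frame_mean
        return df


AtomRef = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


def atom_pair_distance_series(
    traj: Trajectory,
    pairs: list[tuple[AtomRef, AtomRef]],
    window=None,
) -> PairDistanceSeries:
    """Distance time series for named atom pairs (e.g. the Cγ–Cγ distance of
    an F68–L156 contact at every equivalent interface), averaged per frame
    over the pairs."""
    win = resolve_window(window, traj.n_frames)
    topo = traj.topology
    ia = np.array([topo.index_of(*a) for a, _ in pairs])
    ib = np.array([topo.index_of(*b) for _, b in pairs])
    labels = [f"{a[0]}{a[1]}:{a[2]}-{b[0]}{b[1]}:{b[2]}" for a, b in pairs]
    d = np.empty((len(win), len(pairs)))
    times = np.empty(len(win))
    for k, fi in enumerate(win):
        coords = traj.frames[fi].coords
        d[k] = np.linalg.norm(coords[ia] - coords[ib], axis=1)
        times[k] = traj.frames[fi].time
    return PairDistanceSeries(
        times=times,
        per_frame_mean=d.mean(axis=1),
        per_pair=d,
        pair_labels=labels,
        pair_means=d.mean(axis=0),
        pair_sds=d.std(axis=0),
    )


# --------------------------------------------------------------------------
# persistence counting

@dataclass
class PersistenceResult:
    """Fraction of window frames each pair interacts, and the count of pairs
    above the persistence threshold (strict >)."""

    pair_labels: list[str]
    fraction_of_frames: np.ndarray
    threshold: float
    contact_max: float

    @property
    def count_above_threshold(self) -> int:
        return int(np.sum(self.fraction_of_frames > self.threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.pair_labels,
                "fraction_of_frames": self.fraction_of_frames,
                "persistent": self.fraction_of_frames > self.threshold,
            }
        )


def persistent_pair_count(
    traj: Trajectory,
    pairs: list[tuple[Selection, Selection]],
    contact_max: float = 4.0,
    threshold: float = 0.35,
    window=None,
    labels: list[str] | None = None,
) -> PersistenceResult:
    """Count pairs interacting in more than *threshold* of the window frames.

    A pair interacts in a frame iff the minimum distance between the two
    selections' atoms is ≤ *contact_max* (pass selections restricted to the
    charged-group heavy atoms for electrostatic-interaction counting; the
    4 Å default matches the ion-contact cutoff).
    """
    win = resolve_window(window, traj.n_frames)
    topo = traj.topology
    resolved = [(a.resolve(topo), b.resolve(topo)) for a, b in pairs]
    frac = np.zeros(len(pairs))
    for fi in win:
        coords = traj.frames[fi].coords
        for p, (ia, ib) in enumerate(resolved):
            if ia.size and ib.size and cdist(coords[ia], coords[ib]).min() <= contact_max:
                frac[p] += 1
    frac /= len(win)
    if labels is None:
        labels = [f"pair{p}" for p in range(len(pairs))]
    return PersistenceResult(labels, frac, threshold, contact_max)


# --------------------------------------------------------------------------
# SASA (Shrake–Rupley with a deterministic Fibonacci-sphere lattice)

def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-residue solvent-accessible surface areas (Å²)."""

    residue_labels: list[str]
    area: np.ndarray
    normalized_area: np.ndarray  # area / side-chain heavy-atom count
    per_atom_area: dict[int, float]
    probe_radius: float
    selection_label: str = ""

    @property
    def total(self) -> float:
        return float(self.area.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_labels,
                "area_A2": self.area,
                "normalized_area_A2": self.normalized_area,
            }
        )


def sasa(
    frame: Frame,
    topology: Topology,
    selection: Selection | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake–Rupley SASA of the selected atoms (all atoms occlude).

    Each atom's sphere of radius r_vdw + probe is sampled with a
    deterministic Fibonacci lattice; the exposed-point fraction times the
    sphere area gives the per-atom SASA.  Per-residue sums are also reported
    normalised by the residue's side-chain heavy-atom count (a proxy for
    residue size in heavy-atom models).
    """
    if n_points < 16:
        raise ParameterError("n_points must be ≥ 16")
    if probe < 0:
        raise ParameterError("probe radius must be ≥ 0")
    idx = (selection.resolve(topology) if selection is not None
           else np.arange(topology.n_atoms))
    if idx.size == 0:
        raise SelectionError("SASA selection is empty")
    coords = frame.coords
    radii = topology.vdw_radii + probe
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = float(radii.max())
    per_atom: dict[int, float] = {}
    for i in idx:
        i = int(i)
        ri = radii[i]
        pts = coords[i] + ri * unit
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        if neigh:
            d = cdist(pts, coords[neigh])
            buried = (d < radii[neigh][None, :]).any(axis=1)
            exposed = n_points - int(buried.sum())
        else:
            exposed = n_points
        per_atom[i] = (exposed / n_points) * 4.0 * np.pi * ri * ri

    # per-residue aggregation
    labels: list[str] = []
    areas: list[float] = []
    norm: list[float] = []
    for res in topology.residues():
        sel_atoms = [i for i in res.atom_indices if i in per_atom]
        if not sel_atoms:
            continue
        area = float(sum(per_atom[i] for i in sel_atoms))
        sc_heavy = sum(
            1 for i in res.atom_indices
            if topology.sidechain_mask[i] and topology.elements[i] != "H"
        )
        labels.append(f"{res.chain_id}/{res.label}")
        areas.append(area)
        norm.append(area / sc_heavy if sc_heavy else np.nan)
    return SasaResult(labels, np.array(areas), np.array(norm), per_atom, probe)


# --------------------------------------------------------------------------
# RMSD

def backbone_rmsd(
    traj: Trajectory,
    selection: Selection,
    reference: Frame,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms to a reference frame,
    after optimal rigid-body superposition if *superpose*."""
    idx = selection.resolve(traj.topology)
    if idx.size == 0:
        raise SelectionError("RMSD selection is empty")
    if superpose and idx.size < 3:
        raise ConfigError("superposition needs at least 3 atoms")
    ref = reference.coords[idx]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    for k, f in enumerate(traj.frames):
        mob = f.coords[idx]
        if superpose:
            mob_c = mob - mob.mean(axis=0)
            _, rssd = Rotation.align_vectors(ref_c, mob_c)
            out[k] = rssd / np.sqrt(idx.size)
        else:
            out[k] = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
    return out
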