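"""Residue–residue contact-map fingerprints.

A contact map summarises an interface as the matrix of mean closest-atom
distances between the residues of two regions, averaged over a time window
and over all equivalent interfaces of an oligomer (an :class:`InterfaceGroup`).
The mean is a single flat mean over (frame × interface) samples.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, SelectionError
from .model import Frame, Selection, Topology, Trajectory, resolve_window

__all__ = ["InterfaceGroup", "ContactMap", "min_residue_distance", "contact_map",
           "classify_contacts"]


@dataclass(frozen=True)
class InterfaceGroup:
    """A named set of equivalent interfaces to average over.

    Each pair is (SelectionA, SelectionB); the map axes are defined by the
    inclusive residue-number ranges of the two regions (residue numbering is
    assumed equivalent across the interfaces of the group).
    """

    name: str
    pairs: tuple[tuple[Selection, Selection], ...]
    regionA_range: tuple[int, int]
    regionB_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ConfigError("interface group needs at least one pair")


@dataclass
class ContactMap:
    """Mean closest-atom distances (Å) between two residue ranges."""

    row_residues: list[str]
    col_residues: list[str]
    row_numbers: list[int]
    col_numbers: list[int]
    mean_distance: np.ndarray
    n_samples: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_distance, index=self.row_residues,
                            columns=self.col_residues)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="residue")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "row_residues": self.row_residues,
                "col_residues": self.col_residues,
                "mean_distance": self.mean_distance.tolist(),
                "n_samples": self.n_samples.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def min_residue_distance(
    frame: Frame,
    topology: Topology,
    resA: tuple[str, int],
    resB: tuple[str, int],
) -> float:
    """Closest-atom (minimum over all atom pairs) distance between two
    residues, identified as (chain_id, residue_number)."""
    a = topology.residue(*resA)
    b = topology.residue(*resB)
    ca = frame.coords[list(a.atom_indices)]
    cb = frame.coords[list(b.atom_indices)]
    return float(cdist(ca, cb).min())


def _region_residues(topology: Topology, sel_idx: np.ndarray,
                     rng: tuple[int, int]):
    """Residues (ordered by number) of a selection restricted to a residue
    range; returns (labels, numbers, per-residue atom-index arrays)."""
    nums = topology.residue_numbers[sel_idx]
    order: dict[int, list[int]] = {}
    names: dict[int, str] = {}
    for i, n in zip(sel_idx, nums):
        n = int(n)
        if rng[0] <= n <= rng[1]:
            order.setdefault(n, []).append(int(i))
            names[n] = str(topology.residue_names[i])
    numbers = sorted(order)
    labels = [f"{names[n]}{n}" for n in numbers]
    groups = [np.array(order[n]) for n in numbers]
    return labels, numbers, groups


def contact_map(traj: Trajectory, group: InterfaceGroup, window=None) -> ContactMap:
    """Mean closest-atom distance map over a window and an interface group.

    Entry (i, j) is the flat mean, over every window frame and every pair of
    the group, of the minimum atom–atom distance between residue i of region
    A and residue j of region B.
    """
    win = resolve_window(window, traj.n_frames)
    topo = traj.topology

    resolved = []
    row_labels = row_numbers = col_labels = col_numbers = None
    for selA, selB in group.pairs:
        ia, ib = selA.resolve(topo), selB.resolve(topo)
        if ia.size == 0 or ib.size == 0:
            raise SelectionError(f"interface group {group.name!r}: empty side")
        la, na, ga = _region_residues(topo, ia, group.regionA_range)
        lb, nb, gb = _region_residues(topo, ib, group.regionB_range)
        if row_numbers is None:
            row_labels, row_numbers, col_labels, col_numbers = la, na, lb, nb
        elif na != row_numbers or nb != col_numbers:
            raise ConfigError(
                f"interface group {group.name!r}: residue numbering differs "
                "between pairs"
            )
        resolved.append((ga, gb))

    nr, nc = len(row_numbers), len(col_numbers)
    acc = np.zeros((nr, nc))
    n_samples = np.zeros((nr, nc), dtype=np.int64)
    for fi in win:
        coords = traj.frames[fi].coords
        for ga, gb in resolved:
            flat_a = np.concatenate(ga)
            flat_b = np.concatenate(gb)
            d = cdist(coords[flat_a], coords[flat_b])
            # reduce atom-pair distances to residue-pair minima (block-wise)
            ao = np.cumsum([0] + [len(g) for g in ga])
            bo = np.cumsum([0] + [len(g) for g in gb])
            mins = np.empty((nr, nc))
            for i in range(nr):
                da = d[ao[i]:ao[i + 1]]
                for j in range(nc):
                    mins[i, j] = da[:, bo[j]:bo[j + 1]].min()
            acc += mins
            n_samples += 1
    return ContactMap(row_labels, col_labels, row_numbers, col_numbers,
                      acc / np.maximum(n_samples, 1), n_samples)


def classify_contacts(cmap: ContactMap, threshold: float = 5.0) -> np.ndarray:
    """Boolean contact matrix: mean distance strictly below *threshold* Å
    (the conventional 5 Å close-contact cutoff)."""
    return cmap.mean_distance < threshold
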