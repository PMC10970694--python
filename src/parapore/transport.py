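"""Ion-permeation statistics for paracellular channel trajectories.

The workflow mirrors how charge selectivity is read out of applied-field
simulations of a claudin-type pore:

1. the crossing plane is the per-frame centre of mass of the bottleneck
   tetrad (four symmetry-equivalent residues at the pore centre);
2. an axis-aligned cuboid, bounded by the entrance-residue Cα coordinates,
   restricts counting to ions that actually traverse the pore rather than
   leaking around it;
3. the total displacement D of the selected ions is the telescoping sum of
   their frame-to-frame axis-coordinate increments, D = Σ_i Σ_t
   (x_i(t+1) − x_i(t)) — a conductance proxy, signed with direction;
4. regressing D against voltage per ion species gives the selectivity
   slopes (an anion-selective pore has |slope_Cl| ≫ |slope_Na|).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .chemdata import atomic_mass
from .errors import ConfigError, ParaporeError
from .model import Frame, Selection, Topology, Trajectory, resolve_window

__all__ = [
    "CuboidBounds", "CrossingRecord", "TransportResult", "SelectivityFit",
    "bottleneck_com", "cuboid_bounds", "detect_pore_passing_ions",
    "total_displacement", "mean_ion_count", "ion_contact_time",
    "selectivity_regression", "run_transport_analysis",
]


@dataclass(frozen=True)
class CuboidBounds:
    """Axis-aligned box through the pore (Å)."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        for lo, hi, ax in ((self.x_lo, self.x_hi, "x"), (self.y_lo, self.y_hi, "y"),
                           (self.z_lo, self.z_hi, "z")):
            if lo >= hi:
                raise ConfigError(f"cuboid {ax} bounds must satisfy lo < hi")

    def contains(self, coords: np.ndarray, strict_x: bool = False) -> np.ndarray:
        """Vectorised membership; y/z strict, x closed unless *strict_x*."""
        x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
        if strict_x:
            ok_x = (x > self.x_lo) & (x < self.x_hi)
        else:
            ok_x = (x >= self.x_lo) & (x <= self.x_hi)
        return (
            ok_x
            & (y > self.y_lo) & (y < self.y_hi)
            & (z > self.z_lo) & (z < self.z_hi)
        )


@dataclass(frozen=True)
class CrossingRecord:
    """First bottleneck crossing of one ion."""

    ion_id: int  # atom_id of the ion
    species: str
    frame: int  # first frame of the crossing step (t of the t→t+1 step)
    direction: int  # sign of the x motion at the crossing
    inside_cuboid: bool


@dataclass
class SpeciesTransport:
    species: str
    total_displacement: float  # Å, signed
    n_selected: int
    mean_ion_count: float
    crossings: list[CrossingRecord] = field(default_factory=list)


@dataclass
class TransportResult:
    """Per-voltage transport summary for all species."""

    voltage: float
    species: dict[str, SpeciesTransport]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "voltage": self.voltage,
                "species": {
                    s: {
                        "total_displacement_A": r.total_displacement,
                        "n_selected": r.n_selected,
                        "mean_ion_count": r.mean_ion_count,
                    }
                    for s, r in self.species.items()
                },
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "TransportResult":
        d = json.loads(Path(path).read_text())
        return cls(
            voltage=d["voltage"],
            species={
                s: SpeciesTransport(
                    s, r["total_displacement_A"], r["n_selected"], r["mean_ion_count"]
                )
                for s, r in d["species"].items()
            },
        )


def bottleneck_com(
    frame: Frame,
    topology: Topology,
    tetrad: Selection,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Centre of the bottleneck tetrad (unweighted centre of geometry by
    default; mass weighting optional).  The tetrad must resolve to atoms of
    exactly four residues."""
    idx = tetrad.resolve(topology)
    _check_tetrad(topology, idx)
    c = frame.coords[idx]
    if mass_weighted:
        w = np.array([atomic_mass(topology.atoms[i].element) for i in idx])
        return np.average(c, axis=0, weights=w)
    return c.mean(axis=0)


def _check_tetrad(topology: Topology, idx: np.ndarray) -> None:
    residues = {(topology.atoms[int(i)].chain_id, topology.atoms[int(i)].residue_number)
                for i in idx}
    if len(residues) != 4:
        raise ConfigError(
            f"bottleneck tetrad must span exactly 4 residues, got {len(residues)}"
        )


def cuboid_bounds(traj: Trajectory, entrance_ca: Selection, window=None) -> CuboidBounds:
    """Cuboid bounds from the window-averaged positions of the 8 entrance
    Cα atoms (4 per pore end): per-axis min/max."""
    idx = entrance_ca.resolve(traj.topology)
    if idx.size != 8:
        raise ConfigError(f"entrance selection must resolve to 8 Cα atoms, got {idx.size}")
    win = resolve_window(window, traj.n_frames)
    mean_pos = np.mean([traj.frames[fi].coords[idx] for fi in win], axis=0)
    lo = mean_pos.min(axis=0)
    hi = mean_pos.max(axis=0)
    return CuboidBounds(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


def detect_pore_passing_ions(
    traj: Trajectory,
    tetrad: Selection,
    cuboid: CuboidBounds,
    species: str,
    window=None,
    require_inside: str = "at-crossing",
) -> list[CrossingRecord]:
    """Ions of *species* that cross the bottleneck-COM x-plane inside the cuboid.

    A crossing is a pair of consecutive window frames where
    sign(x_ion − x_COM) changes and the ion lies inside the cuboid at both
    frames (y/z strictly, x within bounds).  One record per ion — the first
    crossing — so displacement sums never double-count an ion.
    ``require_inside="always"`` additionally demands cuboid membership at
    every window frame (the stricter whole-transit reading).
    """
    if require_inside not in ("at-crossing", "always"):
        raise ConfigError(f"unknown require_inside mode {require_inside!r}")
    win = resolve_window(window, traj.n_frames)
    topo = traj.topology
    ion_idx = np.flatnonzero(topo.residue_names == species)
    frames = list(win)
    pos = np.stack([traj.frames[fi].coords[ion_idx] for fi in frames])  # (T, n, 3)
    com_x = np.array(
        [bottleneck_com(traj.frames[fi], topo, tetrad)[0] for fi in frames]
    )
    side = np.sign(pos[:, :, 0] - com_x[:, None])
    inside = cuboid.contains(pos)  # (T, n)
    crossed = (side[:-1] * side[1:] < 0)
    if require_inside == "at-crossing":
        eligible = inside[:-1] & inside[1:]
    else:
        eligible = np.all(inside, axis=0)[None, :] & np.ones_like(crossed, dtype=bool)
    events = crossed & eligible
    records: list[CrossingRecord] = []
    for j in range(len(ion_idx)):
        ts = np.flatnonzero(events[:, j])
        if ts.size == 0:
            continue
        t = int(ts[0])
        dx = pos[t + 1, j, 0] - pos[t, j, 0]
        records.append(
            CrossingRecord(
                ion_id=topo.atoms[int(ion_idx[j])].atom_id,
                species=species,
                frame=frames[t],
                direction=int(np.sign(dx)) or 1,
                inside_cuboid=bool(inside[t, j] and inside[t + 1, j]),
            )
        )
    return records


def total_displacement(
    traj: Trajectory,
    ion_ids,
    window=None,
    axis: int = 0,
) -> float:
    """Total displacement D (Å, signed) of the given ions along the pore axis.

    D = Σ over ions Σ over consecutive window frames of (x(t+1) − x(t)) on
    the unwrapped coordinate; by telescoping this equals
    Σ over ions of (x(t_end) − x(t_start)).  Empty selection → 0 with a
    warning.
    """
    ion_ids = list(ion_ids)
    if not ion_ids:
        warnings.warn("total_displacement over an empty ion selection", stacklevel=2)
        return 0.0
    win = resolve_window(window, traj.n_frames)
    id_to_idx = {a.atom_id: i for i, a in enumerate(traj.topology.atoms)}
    try:
        cols = [id_to_idx[i] for i in ion_ids]
    except KeyError as e:
        raise ConfigError(f"unknown ion id {e.args[0]}") from None
    x = traj.unwrapped_axis_coords(axis)[list(win)][:, cols]
    return float(np.diff(x, axis=0).sum())


def mean_ion_count(
    traj: Trajectory,
    cuboid: CuboidBounds,
    species: str,
    window=None,
) -> float:
    """Mean number of *species* ions strictly inside the cuboid per frame."""
    win = resolve_window(window, traj.n_frames)
    ion_idx = np.flatnonzero(traj.topology.residue_names == species)
    if ion_idx.size == 0:
        return 0.0
    counts = [
        int(cuboid.contains(traj.frames[fi].coords[ion_idx], strict_x=True).sum())
        for fi in win
    ]
    return float(np.mean(counts))


def ion_contact_time(
    traj: Trajectory,
    residue_groups: dict[str, list[tuple[str, int]]],
    species: str,
    cutoff: float = 4.0,
    window=None,
) -> dict[str, float]:
    """Percentage of window frames each residue spends closer than *cutoff*
    to at least one *species* ion, averaged over the subunit copies.

    *residue_groups* maps a residue label (e.g. ``"H60"``) to its
    symmetry-equivalent instances as (chain_id, residue_number).
    """
    win = resolve_window(window, traj.n_frames)
    topo = traj.topology
    ion_idx = np.flatnonzero(topo.residue_names == species)
    out: dict[str, float] = {}
    for label, instances in residue_groups.items():
        pcts = []
        for chain, num in instances:
            res = topo.residue(chain, num)
            aidx = np.array(res.atom_indices)
            hits = 0
            for fi in win:
                coords = traj.frames[fi].coords
                if ion_idx.size and cdist(coords[aidx], coords[ion_idx]).min() < cutoff:
                    hits += 1
            pcts.append(100.0 * hits / len(win))
        out[label] = float(np.mean(pcts)) if pcts else 0.0
    return out


@dataclass
class SpeciesFit:
    species: str
    slope: float  # Å / V
    intercept: float  # Å
    r_squared: float
    stderr: float
    points: list[tuple[float, float]]


@dataclass
class SelectivityFit:
    """Per-species OLS fit of total displacement against voltage."""

    species: dict[str, SpeciesFit]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                s: {
                    "slope_A_per_V": f.slope,
                    "intercept_A": f.intercept,
                    "r_squared": f.r_squared,
                    "stderr": f.stderr,
                    "points": f.points,
                }
                for s, f in self.species.items()
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def selectivity_regression(results: list[TransportResult]) -> SelectivityFit:
    """OLS fit of D vs voltage per species over a set of transport results.

    Requires at least two distinct voltages.  The slope (Å/V) is the
    selectivity read-out: the conducting species shows a large-magnitude
    slope with high R², the excluded species a near-zero slope.
    """
    by_species: dict[str, list[tuple[float, float]]] = {}
    for r in results:
        for s, st in r.species.items():
            by_species.setdefault(s, []).append((r.voltage, st.total_displacement))
    fits: dict[str, SpeciesFit] = {}
    for s, pts in by_species.items():
        v = np.array([p[0] for p in pts])
        d = np.array([p[1] for p in pts])
        if np.unique(v).size < 2:
            raise ParaporeError(
                f"selectivity fit for {s!r} needs ≥ 2 distinct voltages"
            )
        res = stats.linregress(v, d)
        fits[s] = SpeciesFit(
            species=s,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            stderr=float(res.stderr),
            points=sorted(pts),
        )
    return SelectivityFit(fits)


def run_transport_analysis(
    traj: Trajectory,
    tetrad: Selection,
    entrances: Selection,
    species: list[str],
    voltage: float,
    window=None,
    require_inside: str = "at-crossing",
) -> TransportResult:
    """Convenience pipeline: cuboid → crossings → D and mean counts per species."""
    cuboid = cuboid_bounds(traj, entrances, window)
    out: dict[str, SpeciesTransport] = {}
    for sp in species:
        crossings = detect_pore_passing_ions(
            traj, tetrad, cuboid, sp, window, require_inside
        )
        ids = [c.ion_id for c in crossings]
        if ids:
            d = total_displacement(traj, ids, window)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = 0.0
        out[sp] = SpeciesTransport(
            species=sp,
            total_displacement=d,
            n_selected=len(ids),
            mean_ion_count=mean_ion_count(traj, cuboid, sp, window),
            crossings=crossings,
        )
    return TransportResult(voltage=voltage, species=out)
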