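"""Synthetic toy-pore scaffolds and drift–diffusion ion trajectories.

The generator emulates the statistical structure the analysis layer assumes
about a paracellular channel system:

* a roughly cylindrical pore of known radius spanning the junction along +x,
  built from pseudo-atoms on a shell so that a probe cannot escape radially;
* marker residue tetrads: four ``BNK`` residues at the pore centre (the
  bottleneck tetrad whose centre of mass defines the crossing plane) and
  four ``ENT`` residues with a Cα at each pore entrance (the corners of the
  cuboid filter);
* ions of two species performing drift–diffusion along the pore axis with
  species- and voltage-dependent drift — charge-selective mobility without
  explicit electrostatics.

The x boundary is periodic with bookkeeping: an ion leaving beyond
``±(L/2 + 5)`` re-enters at the opposite end, and the accumulated offset is
recorded so displacement statistics can use the unwrapped coordinate.  This
gives a stationary steady-state flux; the ion-leakage problem of a real
periodic simulation box is deliberately absent.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, ParameterError
from .model import AtomRecord, Frame, Topology, Trajectory
from . import pdbio

__all__ = [
    "SynthPoreParams",
    "SynthIonParams",
    "build_toy_pore",
    "simulate_ion_walk",
    "preset_drifts",
    "write_run",
    "read_run",
    "MOBILITY_A_PER_FRAME_PER_V",
]

#: drift per frame per volt used by the presets (Å frame⁻¹ V⁻¹), chosen so a
#: 0.4 V bias produces the canonical 0.1 Å/frame reference drift.
MOBILITY_A_PER_FRAME_PER_V = 0.25

EXIT_MARGIN = 5.0  # ions are wrapped at x = ±(L/2 + EXIT_MARGIN)


@dataclass(frozen=True)
class SynthPoreParams:
    """Geometry of the toy pore.

    Scaffold pseudo-atoms sit on a shell of radius ``pore_radius +
    scaffold_atom_radius``, so the maximal inscribed sphere radius along the
    axis is ``pore_radius``.  ``constriction_rings`` adds rings of atoms with
    centres at the given radius (inscribed radius = ring radius − atom
    radius) at the given x stations.
    """

    pore_radius: float = 5.0
    pore_length: float = 60.0
    scaffold_atom_radius: float = 1.5
    axial_spacing: float = 1.0
    angular_count: int | None = None  # default: ceil(2π(R+a)/a)
    include_marker_tetrads: bool = True
    constriction_rings: tuple[tuple[float, float], ...] = ()  # (x, ring radius)
    scaffold: bool = True  # False: markers only (transport-only runs)

    def resolved_angular_count(self) -> int:
        shell = self.pore_radius + self.scaffold_atom_radius
        min_count = math.ceil(2 * math.pi * shell / self.scaffold_atom_radius)
        return self.angular_count if self.angular_count is not None else min_count

    def validate(self) -> None:
        if self.pore_radius <= self.scaffold_atom_radius:
            raise GeometryError("pore_radius must exceed scaffold_atom_radius")
        if self.pore_length <= 0:
            raise GeometryError("pore_length must be positive")
        shell = self.pore_radius + self.scaffold_atom_radius
        min_count = math.ceil(2 * math.pi * shell / self.scaffold_atom_radius)
        if self.resolved_angular_count() < min_count:
            raise GeometryError(
                f"angular_count {self.resolved_angular_count()} leaves radial gaps "
                f"wider than the scaffold atom radius (need ≥ {min_count})"
            )
        if self.axial_spacing > 2 * self.scaffold_atom_radius:
            raise GeometryError(
                "axial_spacing leaves radial gaps wider than the scaffold atom radius"
            )


@dataclass(frozen=True)
class SynthIonParams:
    """Drift–diffusion walk settings.

    ``drift_per_frame`` maps species residue name (``NA``/``CL``) to a
    signed drift in Å/frame — the voltage-scaled, charge-selective mobility.
    """

    n_ions_per_species: int = 20
    drift_per_frame: dict[str, float] = field(
        default_factory=lambda: {"NA": 0.0, "CL": 0.0}
    )
    diffusion_sigma: float = 0.2
    n_frames: int = 1000
    seed: int = 0
    voltage: float = 0.0  # volts, metadata label for selectivity fits
    stride_ns: float = 0.1

    def validate(self) -> None:
        if self.diffusion_sigma < 0:
            raise ParameterError("diffusion_sigma must be ≥ 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be ≥ 2")
        if self.n_ions_per_species < 0:
            raise ParameterError("n_ions_per_species must be ≥ 0")


def preset_drifts(preset: str, voltage: float,
                  mobility: float = MOBILITY_A_PER_FRAME_PER_V) -> dict[str, float]:
    """Species drift maps for the standard study conditions.

    ``anion-selective``: only Cl⁻ responds to voltage (CLDN10a-like);
    ``cation-selective``: only Na⁺ responds (CLDN10b-like);
    ``nonselective``: both species drift identically (null control for the
    zero-selectivity test).
    """
    mu = mobility * voltage
    if preset == "anion-selective":
        return {"CL": mu, "NA": 0.0}
    if preset == "cation-selective":
        return {"NA": mu, "CL": 0.0}
    if preset == "nonselective":
        return {"NA": mu, "CL": mu}
    raise ParameterError(f"unknown preset {preset!r}")


def build_toy_pore(params: SynthPoreParams) -> tuple[Topology, Frame]:
    """Build the static pore scaffold (plus marker tetrads) at time 0."""
    params.validate()
    R, L, a = params.pore_radius, params.pore_length, params.scaffold_atom_radius
    shell = R + a
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    atom_id = 1

    def add_ring(x: float, radius: float, resnum: int, resname: str) -> int:
        nonlocal atom_id
        n_ang = params.resolved_angular_count()
        theta = 2 * np.pi * np.arange(n_ang) / n_ang
        for j in range(n_ang):
            records.append(
                AtomRecord(
                    atom_id=atom_id,
                    atom_name=f"S{j:03d}",
                    element="C",
                    residue_name=resname,
                    residue_number=resnum,
                    chain_id="P",
                    vdw_radius=a,
                    is_backbone=False,
                    is_sidechain=False,
                )
            )
            coords.append(
                np.array([x, radius * np.cos(theta[j]), radius * np.sin(theta[j])])
            )
            atom_id += 1
        return resnum + 1

    resnum = 1
    if params.scaffold:
        n_rings = int(round(L / params.axial_spacing)) + 1
        xs = np.linspace(-L / 2, L / 2, n_rings)
        for x in xs:
            resnum = add_ring(float(x), shell, resnum, "CYL")
        for cx, cr in params.constriction_rings:
            if cr <= a:
                raise GeometryError("constriction ring radius must exceed atom radius")
            resnum = add_ring(float(cx), float(cr), resnum, "CON")

    if params.include_marker_tetrads:
        # bottleneck tetrad: 4 single-atom BNK residues at x=0, 90° apart on
        # the shell; their centre of geometry is exactly (0, 0, 0)
        for k in range(4):
            ang = k * np.pi / 2
            records.append(
                AtomRecord(atom_id, "CB", "C", "BNK", k + 1, "M", a, False, False)
            )
            coords.append(np.array([0.0, shell * np.cos(ang), shell * np.sin(ang)]))
            atom_id += 1
        # entrance markers: 4 Cα per pore end at the cuboid corners, slightly
        # outside the pore radius so every in-pore ion is strictly inside in y/z
        corner = R + 1.0
        num = 5
        for sx in (-1.0, 1.0):
            for sy, sz in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                records.append(
                    AtomRecord(atom_id, "CA", "C", "ENT", num, "M", a, False, False)
                )
                coords.append(np.array([sx * L / 2, sy * corner, sz * corner]))
                atom_id += 1
                num += 1

    topo = Topology(records)
    return topo, Frame(time=0.0, coords=np.array(coords))


def simulate_ion_walk(
    pore: tuple[Topology, Frame],
    ions: SynthIonParams,
    pore_params: SynthPoreParams | None = None,
) -> Trajectory:
    """Drift–diffusion walk of two ion species inside the pore cylinder.

    Ions start uniformly at random inside the cylinder (radius R, the pore
    span in x).  Each frame every ion takes a Gaussian step of width
    ``diffusion_sigma`` in each coordinate plus its species drift along x;
    the radial wall at R reflects, and the x boundary at ±(L/2 + 5) wraps to
    the opposite end with offset bookkeeping.  Fully deterministic given the
    seed: all randomness comes from one ``numpy`` Generator, drawn in a fixed
    order (initial positions species-by-species in the order of
    ``drift_per_frame``, then one (n_ions, 3) normal block per frame).
    """
    ions.validate()
    pore_topo, pore_frame = pore
    pp = pore_params or SynthPoreParams()
    R, L = pp.pore_radius, pp.pore_length
    x_edge = L / 2 + EXIT_MARGIN
    period = 2 * x_edge

    rng = np.random.default_rng(ions.seed)
    species = list(ions.drift_per_frame.keys())
    n_per = ions.n_ions_per_species
    n_ions = n_per * len(species)

    # ion atoms appended after the pore atoms
    next_id = (max(a.atom_id for a in pore_topo.atoms) + 1) if pore_topo.n_atoms else 1
    ion_records = []
    drift = np.empty(n_ions)
    for s_i, sp in enumerate(species):
        for k in range(n_per):
            ion_records.append(
                AtomRecord(
                    atom_id=next_id,
                    atom_name=sp,
                    element=sp,
                    residue_name=sp,
                    residue_number=s_i * n_per + k + 1,
                    chain_id="I",
                    vdw_radius={"NA": 2.27, "CL": 1.75}.get(sp, 2.0),
                    is_backbone=False,
                    is_sidechain=False,
                    formal_charge={"NA": +1, "CL": -1}.get(sp, 0),
                )
            )
            next_id += 1
        drift[s_i * n_per : (s_i + 1) * n_per] = ions.drift_per_frame[sp]

    topo = Topology(pore_topo.atoms + ion_records)

    # initial positions: uniform in the cylinder, species by species
    pos = np.empty((n_ions, 3))
    for s_i in range(len(species)):
        sl = slice(s_i * n_per, (s_i + 1) * n_per)
        r = R * np.sqrt(rng.uniform(size=n_per))
        ang = rng.uniform(0, 2 * np.pi, size=n_per)
        pos[sl, 0] = rng.uniform(-L / 2, L / 2, size=n_per)
        pos[sl, 1] = r * np.cos(ang)
        pos[sl, 2] = r * np.sin(ang)

    box = np.array([period, 2 * (R + pp.scaffold_atom_radius) + 4, 2 * (R + pp.scaffold_atom_radius) + 4])
    frames: list[Frame] = []
    offsets = np.zeros((ions.n_frames, topo.n_atoms))
    ion_off = np.zeros(n_ions)
    pore_coords = pore_frame.coords

    def record(i: int) -> None:
        frames.append(
            Frame(
                time=i * ions.stride_ns,
                coords=np.vstack([pore_coords, pos]) if pore_topo.n_atoms else pos.copy(),
                box=box,
            )
        )
        offsets[i, topo.n_atoms - n_ions :] = ion_off

    record(0)
    for t in range(1, ions.n_frames):
        step = rng.normal(0.0, ions.diffusion_sigma, size=(n_ions, 3))
        pos = pos + step
        pos[:, 0] += drift
        # reflecting radial wall at R
        rad = np.hypot(pos[:, 1], pos[:, 2])
        over = rad > R
        if np.any(over):
            scale = np.clip(2 * R - rad[over], 0.0, R) / rad[over]
            pos[over, 1] *= scale
            pos[over, 2] *= scale
        # periodic x with wrap bookkeeping (unwrapped x = stored x + offset)
        hi = pos[:, 0] > x_edge
        lo = pos[:, 0] < -x_edge
        pos[hi, 0] -= period
        ion_off[hi] += period
        pos[lo, 0] += period
        ion_off[lo] -= period
        record(t)

    return Trajectory(topo, frames, x_unwrap_offset=offsets)


def ion_indices(traj: Trajectory, species: str) -> np.ndarray:
    """Atom indices of all single-atom ion residues of *species*."""
    return np.flatnonzero(traj.topology.residue_names == species)


def write_run(
    outdir: str | Path,
    traj: Trajectory,
    pore_params: SynthPoreParams,
    ion_params: SynthIonParams,
) -> None:
    """Persist a synthetic run: scaffold PDB + ion frame-table CSV + params JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ion_mask = traj.topology.chain_ids == "I"
    pore_idx = np.flatnonzero(~ion_mask)
    ion_idx = np.flatnonzero(ion_mask)
    pore_topo = traj.topology.subset(pore_idx)
    pdbio.write_structure(outdir / "pore.pdb", pore_topo, Frame(0.0, traj.frames[0].coords[pore_idx]))
    ion_topo = traj.topology.subset(ion_idx)
    ion_frames = [Frame(f.time, f.coords[ion_idx], box=f.box) for f in traj.frames]
    pdbio.write_frame_table(outdir / "ions.csv", Trajectory(ion_topo, ion_frames))
    params = {
        "pore": {k: getattr(pore_params, k) for k in (
            "pore_radius", "pore_length", "scaffold_atom_radius", "axial_spacing",
            "include_marker_tetrads", "scaffold")},
        "ions": {
            "n_ions_per_species": ion_params.n_ions_per_species,
            "drift_per_frame": ion_params.drift_per_frame,
            "diffusion_sigma": ion_params.diffusion_sigma,
            "n_frames": ion_params.n_frames,
            "seed": ion_params.seed,
            "voltage": ion_params.voltage,
            "stride_ns": ion_params.stride_ns,
        },
        "x_period": pore_params.pore_length + 2 * EXIT_MARGIN,
    }
    (outdir / "params.json").write_text(json.dumps(params, indent=2))


def read_run(outdir: str | Path) -> tuple[Trajectory, dict]:
    """Reload a persisted run as one combined trajectory.

    Unwrap offsets are reconstructed by minimum-image continuity with the
    recorded x period (valid because per-frame steps are far below half the
    period).
    """
    outdir = Path(outdir)
    params = json.loads((outdir / "params.json").read_text())
    pore_topo, pore_frame = pdbio.read_structure(outdir / "pore.pdb")
    # rebuild ion topology from the params (the CSV stores only coordinates)
    ion_params = SynthIonParams(**params["ions"])
    n_per = ion_params.n_ions_per_species
    species = list(ion_params.drift_per_frame.keys())
    next_id = (max(a.atom_id for a in pore_topo.atoms) + 1) if pore_topo.n_atoms else 1
    ion_records = []
    for s_i, sp in enumerate(species):
        for k in range(n_per):
            ion_records.append(
                AtomRecord(next_id, sp, sp, sp, s_i * n_per + k + 1, "I",
                           {"NA": 2.27, "CL": 1.75}.get(sp, 2.0), False, False,
                           {"NA": +1, "CL": -1}.get(sp, 0))
            )
            next_id += 1
    ion_topo = Topology(ion_records)
    ion_traj = pdbio.read_frame_table(outdir / "ions.csv", ion_topo)

    period = float(params["x_period"])
    topo = Topology(pore_topo.atoms + ion_records)
    box = np.array([period, 0.0, 0.0])
    frames = [
        Frame(f.time, np.vstack([pore_frame.coords, f.coords]), box=box)
        for f in ion_traj.frames
    ]
    # reconstruct unwrap offsets via minimum-image continuity
    n_ions = ion_topo.n_atoms
    x = np.stack([f.coords[:, 0] for f in ion_traj.frames])
    dx = np.diff(x, axis=0)
    wraps = -np.round(dx / period)
    off = np.concatenate([np.zeros((1, n_ions)), np.cumsum(wraps * period, axis=0)])
    offsets = np.zeros((len(frames), topo.n_atoms))
    offsets[:, pore_topo.n_atoms:] = off
    return Trajectory(topo, frames, x_unwrap_offset=offsets), params
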