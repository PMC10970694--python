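"""Structure and trajectory I/O.

Two on-disk formats are supported natively:

* **PDB** (wwPDB v3.3 columns), single- and multi-MODEL, read and written
  through biotite.  altLoc entries other than ''/'A' are dropped.
* the **internal frame table**: plain-text CSV with header
  ``frame,time_ns,atom_id,x,y,z``, one row per atom per frame, coordinates
  printed at 6 decimals (bit-exact round trip at that precision).

vdW radii and formal charges are (re)assigned from the internal tables on
read; they are chemistry metadata, not file content.
"""
from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chemdata import formal_charge_for_atom, infer_element, vdw_radius
from .errors import FormatError, ShapeError
from .model import AtomRecord, Frame, Topology, Trajectory, classify_atom

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_frame_table",
    "write_frame_table",
]


def _prescan_pdb(text: str) -> int:
    """Validate coordinate records line by line; return the number of MODELs.

    Raises FormatError naming the first unparsable line.
    """
    n_models = 0
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            n_models += 1
        elif rec in ("ATOM  ", "HETATM"):
            n_atoms += 1
            try:
                int(line[22:26])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError):
                raise FormatError(
                    f"unparsable {rec.strip()} record at line {lineno}: {line!r}"
                ) from None
    if n_atoms == 0:
        raise FormatError("no ATOM/HETATM records found (empty input)")
    return n_models


def _atoms_per_model(text: str) -> list[int]:
    counts: list[int] = []
    cur = 0
    in_model = False
    for line in text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            in_model = True
            cur = 0
        elif rec == "ENDMDL":
            counts.append(cur)
            in_model = False
        elif rec in ("ATOM  ", "HETATM") and in_model:
            cur += 1
    return counts


def _topology_from_atom_array(arr: struc.AtomArray) -> Topology:
    records = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        resname = str(arr.res_name[i])
        element = str(arr.element[i]).strip() or infer_element(name, resname)
        bb, sc = classify_atom(name, resname)
        records.append(
            AtomRecord(
                atom_id=i + 1,
                atom_name=name,
                element=element,
                residue_name=resname,
                residue_number=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                vdw_radius=vdw_radius(element),
                is_backbone=bb,
                is_sidechain=sc,
                formal_charge=formal_charge_for_atom(resname, name),
            )
        )
    return Topology(records)


def _box_from_array(arr) -> np.ndarray | None:
    box = getattr(arr, "box", None)
    if box is None:
        return None
    box = np.asarray(box)
    if box.ndim == 3:
        box = box[0]
    lengths = np.linalg.norm(box, axis=-1)
    if np.all(lengths <= 0):
        return None
    return lengths


def read_structure(path: str | Path) -> tuple[Topology, Frame]:
    """Read a (single-model) PDB file into (Topology, Frame)."""
    text = Path(path).read_text()
    _prescan_pdb(text)
    pdb = PDBFile.read(io.StringIO(text))
    arr = pdb.get_structure(model=1, altloc="first")
    topo = _topology_from_atom_array(arr)
    frame = Frame(time=0.0, coords=np.asarray(arr.coord, dtype=np.float64),
                  box=_box_from_array(arr))
    return topo, frame


def _atom_array_from(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in topology.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in topology.atoms], dtype="U6")
    arr.element = np.array([a.element for a in topology.atoms], dtype="U2")
    arr.hetero = np.array(
        [not (a.is_backbone or a.is_sidechain) for a in topology.atoms]
    )
    return arr


def write_structure(path: str | Path, topology: Topology, frame: Frame) -> None:
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from(topology, frame.coords))
    pdb.write(str(path))


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory as a multi-MODEL PDB (one MODEL per frame)."""
    stack = struc.stack(
        [_atom_array_from(traj.topology, f.coords) for f in traj.frames]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory(
    path: str | Path,
    topology: Topology | None = None,
    stride_ns: float = 1.0,
) -> Trajectory:
    """Read a trajectory from a multi-MODEL PDB or an internal frame table.

    CSV frame tables require *topology*; PDB files derive it from the first
    model (or validate against a supplied one by atom count).  PDB models
    carry no time stamps, so frame times are ``i * stride_ns``.
    """
    path = Path(path)
    if path.suffix.lower() in {".csv", ".table", ".tsv"}:
        if topology is None:
            raise ShapeError("reading a frame table requires a topology")
        return read_frame_table(path, topology)
    text = path.read_text()
    n_models = _prescan_pdb(text)
    if n_models > 1:
        counts = _atoms_per_model(text)
        if len(set(counts)) > 1:
            ref = counts[0]
            bad = next(i for i, c in enumerate(counts) if c != ref)
            raise ShapeError(
                f"frame {bad} has {counts[bad]} atoms, expected {ref}"
            )
    pdb = PDBFile.read(io.StringIO(text))
    arr = pdb.get_structure(altloc="first")
    if isinstance(arr, struc.AtomArray):
        arr = struc.stack([arr])
    topo = topology or _topology_from_atom_array(arr[0])
    if arr.array_length() != topo.n_atoms:
        raise ShapeError(
            f"trajectory has {arr.array_length()} atoms per frame, "
            f"topology has {topo.n_atoms}"
        )
    box = _box_from_array(arr)
    frames = [
        Frame(time=i * stride_ns, coords=np.asarray(arr.coord[i], dtype=np.float64),
              box=box)
        for i in range(arr.stack_depth())
    ]
    return Trajectory(topo, frames)


def write_frame_table(path: str | Path, traj: Trajectory) -> None:
    """Write the internal frame-table CSV (header
    ``frame,time_ns,atom_id,x,y,z``, 6-decimal coordinates)."""
    atom_ids = np.array([a.atom_id for a in traj.topology.atoms])
    rows = []
    for i, f in enumerate(traj.frames):
        df = pd.DataFrame(
            {
                "frame": i,
                "time_ns": f.time,
                "atom_id": atom_ids,
                "x": f.coords[:, 0],
                "y": f.coords[:, 1],
                "z": f.coords[:, 2],
            }
        )
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_frame_table(path: str | Path, topology: Topology) -> Trajectory:
    """Read the internal frame-table CSV against a known topology."""
    df = pd.read_csv(path)
    expected = {"frame", "time_ns", "atom_id", "x", "y", "z"}
    if not expected.issubset(df.columns):
        raise FormatError(
            f"frame table must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    atom_ids = [a.atom_id for a in topology.atoms]
    order = {aid: i for i, aid in enumerate(atom_ids)}
    frames: list[Frame] = []
    for fi, sub in df.groupby("frame", sort=True):
        if len(sub) != topology.n_atoms or set(sub["atom_id"]) != set(atom_ids):
            raise ShapeError(
                f"frame {fi} has {len(sub)} atoms, topology has {topology.n_atoms}"
            )
        coords = np.empty((topology.n_atoms, 3))
        idx = sub["atom_id"].map(order).to_numpy()
        coords[idx] = sub[["x", "y", "z"]].to_numpy()
        frames.append(Frame(time=float(sub["time_ns"].iloc[0]), coords=coords))
    return Trajectory(topology, frames)
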