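"""Interface metrics: H-bonds, pair distances, persistence, SASA, RMSD."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from parapore.errors import ConfigError, ParameterError, SelectionError
from parapore.metrics import (
    HBondCriterion,
    atom_pair_distance_series,
    backbone_rmsd,
    count_backbone_hbonds,
    fibonacci_sphere,
    persistent_pair_count,
    sasa,
)
from parapore.model import Frame, Selection, Topology, Trajectory

from conftest import make_atom


# --------------------------------------------------------------------------
# hydrogen bonds

def strand_pair_topology(n_res=2, chain_a="A", chain_b="B"):
    """Two short backbone strands (N, CA, C, O per residue)."""
    records, aid = [], 1
    for chain in (chain_a, chain_b):
        for r in range(1, n_res + 1):
            for name in ("N", "CA", "C", "O"):
                records.append(make_atom(aid, name, "GLY", r, chain))
                aid += 1
    return Topology(records)


def place_strands(topo, coords_a, coords_b):
    coords = np.vstack([coords_a, coords_b])
    return Frame(0.0, coords)


def ideal_strand(origin, direction=(1.0, 0, 0)):
    """Backbone coordinates N, CA, C, O per residue along a line."""
    origin = np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    out = []
    for r in range(2):
        base = origin + 7.0 * r * d
        out += [base, base + 1.2 * d, base + 2.4 * d, base + 3.0 * d]
    return np.array(out)


def test_ideal_antiparallel_hbond_counted():
    topo = strand_pair_topology()
    a = ideal_strand([0, 0, 0])
    b = a.copy()
    b[:, 1] = 10.0
    # put B residue 1's O collinear behind A residue 1's N: N…O = 2.9 Å
    b[3] = [0.0, 2.9, 0.0]   # O of B res 1
    b[2] = [0.0, 4.1, 0.0]   # its carbonyl C, angle C-O…N = 180°
    frame = place_strands(topo, a, b)
    n = count_backbone_hbonds(frame, topo,
                              Selection(chains=frozenset("A")),
                              Selection(chains=frozenset("B")))
    assert n == 1


def test_distant_segments_no_hbonds():
    topo = strand_pair_topology()
    frame = place_strands(topo, ideal_strand([0, 0, 0]), ideal_strand([0, 20, 0]))
    assert count_backbone_hbonds(frame, topo,
                                 Selection(chains=frozenset("A")),
                                 Selection(chains=frozenset("B"))) == 0


def test_hbond_counts_match_enumeration_oracle(rng):
    """Random two-strand geometries vs an exhaustive N/O pair enumeration."""
    topo = strand_pair_topology(n_res=3)
    crit = HBondCriterion(donor_acceptor_max=3.5, angle_min=100.0)
    selA, selB = Selection(chains=frozenset("A")), Selection(chains=frozenset("B"))
    for _ in range(50):
        coords = rng.uniform(0, 8, size=(topo.n_atoms, 3))
        frame = Frame(0.0, coords)
        got = count_backbone_hbonds(frame, topo, selA, selB, crit)

        def hb(n_i, o_i):
            if np.linalg.norm(coords[n_i] - coords[o_i]) > 3.5:
                return False
            o = topo.atoms[o_i]
            c_i = topo.index_of(o.chain_id, o.residue_number, "C")
            v1 = coords[c_i] - coords[o_i]
            v2 = coords[n_i] - coords[o_i]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            return np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 100.0

        idx = {("A", n): i for i, n in
               [(i, (topo.atoms[i].chain_id, topo.atoms[i].atom_name, topo.atoms[i].residue_number)) for i in range(topo.n_atoms)]}
        oracle = 0
        for i in range(topo.n_atoms):
            ai = topo.atoms[i]
            if ai.atom_name != "N":
                continue
            for j in range(topo.n_atoms):
                aj = topo.atoms[j]
                if aj.atom_name != "O" or aj.chain_id == ai.chain_id:
                    continue
                if hb(i, j):
                    oracle += 1
        assert got == oracle


def test_hbond_invariant_under_rigid_motion(rng):
    topo = strand_pair_topology(n_res=3)
    coords = rng.uniform(0, 8, size=(topo.n_atoms, 3))
    selA, selB = Selection(chains=frozenset("A")), Selection(chains=frozenset("B"))
    n0 = count_backbone_hbonds(Frame(0.0, coords), topo, selA, selB)
    R = Rotation.from_euler("zyx", [0.4, -1.1, 2.2]).as_matrix()
    n1 = count_backbone_hbonds(Frame(0.0, coords @ R.T + [5, -3, 8]), topo, selA, selB)
    assert n0 == n1


def test_hbond_requires_backbone_polar_atoms():
    topo = Topology([make_atom(1, "CB", "ALA", 1, "A"), make_atom(2, "CB", "ALA", 1, "B")])
    with pytest.raises(SelectionError):
        count_backbone_hbonds(Frame(0.0, np.zeros((2, 3))), topo,
                              Selection(chains=frozenset("A")),
                              Selection(chains=frozenset("B")))


# --------------------------------------------------------------------------
# atom-pair distance series

def pair_system():
    records = [
        make_atom(1, "CG", "PHE", 68, "A"), make_atom(2, "CG", "LEU", 156, "B"),
        make_atom(3, "CG", "PHE", 68, "C"), make_atom(4, "CG", "LEU", 156, "D"),
    ]
    return Topology(records)


def test_constant_pair_distance_series():
    topo = pair_system()
    coords = np.array([[0, 0, 0], [7.7, 0, 0], [0, 30, 0], [7.7, 30, 0]])
    traj = Trajectory(topo, [Frame(float(t), coords) for t in range(10)])
    s = atom_pair_distance_series(
        traj, [(("A", 68, "CG"), ("B", 156, "CG")), (("C", 68, "CG"), ("D", 156, "CG"))]
    )
    assert np.allclose(s.per_frame_mean, 7.7)
    assert np.allclose(s.pair_sds, 0.0)


def test_two_pairs_average():
    topo = pair_system()
    coords = np.array([[0, 0, 0], [6.0, 0, 0], [0, 30, 0], [8.0, 30, 0]])
    traj = Trajectory(topo, [Frame(0.0, coords)])
    s = atom_pair_distance_series(
        traj, [(("A", 68, "CG"), ("B", 156, "CG")), (("C", 68, "CG"), ("D", 156, "CG"))]
    )
    assert s.per_frame_mean[0] == pytest.approx(7.0)


def test_series_matches_direct_recomputation(rng):
    topo = pair_system()
    frames = [Frame(float(t), rng.normal(size=(4, 3)) * 5) for t in range(6)]
    traj = Trajectory(topo, frames)
    pairs = [(("A", 68, "CG"), ("D", 156, "CG")), (("C", 68, "CG"), ("B", 156, "CG"))]
    s = atom_pair_distance_series(traj, pairs)
    for t, f in enumerate(frames):
        d1 = np.linalg.norm(f.coords[0] - f.coords[3])
        d2 = np.linalg.norm(f.coords[2] - f.coords[1])
        assert s.per_frame_mean[t] == pytest.approx((d1 + d2) / 2, abs=1e-9)


def test_missing_atom_names_residue():
    topo = pair_system()
    traj = Trajectory(topo, [Frame(0.0, np.zeros((4, 3)))])
    with pytest.raises(SelectionError, match="CD1"):
        atom_pair_distance_series(traj, [(("A", 68, "CD1"), ("B", 156, "CG"))])


# --------------------------------------------------------------------------
# persistence

def contact_pattern_trajectory(pattern, near=3.0, far=8.0):
    """Two single-atom residues whose distance follows a binary pattern."""
    topo = Topology([make_atom(1, "NZ", "LYS", 1, "A"),
                     make_atom(2, "OE1", "GLU", 2, "B")])
    frames = [
        Frame(float(t), np.array([[0.0, 0, 0], [near if c else far, 0, 0]]))
        for t, c in enumerate(pattern)
    ]
    return Trajectory(topo, frames)


def sel_pair():
    return (Selection(chains=frozenset("A")), Selection(chains=frozenset("B")))


def test_persistence_fraction_and_count():
    traj = contact_pattern_trajectory([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    res = persistent_pair_count(traj, [sel_pair()])
    assert res.fraction_of_frames[0] == pytest.approx(0.4)
    assert res.count_above_threshold == 1


def test_persistence_boundary_is_strict():
    traj = contact_pattern_trajectory([1] * 7 + [0] * 13)  # exactly 35%
    res = persistent_pair_count(traj, [sel_pair()])
    assert res.fraction_of_frames[0] == pytest.approx(0.35)
    assert res.count_above_threshold == 0


def test_persistence_matches_counting_oracle(rng):
    pattern = rng.integers(0, 2, size=17)
    traj = contact_pattern_trajectory(pattern)
    res = persistent_pair_count(traj, [sel_pair()], contact_max=4.0)
    assert res.fraction_of_frames[0] == pytest.approx(pattern.mean())


def test_persistence_invariant_under_frame_reordering(rng):
    pattern = rng.integers(0, 2, size=12)
    a = persistent_pair_count(contact_pattern_trajectory(pattern), [sel_pair()])
    b = persistent_pair_count(contact_pattern_trajectory(pattern[::-1]), [sel_pair()])
    assert a.fraction_of_frames[0] == pytest.approx(b.fraction_of_frames[0])


# --------------------------------------------------------------------------
# SASA

def test_isolated_atom_analytic_sphere():
    topo = Topology([make_atom(1, vdw=1.9)])
    res = sasa(Frame(0.0, np.zeros((1, 3))), topo)
    assert res.total == pytest.approx(4 * np.pi * 3.3**2, rel=0.01)


def test_enclosed_atom_is_buried():
    # central atom surrounded by a dense shell of overlapping atoms
    shell = fibonacci_sphere(80) * 2.0
    records = [make_atom(1, "C1", "UNK", 1, "A", vdw=1.7)]
    records += [make_atom(i + 2, f"S{i:02d}", "SHL", 2, "A", vdw=1.7)
                for i in range(80)]
    topo = Topology(records)
    coords = np.vstack([[0.0, 0, 0], shell])
    res = sasa(Frame(0.0, coords), topo,
               Selection(resnames=frozenset(["UNK"])))
    assert res.per_atom_area[0] < 1.0


@pytest.mark.parametrize("separation", [1.0, 2.5, 4.0, 6.0])
def test_two_sphere_overlap_vs_monte_carlo_oracle(separation, rng):
    """Fibonacci quadrature within 2% of a seeded 1e5-point MC integrator."""
    r1, r2, probe = 1.7, 1.52, 1.4
    topo = Topology([make_atom(1, "C1", "UNK", 1, "A", vdw=r1),
                     make_atom(2, "O1", "UNK", 2, "A", element="O", vdw=r2)])
    centers = np.array([[0.0, 0, 0], [separation, 0, 0]])
    res = sasa(Frame(0.0, centers), topo, n_points=960)

    def mc_area(center, radius, other_center, other_radius, n=100_000):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = center + radius * v
        exposed = np.linalg.norm(pts - other_center, axis=1) >= other_radius
        return exposed.mean() * 4 * np.pi * radius**2

    o1 = mc_area(centers[0], r1 + probe, centers[1], r2 + probe)
    o2 = mc_area(centers[1], r2 + probe, centers[0], r1 + probe)
    for got, want in ((res.per_atom_area[0], o1), (res.per_atom_area[1], o2)):
        if want > 1.0:
            assert got == pytest.approx(want, rel=0.02)
        else:
            assert got < 2.0


def test_sasa_additivity_bound(rng):
    coords = rng.uniform(0, 6, size=(5, 3))
    topo = Topology([make_atom(i + 1, f"C{i}", "UNK", i + 1, "A", vdw=1.7)
                     for i in range(5)])
    joint = sasa(Frame(0.0, coords), topo).total
    isolated = sum(
        sasa(Frame(0.0, coords[[i]]), Topology([make_atom(1, "C0", "UNK", 1, "A", vdw=1.7)])).total
        for i in range(5)
    )
    assert joint <= isolated + 1e-6


def test_sasa_parameter_validation():
    topo = Topology([make_atom(1)])
    with pytest.raises(ParameterError):
        sasa(Frame(0.0, np.zeros((1, 3))), topo, n_points=8)


def test_sasa_normalization_uses_sidechain_heavy_atoms():
    # LYS with CB+NZ side chain: normalized = area / 2
    records = [make_atom(1, "CA", "LYS", 1, "A"),
               make_atom(2, "CB", "LYS", 1, "A"),
               make_atom(3, "NZ", "LYS", 1, "A", element="N")]
    topo = Topology(records)
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
    res = sasa(Frame(0.0, coords), topo)
    assert res.normalized_area[0] == pytest.approx(res.area[0] / 2)


# --------------------------------------------------------------------------
# RMSD

def ca_trajectory(frames_coords):
    n = frames_coords[0].shape[0]
    topo = Topology([make_atom(i + 1, "CA", "ALA", i + 1, "A") for i in range(n)])
    frames = [Frame(float(t), c) for t, c in enumerate(frames_coords)]
    return topo, Trajectory(topo, frames)


def test_rmsd_zero_for_identical_frame(rng):
    coords = rng.normal(size=(10, 3)) * 4
    _, traj = ca_trajectory([coords])
    assert backbone_rmsd(traj, Selection(), traj.frames[0])[0] == pytest.approx(0.0, abs=1e-6)


def test_rmsd_zero_after_superposition_of_rigid_copy(rng):
    coords = rng.normal(size=(10, 3)) * 4
    R = Rotation.from_euler("xyz", [0.7, -0.2, 1.9]).as_matrix()
    moved = coords @ R.T + [10, -5, 3]
    _, traj = ca_trajectory([moved])
    out = backbone_rmsd(traj, Selection(), Frame(0.0, coords))
    assert out[0] < 1e-6


def test_rmsd_single_displacement_closed_form(rng):
    coords = rng.normal(size=(16, 3)) * 6
    moved = coords.copy()
    moved[3, 1] += 2.4
    _, traj = ca_trajectory([moved])
    out = backbone_rmsd(traj, Selection(), Frame(0.0, coords), superpose=False)
    assert out[0] == pytest.approx(2.4 / np.sqrt(16), abs=1e-12)


def test_rmsd_superposed_never_exceeds_raw(rng):
    coords = rng.normal(size=(12, 3)) * 5
    frames = [coords + rng.normal(size=(12, 3)) for _ in range(4)]
    _, traj = ca_trajectory(frames)
    sup = backbone_rmsd(traj, Selection(), Frame(0.0, coords), superpose=True)
    raw = backbone_rmsd(traj, Selection(), Frame(0.0, coords), superpose=False)
    assert np.all(sup <= raw + 1e-9)


def test_rmsd_agrees_with_mdanalysis_oracle(rng):
    mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
    coords = rng.normal(size=(15, 3)) * 5
    mobile = coords + rng.normal(size=(15, 3)) * 2
    _, traj = ca_trajectory([mobile])
    got = backbone_rmsd(traj, Selection(), Frame(0.0, coords), superpose=True)[0]
    want = mda_rms.rmsd(mobile, coords, superposition=True, center=True)
    assert got == pytest.approx(want, abs=1e-6)


def test_rmsd_needs_three_atoms_for_superposition():
    _, traj = ca_trajectory([np.zeros((2, 3))])
    with pytest.raises(ConfigError):
        backbone_rmsd(traj, Selection(), traj.frames[0], superpose=True)
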