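"""PDB I/O, superposition and descriptor tests.

Oracles: an independent quaternion (Horn) superposition, direct-summation
formulas for Rg/RMSF, and closed-form sphere/two-sphere areas for SASA.
"""

import math

import numpy as np
import pytest
import biotite.structure as struc
from hypothesis import given, settings, strategies as st

from agekit.structures import (
    DegenerateGeometryError,
    PdbParseError,
    Structure,
    Trajectory,
    atom_distance,
    infer_element,
    kabsch_superpose,
    radius_of_gyration,
    read_pdb,
    rmsf,
    sasa,
    write_pdb,
)
from agekit.synthetic import make_planted_complex, PlantedComplexSpec

from conftest import random_rigid_transform


def _atom(coord, name="CB", element="C", res_id=1, chain="A", res_name="ALA"):
    return struc.Atom(
        coord, chain_id=chain, res_id=res_id, res_name=res_name,
        atom_name=name, element=element, hetero=False,
    )


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------


def test_single_atom_file(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(
        "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00"
        "           C  \n"
    )
    st_ = read_pdb(path)
    assert st_.n_models == 1 and st_.n_atoms == 1
    assert np.allclose(st_.model(0).coord[0], [1, 2, 3])


def test_multi_model_file(tmp_path):
    spec = PlantedComplexSpec(n_salt_bridges=2, seed=1)
    base, _ = make_planted_complex(spec)
    frames = [base.model(0).copy() for _ in range(3)]
    for i, f in enumerate(frames):
        f.coord += i
    multi = Structure(struc.stack(frames))
    path = tmp_path / "multi.pdb"
    write_pdb(multi, path)
    back = read_pdb(path)
    assert back.n_models == 3
    assert back.n_atoms == base.n_atoms
    # identical topology across models is guaranteed by the container
    assert np.array_equal(back.model(0).atom_name, back.model(2).atom_name)


def test_roundtrip_idempotent(tmp_path, planted):
    """write -> read -> write reproduces records byte-for-byte."""
    st_, _ = planted
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_pdb(st_, p1)
    once = read_pdb(p1)
    write_pdb(once, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert np.allclose(once.model(0).coord, st_.model(0).coord, atol=1.5e-3)


def test_malformed_record_reports_line(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text(
        "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00\n"
        "ATOM      2  CB  GLY A   1       1.000   x.000   3.000  1.00  0.00\n"
    )
    with pytest.raises(PdbParseError, match=":2:"):
        read_pdb(path)


def test_element_inference():
    assert infer_element(" CA ") == "C"
    assert infer_element("NZ") == "N"
    assert infer_element("1HB2") == "H"
    assert infer_element("OXT") == "O"


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------


def _quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion method."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    m = mob.T @ ref
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (mob**2).sum() + (ref**2).sum()
    rmsd_sq = max((e0 - 2.0 * lam), 0.0) / len(mobile)
    return math.sqrt(rmsd_sq)


def test_identical_sets_give_identity():
    pts = np.random.default_rng(0).normal(size=(8, 3))
    res = kabsch_superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-7)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-8)


def test_known_transform_recovered():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12, 3))
    theta = np.deg2rad(30)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    trans = np.array([3.0, -2.0, 7.0])
    mobile = (pts - trans) @ rot  # so that rot @ mobile + trans = pts
    res = kabsch_superpose(mobile, pts)
    assert np.allclose(res.rotation, rot, atol=1e-9)
    assert np.allclose(res.translation, trans, atol=1e-9)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_rmsd_matches_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    mobile = rng.normal(size=(10, 3))
    reference = rng.normal(size=(10, 3))
    res = kabsch_superpose(mobile, reference)
    assert res.rmsd == pytest.approx(
        _quaternion_superpose_rmsd(mobile, reference), abs=1e-9
    )


def test_superposition_beats_random_transforms():
    """Monte-Carlo optimality: no random rigid transform does better."""
    rng = np.random.default_rng(3)
    mobile = rng.normal(size=(7, 3))
    reference = rng.normal(size=(7, 3))
    best = kabsch_superpose(mobile, reference).rmsd
    for _ in range(1000):
        rot, trans = random_rigid_transform(rng)
        moved = mobile @ rot.T + trans
        rmsd = np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1)))
        assert best <= rmsd + 1e-9


def test_degenerate_and_mismatched_inputs():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(line, line)
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


# --------------------------------------------------------------------------
# radius of gyration
# --------------------------------------------------------------------------


def test_rg_single_atom_is_zero():
    arr = struc.array([_atom([1, 2, 3])])
    assert radius_of_gyration(arr) == pytest.approx(0.0, abs=1e-12)


def test_rg_two_equal_masses_two_angstrom():
    arr = struc.array([_atom([0, 0, 0]), _atom([2, 0, 0])])
    assert radius_of_gyration(arr) == pytest.approx(1.0, abs=1e-9)


def test_rg_matches_direct_formula():
    """Oracle: Rg^2 = <m r^2> - |<m r>|^2 (different algebraic route)."""
    rng = np.random.default_rng(5)
    elements = rng.choice(["C", "N", "O", "S"], size=50)
    atoms = [
        _atom(rng.normal(scale=8, size=3), element=e, name=e + "X")
        for e in elements
    ]
    arr = struc.array(atoms)
    import biotite.structure.info as info

    masses = np.array([info.mass(str(e)) for e in arr.element])
    coords = arr.coord.astype(float)
    mean_r2 = np.average((coords**2).sum(axis=1), weights=masses)
    com = np.average(coords, axis=0, weights=masses)
    oracle = math.sqrt(mean_r2 - (com**2).sum())
    assert radius_of_gyration(arr) == pytest.approx(oracle, abs=1e-9)


def test_rg_empty_selection_errors():
    arr = struc.array([_atom([0, 0, 0])])
    with pytest.raises(ValueError):
        radius_of_gyration(arr, mask=np.zeros(1, dtype=bool))


# --------------------------------------------------------------------------
# RMSF
# --------------------------------------------------------------------------


def _static_cloud(n=6, seed=0):
    rng = np.random.default_rng(seed)
    return [
        _atom(rng.normal(scale=5, size=3), res_id=i + 1) for i in range(n)
    ]


def test_rmsf_static_trajectory_is_zero():
    arr = struc.array(_static_cloud())
    traj = Trajectory(
        Structure(struc.stack([arr, arr, arr])), frame_times=[0, 1, 2]
    )
    assert np.allclose(rmsf(traj).values, 0.0, atol=1e-6)


def test_rmsf_alternating_atom_closed_form():
    """One atom alternating +/-d along x about a fixed mean has RMSF d when
    the fit is anchored on the static atoms."""
    d = 0.75
    static = _static_cloud(8)
    frames = []
    for sign in (1, -1, 1, -1):
        atoms = [
            _atom(a.coord.copy(), res_id=i + 1) for i, a in enumerate(static)
        ]
        atoms.append(_atom([sign * d, 0.0, 0.0], res_id=99))
        frames.append(struc.array(atoms))
    stack = struc.stack(frames)
    traj = Trajectory(Structure(stack), frame_times=np.arange(4.0))
    fit_mask = stack.res_id[:] != 99
    series = rmsf(traj, fit_mask=fit_mask)
    assert series.values[-1] == pytest.approx(d, abs=1e-6)
    assert np.allclose(series.values[:-1], 0.0, atol=1e-6)


def test_rmsf_matches_std_oracle():
    """Brute-force oracle: per-atom std of coordinates after identical fit."""
    rng = np.random.default_rng(11)
    base = struc.array(_static_cloud(10, seed=2))
    frames = []
    for _ in range(12):
        f = base.copy()
        f.coord = f.coord + rng.normal(scale=0.1, size=f.coord.shape).astype(
            np.float32
        )
        frames.append(f)
    stack = struc.stack(frames)
    traj = Trajectory(Structure(stack), frame_times=np.arange(12.0))
    series = rmsf(traj)
    fitted, _ = struc.superimpose(stack[0], stack)
    mean = fitted.coord.mean(axis=0)
    oracle = np.sqrt(((fitted.coord - mean) ** 2).sum(axis=-1).mean(axis=0))
    assert np.allclose(series.values, oracle, atol=1e-6)


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------


def test_sasa_isolated_atom_sphere_area():
    arr = struc.array([_atom([0, 0, 0], element="C")])
    expected = 4 * math.pi * (1.7 + 1.4) ** 2
    assert sasa(arr)[0] == pytest.approx(expected, rel=0.01)


def test_sasa_two_overlapping_spheres_analytic():
    """Closed form for two equal intersecting spheres: total exposed area
    4*pi*R^2 + 2*pi*R*d."""
    d = 2.0
    arr = struc.array([_atom([0, 0, 0]), _atom([d, 0, 0])])
    r = 1.7 + 1.4
    expected = 4 * math.pi * r**2 + 2 * math.pi * r * d
    assert sasa(arr).sum() == pytest.approx(expected, rel=0.01)


def test_sasa_quadrature_convergence(planted):
    st_, _ = planted
    frame = st_.model(0)
    total_1x = sasa(frame, n_points=960).sum()
    total_2x = sasa(frame, n_points=1920).sum()
    assert abs(total_2x - total_1x) / total_1x < 0.005


def test_sasa_unknown_element_errors():
    arr = struc.array([_atom([0, 0, 0], element="XX")])
    with pytest.raises(KeyError):
        sasa(arr)


# --------------------------------------------------------------------------
# distances and rigid-motion invariance
# --------------------------------------------------------------------------


def test_atom_distance_basics():
    assert atom_distance([1, 1, 1], [1, 1, 1]) == 0.0
    assert atom_distance([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        atom_distance([np.nan, 0, 0], [0, 0, 0])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rigid_motion_invariance(seed):
    """Rg and pairwise distance are invariant under rigid motion (<=1e-6
    relative)."""
    rng = np.random.default_rng(seed)
    arr = struc.array(
        [_atom(rng.normal(scale=6, size=3), res_id=i + 1) for i in range(12)]
    )
    rot, trans = random_rigid_transform(rng)
    moved = arr.copy()
    moved.coord = (arr.coord.astype(float) @ rot.T + trans).astype(np.float32)
    rg_a, rg_b = radius_of_gyration(arr), radius_of_gyration(moved)
    assert abs(rg_a - rg_b) / rg_a < 1e-5  # float32 storage limits precision
    d_a = atom_distance(arr.coord[0], arr.coord[5])
    d_b = atom_distance(moved.coord[0], moved.coord[5])
    assert abs(d_a - d_b) / d_a < 1e-5


def test_rigid_motion_invariance_float64_exact():
    """At float64 the invariance holds to 1e-6 absolute."""
    rng = np.random.default_rng(42)
    pts = rng.normal(scale=6, size=(30, 3))
    rot, trans = random_rigid_transform(rng)
    moved = pts @ rot.T + trans
    d0 = np.linalg.norm(pts[3] - pts[17])
    d1 = np.linalg.norm(moved[3] - moved[17])
    assert abs(d0 - d1) < 1e-6
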