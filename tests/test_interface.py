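"""Contact census, specific-contact classification, persistence and the
printed-table ingestion path."""

from collections import Counter

import numpy as np
import pytest
import biotite.structure as struc
from hypothesis import given, settings, strategies as st

from agekit.config import Thresholds
from agekit.interface import (
    INTERACTION_SURFACES,
    classify_pair,
    contact_census,
    cml_engagement,
    is_membership,
    load_published_interface_table,
    parse_contact_table,
    persistence,
    specific_contacts,
)
from agekit.structures import RAGE_DOMAINS, Structure, Trajectory
from agekit.synthetic import (
    PersistenceSchedule,
    PlantedComplexSpec,
    make_planted_complex,
    make_trajectory,
)


def _cloud(rng, n_a=30, n_b=30, scale=8.0):
    """Random two-group atom cloud for census oracle comparisons."""
    atoms = []
    for i in range(n_a):
        atoms.append(
            struc.Atom(
                rng.normal(scale=scale, size=3), chain_id="A", res_id=i + 1,
                res_name="ALA", atom_name="CB", element="C", hetero=False,
            )
        )
    for i in range(n_b):
        atoms.append(
            struc.Atom(
                rng.normal(scale=scale, size=3) + np.array([4.0, 0, 0]),
                chain_id="B", res_id=i + 1,
                res_name="ALA", atom_name="CB", element="C", hetero=False,
            )
        )
    arr = struc.array(atoms)
    return arr, arr.chain_id == "A", arr.chain_id == "B"


def _brute_force_pairs(frame, mask_a, mask_b, cutoff):
    ia, ib = np.flatnonzero(mask_a), np.flatnonzero(mask_b)
    out = set()
    for i in ia:
        for j in ib:
            if np.linalg.norm(frame.coord[i] - frame.coord[j]) <= cutoff:
                out.add((int(i), int(j)))
    return out


# --------------------------------------------------------------------------
# census
# --------------------------------------------------------------------------


def test_far_atoms_no_records():
    atoms = [
        struc.Atom([0, 0, 0], chain_id="A", res_id=1, res_name="ALA",
                   atom_name="CB", element="C", hetero=False),
        struc.Atom([5, 0, 0], chain_id="B", res_id=1, res_name="ALA",
                   atom_name="CB", element="C", hetero=False),
    ]
    arr = struc.array(atoms)
    res = contact_census(arr, arr.chain_id == "A", arr.chain_id == "B", cutoff=3.5)
    assert res.records == [] and res.n_atoms_a == 0 and res.n_atoms_b == 0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_census_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    arr, ma, mb = _cloud(rng)
    res = contact_census(arr, ma, mb, cutoff=3.5)
    got = {(r.atom_a, r.atom_b) for r in res.records}
    assert got == _brute_force_pairs(arr, ma, mb, 3.5)


def test_census_planted_pairs_recovered():
    spec = PlantedComplexSpec(n_steric=12, seed=4)
    st_, truth = make_planted_complex(spec)
    frame = st_.model(0)
    res = contact_census(frame, st_.mask(chain="A"), st_.mask(chain="B"))
    assert res.residue_pairs() == {
        (("A", t.res_a), ("B", t.res_b)) for t in truth
    }


def test_census_symmetry_and_monotonicity(planted):
    st_, _ = planted
    frame = st_.model(0)
    ma, mb = st_.mask(chain="A"), st_.mask(chain="B")
    fwd = contact_census(frame, ma, mb)
    rev = contact_census(frame, mb, ma)
    assert fwd.n_atoms_a == rev.n_atoms_b and fwd.n_atoms_b == rev.n_atoms_a
    assert {(r.atom_a, r.atom_b) for r in fwd.records} == {
        (r.atom_b, r.atom_a) for r in rev.records
    }
    counts = [
        len(contact_census(frame, ma, mb, cutoff=c).records)
        for c in (2.5, 3.0, 3.5, 4.5, 6.0)
    ]
    assert counts == sorted(counts)


def test_census_rejects_bad_selections(planted):
    st_, _ = planted
    frame = st_.model(0)
    ma = st_.mask(chain="A")
    with pytest.raises(ValueError, match="overlap"):
        contact_census(frame, ma, ma)
    with pytest.raises(ValueError, match="non-empty"):
        contact_census(frame, ma, np.zeros_like(ma))


def test_census_rigid_motion_invariant(planted):
    from conftest import random_rigid_transform

    st_, _ = planted
    frame = st_.model(0)
    rng = np.random.default_rng(8)
    rot, trans = random_rigid_transform(rng)
    moved = frame.copy()
    moved.coord = (frame.coord.astype(float) @ rot.T + trans).astype(np.float32)
    a = contact_census(frame, st_.mask(chain="A"), st_.mask(chain="B"))
    b = contact_census(moved, st_.mask(chain="A"), st_.mask(chain="B"))
    assert {(r.atom_a, r.atom_b) for r in a.records} == {
        (r.atom_a, r.atom_b) for r in b.records
    }
    assert (a.n_atoms_a, a.n_atoms_b) == (b.n_atoms_a, b.n_atoms_b)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


def test_planted_kinds_recovered_exactly(planted):
    st_, truth = planted
    frame = st_.model(0)
    kinds = specific_contacts(frame, st_.mask(chain="A"), st_.mask(chain="B"))
    assert Counter(kinds.values()) == Counter(
        {k: c for k, c in Counter(t.kind for t in truth).items() if k != "steric"}
    )


def test_every_specific_contact_is_within_its_own_census(planted):
    st_, _ = planted
    frame = st_.model(0)
    ma, mb = st_.mask(chain="A"), st_.mask(chain="B")
    kinds = specific_contacts(frame, ma, mb)
    thr = Thresholds()
    reach = {"SB": thr.salt_bridge, "HB": thr.hbond, "PP": thr.pipi}
    for (ra, rb), kind in kinds.items():
        census = contact_census(frame, ma, mb, cutoff=reach[kind])
        assert (ra, rb) in census.residue_pairs()


def test_distant_charges_not_salt_bridge():
    spec = PlantedComplexSpec(n_salt_bridges=1, d_salt_bridge=3.2, seed=0)
    st_, truth = make_planted_complex(spec)
    frame = st_.model(0).copy()
    # move the anion 8 A away: charge pair no longer bridges
    m = (frame.chain_id == "B") & (frame.res_id == truth[0].res_b)
    frame.coord[m, 0] += 8.0
    assert classify_pair(frame, ("A", 1), ("B", 1)) == "steric"


def test_cml_carboxylate_forms_salt_bridge():
    """A carboxymethylated lysine's carboxylate against an arginine
    guanidinium at salt-bridge range classifies as SB."""
    from agekit.glycation import graft_cml
    from agekit.synthetic import make_extended_tripeptide, make_polypeptide

    tri = graft_cml(make_extended_tripeptide("K"), "A", 2)
    frame = tri.model(0)
    ox1 = frame.coord[frame.atom_name == "OX1"][0]
    arg = make_polypeptide("R", "B", (0.0, 0.0, 0.0))
    nh1 = arg.coord[arg.atom_name == "NH1"][0]
    arg = arg.copy()
    arg.coord = arg.coord + (ox1 - nh1) + np.array([3.2, 0, 0], dtype=np.float32)
    merged = frame + arg
    assert classify_pair(merged, ("A", 2), ("B", 1)) == "SB"


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "schedule,expected",
    [
        (np.ones(10, bool), 100.0),
        (np.zeros(10, bool), 0.0),
        (np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0], bool), 70.0),
    ],
)
def test_persistence_matches_schedule(planted, schedule, expected):
    st_, truth = planted
    sched = PersistenceSchedule(schedules={0: schedule}, seed=2)
    traj, _ = make_trajectory(st_, truth, sched)
    rec = persistence(
        traj, [(("A", truth[0].res_a), ("B", truth[0].res_b), truth[0].kind)]
    )[0]
    assert rec.lifetime == expected


def test_persistence_linear_in_on_fraction(planted):
    st_, truth = planted
    for k in range(0, 11, 2):
        on = np.array([1] * k + [0] * (10 - k), bool)
        traj, _ = make_trajectory(
            st_, truth, PersistenceSchedule(schedules={0: on}, seed=k)
        )
        rec = persistence(
            traj, [(("A", truth[0].res_a), ("B", truth[0].res_b), truth[0].kind)]
        )[0]
        assert rec.lifetime == pytest.approx(10.0 * k)


def test_persistence_missing_residue_errors(planted):
    st_, truth = planted
    sched = PersistenceSchedule(schedules={0: np.ones(3, bool)})
    traj, _ = make_trajectory(st_, truth, sched)
    with pytest.raises(KeyError):
        persistence(traj, [(("A", 999), ("B", 1), "SB")])


# --------------------------------------------------------------------------
# interaction surfaces
# --------------------------------------------------------------------------


def test_is_sets_disjoint_and_within_v_domain():
    seen = set()
    lo, hi = RAGE_DOMAINS["V"]
    for members in INTERACTION_SURFACES.values():
        nums = set(members)
        assert not (nums & seen)
        seen |= nums
        assert all(lo <= n <= hi for n in nums)


@pytest.mark.parametrize(
    "residue,expected",
    [(48, "IS2"), (81, "IS1"), (29, "IS3"), (200, None), (107, "IS2")],
)
def test_is_membership(residue, expected):
    assert is_membership([residue])[residue] == expected


# --------------------------------------------------------------------------
# printed-table ingestion
# --------------------------------------------------------------------------


def test_parse_contact_row_grammar():
    records = parse_contact_table(
        "Glu45-Arg48 (SB, 100%); Phe374-Phe85 (PP, 20%)"
    )
    assert [(r.res_a, r.res_b, r.kind, r.lifetime) for r in records] == [
        ("Glu45", "Arg48", "SB", 100.0),
        ("Phe374", "Phe85", "PP", 20.0),
    ]
    assert parse_contact_table("") == []
    with pytest.raises(ValueError, match="Glu45=Arg48"):
        parse_contact_table("Glu45=Arg48 (SB, 100%)")


def test_published_table_summaries():
    reports = {r.label: r for r in load_published_interface_table()}
    lys64 = Counter(p.kind for p in reports["Lys64"].persistence)
    assert lys64["SB"] == 7
    assert sum(
        p.kind == "SB" and p.lifetime >= 70 for p in reports["Lys64"].persistence
    ) == 5
    lys233 = Counter(p.kind for p in reports["Lys233"].persistence)
    assert (lys233["SB"], lys233["HB"]) == (10, 4)
    assert (reports["Lys233"].n_atoms_a, reports["Lys233"].n_atoms_b) == (104, 103)


def test_cml_engagement_from_published_reports():
    reports = load_published_interface_table()
    assert cml_engagement(reports) == 8
    by_label = {r.label: r for r in reports}
    assert not by_label["Lys317"].cml_engaged
    assert not by_label["Lys574"].cml_engaged
    assert by_label["Lys233"].cml_engaged


def test_engagement_requires_actual_contact(planted):
    """A complex whose modified lysine sits far from the partner is not
    engaged under the structural (census) definition."""
    from agekit.interface import cml_contacts

    st_, truth = planted
    frame = st_.model(0)
    # pretend residue A:1 is the glycation site but displace it 20 A away
    moved = frame.copy()
    m = (moved.chain_id == "A") & (moved.res_id == 1)
    moved.coord[m, 0] -= 20.0
    census = cml_contacts(moved, m, moved.chain_id == "B")
    assert census.records == []
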