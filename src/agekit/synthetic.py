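"""Deterministic synthetic fixtures: structures with planted interactions,
trajectories with known contact schedules, and alignments with known
per-column conservation classes.

Every generator is a pure function of its specification and seed, and each
planted feature is constructed so that the corresponding analysis module
recovers it exactly (closed-loop property).  Geometry is simplified on
purpose: residues carry only the atoms the classifiers inspect (carboxylate
oxygens, charged nitrogens, ring carbons, minimal backbones); no physical
realism beyond the geometric criteria under test is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .structures import Structure, Trajectory

# --------------------------------------------------------------------------
# internal-coordinate atom placement
# --------------------------------------------------------------------------


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Position of atom d given three predecessors and internal coordinates.

    ``bond`` = |cd| in Angstrom, ``angle`` = b-c-d in degrees, ``torsion`` =
    a-b-c-d in degrees (standard NeRF construction).
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# --------------------------------------------------------------------------
# residue construction tables
# --------------------------------------------------------------------------

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Simplified side-chain topologies: atom, (parent, grandparent, great-gp),
# bond, angle, torsion.  Only the atoms the analysis layers inspect.
_SIDE_CHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0)],
    "SER": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("OG", ("N", "CA", "CB"), 1.42, 110.5, 180.0),
    ],
    "CYS": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("SG", ("N", "CA", "CB"), 1.81, 112.0, 180.0),
    ],
    "ASP": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("CG", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, 180.0),
    ],
    "ASN": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("CG", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.0, 0.0),
        ("ND2", ("CA", "CB", "CG"), 1.33, 120.0, 180.0),
    ],
    "GLU": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("CG", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.0, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.0, 180.0),
    ],
    "GLN": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("CG", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.0, 0.0),
        ("NE2", ("CB", "CG", "CD"), 1.33, 120.0, 180.0),
    ],
    "LYS": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("CG", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.52, 112.0, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.47, 112.0, 180.0),
    ],
    "ARG": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("CG", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.0, 180.0),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "PHE": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, 123.0),
        ("CG", ("N", "CA", "CB"), 1.50, 114.0, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.0, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
}

_ELEMENT_OF = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _element(atom_name: str) -> str:
    return _ELEMENT_OF[atom_name[0]]


# --------------------------------------------------------------------------
# helix and tripeptide builders
# --------------------------------------------------------------------------

_BB_BOND_N = 1.329
_BB_BOND_CA = 1.458
_BB_BOND_C = 1.525
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_N_CA_C = 111.2


def _build_chain(
    sequence: str,
    chain_id: str,
    start: np.ndarray,
    phi: float,
    psi: float,
    first_res_id: int = 1,
) -> struc.AtomArray:
    """Polypeptide with ideal backbone dihedrals and simplified side chains."""
    atoms: list[struc.Atom] = []
    start = np.asarray(start, dtype=float)
    positions: dict[str, np.ndarray] = {}
    for i, letter in enumerate(sequence):
        try:
            res_name = _AA3[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter {letter!r}") from None
        if res_name not in _SIDE_CHAINS:
            raise ValueError(f"no simplified side chain for {res_name}")
        if i == 0:
            n = start
            ca = n + np.array([_BB_BOND_CA, 0.0, 0.0])
            ang = np.deg2rad(_ANG_N_CA_C)
            c = ca + _BB_BOND_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev_n, prev_ca, prev_c = positions["N"], positions["CA"], positions["C"]
            n = place_atom(prev_n, prev_ca, prev_c, _BB_BOND_N, _ANG_CA_C_N, psi)
            ca = place_atom(prev_ca, prev_c, n, _BB_BOND_CA, _ANG_C_N_CA, 180.0)
            c = place_atom(prev_c, n, ca, _BB_BOND_C, _ANG_N_CA_C, phi)
        res_id = first_res_id + i
        local = {"N": n, "CA": ca, "C": c}
        # carbonyl oxygen, anti to the next amide nitrogen
        local["O"] = place_atom(n, ca, c, 1.231, 120.5, psi + 180.0)
        for name, (p3, p2, p1), bond, angle, torsion in _SIDE_CHAINS[res_name]:
            local[name] = place_atom(
                local[p3], local[p2], local[p1], bond, angle, torsion
            )
        for name in ["N", "CA", "C", "O"] + [
            entry[0] for entry in _SIDE_CHAINS[res_name]
        ]:
            atoms.append(
                struc.Atom(
                    local[name],
                    chain_id=chain_id,
                    res_id=res_id,
                    res_name=res_name,
                    atom_name=name,
                    element=_element(name),
                    hetero=False,
                )
            )
        positions = {"N": n, "CA": ca, "C": c}
    return struc.array(atoms)


def make_polypeptide(
    sequence: str,
    chain_id: str = "A",
    start: tuple[float, float, float] = (0.0, 0.0, 0.0),
    first_res_id: int = 1,
    phi: float = -57.0,
    psi: float = -47.0,
) -> struc.AtomArray:
    """Raw helical (or extended, via phi/psi) chain as an ``AtomArray``.

    Building block for multi-chain fixtures; residue numbering starts at
    ``first_res_id`` so receptor-style numbering (V-domain from residue 23)
    can be emulated.
    """
    return _build_chain(
        sequence, chain_id, np.asarray(start, float), phi, psi, first_res_id
    )


def make_helix(
    sequence: str,
    start: tuple[float, float, float] = (0.0, 0.0, 0.0),
    chain_id: str = "A",
) -> Structure:
    """Ideal alpha-helix (phi = -57, psi = -47) from a one-letter sequence."""
    arr = _build_chain(sequence, chain_id, np.asarray(start, float), -57.0, -47.0)
    return Structure(struc.stack([arr]), source=f"synthetic-helix:{sequence}")


def make_extended_tripeptide(center_letter: str) -> Structure:
    """Extended Gly-X-Gly tripeptide.

    Serves as the declared reference state for 'free' side-chain solvent
    accessibility: in the fully extended conformation the central side chain
    has no tertiary contacts, so its SASA approximates the maximum attainable
    value for that residue type.
    """
    arr = _build_chain("G" + center_letter + "G", "A", np.zeros(3), 180.0, 180.0)
    return Structure(
        struc.stack([arr]), source=f"synthetic-gxg:{center_letter}"
    )


# --------------------------------------------------------------------------
# planted two-chain complexes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedContact:
    """Ground truth for one planted inter-chain interaction."""

    res_a: int
    res_b: int
    kind: str  # SB | HB | PP | steric
    atom_a: str
    atom_b: str
    distance: float


@dataclass
class PlantedComplexSpec:
    """Requested composition of a planted two-chain complex."""

    n_salt_bridges: int = 0
    n_hbonds: int = 0
    n_pipi: int = 0
    n_steric: int = 0
    d_salt_bridge: float = 3.0
    d_hbond: float = 2.9
    d_pipi: float = 4.5
    d_steric: float = 3.0
    seed: int = 0

    def kinds(self) -> list[str]:
        return (
            ["SB"] * self.n_salt_bridges
            + ["HB"] * self.n_hbonds
            + ["PP"] * self.n_pipi
            + ["steric"] * self.n_steric
        )


# Local templates: (res_name, defining_atom, [(atom, x, y, z), ...]) with the
# defining atom at the origin and the backbone receding to negative x.
_PLANT_TEMPLATES: dict[str, tuple[str, str, list[tuple[str, float, float, float]]]] = {
    "neg": (
        "GLU",
        "OE1",
        [
            ("OE1", 0.0, 0.0, 0.0),
            ("CD", -1.08, 0.62, 0.0),
            ("OE2", -1.08, 1.87, 0.0),
            ("CG", -2.40, 0.05, 0.0),
            ("CB", -3.75, 0.65, 0.0),
            ("CA", -5.10, 0.05, 0.0),
            ("N", -5.60, 1.25, 0.3),
            ("C", -6.30, -0.95, 0.0),
            ("O", -6.25, -2.15, 0.2),
        ],
    ),
    "pos": (
        "ARG",
        "NH1",
        [
            ("NH1", 0.0, 0.0, 0.0),
            ("CZ", -1.10, 0.62, 0.0),
            ("NH2", -1.10, 1.95, 0.0),
            ("NE", -2.28, -0.05, 0.0),
            ("CD", -3.60, 0.55, 0.0),
            ("CG", -4.90, -0.05, 0.0),
            ("CB", -6.20, 0.55, 0.0),
            ("CA", -7.50, -0.05, 0.0),
            ("N", -8.00, 1.15, 0.3),
            ("C", -8.60, -1.25, 0.0),
            ("O", -8.55, -2.45, 0.2),
        ],
    ),
    "donor": (
        "SER",
        "OG",
        [
            ("OG", 0.0, 0.0, 0.0),
            ("CB", -1.42, 0.0, 0.0),
            ("CA", -2.30, 1.18, 0.0),
            ("N", -2.20, 2.05, 1.1),
            ("C", -3.75, 0.75, 0.0),
            ("O", -4.65, 1.60, 0.2),
        ],
    ),
    "acceptor": (
        "ASN",
        "OD1",
        [
            ("OD1", 0.0, 0.0, 0.0),
            ("CG", -1.23, 0.10, 0.0),
            ("ND2", -1.95, 1.20, 0.0),
            ("CB", -2.00, -1.20, 0.0),
            ("CA", -3.45, -1.35, 0.0),
            ("N", -3.95, -1.50, 1.3),
            ("C", -4.20, -2.55, -0.6),
            ("O", -5.35, -2.95, -0.6),
        ],
    ),
    "ring": (
        "PHE",
        "__centroid__",
        [
            # benzene ring in the yz plane, centroid at the origin
            ("CG", 0.0, 1.39, 0.0),
            ("CD1", 0.0, 0.695, 1.2037),
            ("CD2", 0.0, 0.695, -1.2037),
            ("CE1", 0.0, -0.695, 1.2037),
            ("CE2", 0.0, -0.695, -1.2037),
            ("CZ", 0.0, -1.39, 0.0),
            ("CB", -1.35, 2.15, 0.0),
            ("CA", -2.70, 1.50, 0.0),
            ("N", -3.10, 1.30, 1.35),
            ("C", -3.80, 2.35, -0.75),
            ("O", -4.95, 2.05, -0.85),
        ],
    ),
    "steric": (
        "ALA",
        "CB",
        [
            ("CB", 0.0, 0.0, 0.0),
            ("CA", -1.52, 0.0, 0.0),
            ("N", -2.05, 1.15, 0.5),
            ("C", -2.20, -1.25, -0.3),
            ("O", -1.75, -2.35, -0.2),
        ],
    ),
}

_PLANT_PAIRS = {
    "SB": ("neg", "pos"),
    "HB": ("donor", "acceptor"),
    "PP": ("ring", "ring"),
    "steric": ("steric", "steric"),
}

_PLANT_SPACING = 14.0  # Angstrom along z between planted pairs


def make_planted_complex(
    spec: PlantedComplexSpec,
) -> tuple[Structure, list[PlantedContact]]:
    """Two-chain complex with the requested planted interactions.

    Chain A holds one partner of every plant, chain B the other; successive
    plants are spaced far enough apart that no unintended inter-chain contact
    forms.  The defining distance of each plant matches its target exactly
    (to well under 0.01 Angstrom); filler geometry is deterministic in the
    seed.
    """
    kinds = spec.kinds()
    rng = np.random.default_rng(spec.seed)
    targets = {
        "SB": spec.d_salt_bridge,
        "HB": spec.d_hbond,
        "PP": spec.d_pipi,
        "steric": spec.d_steric,
    }
    limits = {"SB": 4.0, "HB": 3.5, "PP": 5.5, "steric": 3.5}
    for kind in set(kinds):
        if targets[kind] > limits[kind]:
            raise ValueError(
                f"target distance {targets[kind]} for {kind} exceeds its "
                f"detection threshold {limits[kind]}: spec is infeasible"
            )
    atoms_a: list[struc.Atom] = []
    atoms_b: list[struc.Atom] = []
    truth: list[PlantedContact] = []
    for slot, kind in enumerate(kinds):
        z = slot * _PLANT_SPACING
        d = targets[kind]
        tmpl_a, tmpl_b = (_PLANT_TEMPLATES[t] for t in _PLANT_PAIRS[kind])
        res_a = slot + 1
        res_b = slot + 1
        for side, (res_name, defining, template) in (("A", tmpl_a), ("B", tmpl_b)):
            for name, x, y, zz in template:
                if side == "A":
                    coord = np.array([x, y, z + zz])
                else:  # mirror through the interface plane at x = d/2
                    coord = np.array([d - x, y, z + zz])
                atom = struc.Atom(
                    coord,
                    chain_id=side,
                    res_id=res_a if side == "A" else res_b,
                    res_name=res_name,
                    atom_name=name,
                    element=_element(name),
                    hetero=False,
                )
                (atoms_a if side == "A" else atoms_b).append(atom)
        truth.append(
            PlantedContact(
                res_a=res_a,
                res_b=res_b,
                kind=kind,
                atom_a=tmpl_a[1],
                atom_b=tmpl_b[1],
                distance=d,
            )
        )
    if not truth:
        # an 'empty' complex still has two chains, parked far apart
        for side, x0 in (("A", 0.0), ("B", 50.0)):
            for name, x, y, zz in _PLANT_TEMPLATES["steric"][2]:
                (atoms_a if side == "A" else atoms_b).append(
                    struc.Atom(
                        np.array([x0 + x, y, zz]),
                        chain_id=side,
                        res_id=1,
                        res_name="ALA",
                        atom_name=name,
                        element=_element(name),
                        hetero=False,
                    )
                )
    arr = struc.array(atoms_a + atoms_b)
    # deterministic sub-resolution jitter on y only, leaving every defining
    # x/z geometry untouched -- keeps plants exact while varying the fixture
    arr.coord[:, 1] += rng.normal(0.0, 1e-4, arr.array_length())
    return Structure(struc.stack([arr]), source="synthetic-complex"), truth


# --------------------------------------------------------------------------
# trajectories with known persistence
# --------------------------------------------------------------------------


@dataclass
class PersistenceSchedule:
    """Per-plant on/off schedule over frames, plus coordinate jitter."""

    schedules: dict[int, np.ndarray] = field(default_factory=dict)
    jitter_sigma: float = 0.0
    seed: int = 0

    def n_frames(self) -> int:
        lengths = {len(v) for v in self.schedules.values()}
        if len(lengths) != 1:
            raise ValueError("all schedules must cover the same frame count")
        return lengths.pop()


_OFF_DISPLACEMENT = 12.0  # Angstrom, > 2x any detection threshold


def make_trajectory(
    base: Structure,
    truth: list[PlantedContact],
    schedule: PersistenceSchedule,
) -> tuple[Trajectory, dict[int, float]]:
    """Multi-frame trajectory realising a known on/off contact schedule.

    In 'off' frames the chain-B residue of the scheduled plant is displaced
    along +x far beyond every detection threshold; in 'on' frames the base
    geometry is kept (sigma = 0 reproduces it exactly).  Returns the
    trajectory and ground-truth lifetimes in percent.
    """
    for idx in schedule.schedules:
        if not 0 <= idx < len(truth):
            raise KeyError(f"schedule references unknown plant index {idx}")
    n_frames = schedule.n_frames()
    rng = np.random.default_rng(schedule.seed)
    arr0 = base.model(0)
    frames = []
    for f in range(n_frames):
        frame = arr0.copy()
        for idx, on_off in schedule.schedules.items():
            if not on_off[f]:
                plant = truth[idx]
                m = (frame.chain_id == "B") & (frame.res_id == plant.res_b)
                frame.coord[m, 0] += _OFF_DISPLACEMENT
        if schedule.jitter_sigma > 0:
            frame.coord += rng.normal(
                0.0, schedule.jitter_sigma, frame.coord.shape
            )
        frames.append(frame)
    traj = Trajectory(
        Structure(struc.stack(frames), source="synthetic-trajectory"),
        frame_times=np.arange(n_frames, dtype=float),
    )
    lifetimes = {
        idx: 100.0 * float(np.mean(np.asarray(on_off, bool)))
        for idx, on_off in schedule.schedules.items()
    }
    return traj, lifetimes


# --------------------------------------------------------------------------
# alignments with known conservation classes
# --------------------------------------------------------------------------


def make_msa(
    column_classes: list[str],
    species: list[str],
    seed: int = 0,
):
    """Aligned sequences whose per-column conservation symbols are prescribed.

    Columns are sampled so that each realises exactly its requested Clustal
    symbol ('*', ':', '.' or ' ') for the given number of sequences; the
    construction is verified against the conservation module before return
    and fails loudly if a class is unrealisable (e.g. anything but '*' for a
    single sequence).
    """
    from .conservation import (
        AlignedSequenceSet,
        STRONG_GROUPS,
        WEAK_GROUPS,
        conservation_symbols,
    )

    if not column_classes:
        raise ValueError("need at least one column class")
    rng = np.random.default_rng(seed)
    n = len(species)
    alphabet = sorted(_AA3)

    def sample_identical() -> list[str]:
        r = alphabet[rng.integers(len(alphabet))]
        return [r] * n

    def sample_from_pool(pool: list[str]) -> list[str]:
        col = [pool[rng.integers(len(pool))] for _ in range(n)]
        # guarantee at least two distinct members
        col[0], col[1] = pool[0], pool[1]
        return col

    def strong_pools() -> list[list[str]]:
        return [sorted(g) for g in STRONG_GROUPS if len(g) >= 2]

    def weak_pairs() -> list[list[str]]:
        pairs = []
        for g in WEAK_GROUPS:
            for a in sorted(g):
                for b in sorted(g):
                    if a < b and not any(
                        {a, b} <= s for s in STRONG_GROUPS
                    ):
                        pairs.append([a, b])
        return pairs

    def unrelated_pairs() -> list[list[str]]:
        pairs = []
        for a in alphabet:
            for b in alphabet:
                if a < b and not any(
                    {a, b} <= g for g in list(STRONG_GROUPS) + list(WEAK_GROUPS)
                ):
                    pairs.append([a, b])
        return pairs

    columns: list[list[str]] = []
    for cls in column_classes:
        if cls == "*":
            columns.append(sample_identical())
            continue
        if n < 2:
            raise ValueError(
                f"class {cls!r} is unrealisable with {n} sequence(s)"
            )
        if cls == ":":
            pools = strong_pools()
        elif cls == ".":
            pools = weak_pairs()
        elif cls == " ":
            pools = unrelated_pairs()
        else:
            raise ValueError(f"unknown column class {cls!r}")
        columns.append(sample_from_pool(pools[rng.integers(len(pools))]))

    rows = ["".join(col[i] for col in columns) for i in range(n)]
    aln = AlignedSequenceSet(labels=list(species), rows=rows)
    got = conservation_symbols(aln)
    if list(got) != list(column_classes):
        raise AssertionError(
            f"generator failed to realise requested classes: {got!r} != "
            f"{column_classes!r}"
        )
    return aln
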