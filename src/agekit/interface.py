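"""Interprotein interface engine: short-range contact census, specific-contact
classification (salt bridges, hydrogen bonds, pi-pi stacks), persistence over
trajectories, interaction-surface membership and glycated-lysine engagement.

Interaction efficiency between two proteins is quantified here the way it is
commonly done for macromolecular complexes where free-energy estimates are
unreliable: by counting the atoms involved in short-range (3.5 Angstrom)
contacts and classifying the specific (polar/aromatic) interactions among
them.  Over a trajectory each specific contact gets a *lifetime*: the
percentage of frames in which its geometric criterion holds.

The experimentally mapped interaction surfaces on the RAGE V-domain that bind
AGE-modified ligands are encoded as IS1/IS2/IS3 (UniProt numbering).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree

from .config import DEFAULT_THRESHOLDS, Thresholds
from .structures import Structure, Trajectory

# --------------------------------------------------------------------------
# interaction surfaces (UniProt Q15109 numbering, all within the V-domain)
# --------------------------------------------------------------------------

INTERACTION_SURFACES: dict[str, dict[int, str]] = {
    "IS1": {
        36: "Leu", 37: "Lys", 38: "Cys", 40: "Gly", 41: "Ala",
        43: "Lys", 49: "Leu", 81: "Asn", 99: "Cys",
    },
    "IS2": {
        48: "Arg", 50: "Glu", 98: "Arg", 102: "Met", 105: "Asn",
        106: "Gly", 107: "Lys",
    },
    "IS3": {28: "Arg", 29: "Arg", 30: "Ile", 91: "Ile", 94: "Glu", 95: "Gly"},
}


def is_membership(residues: list[int]) -> dict[int, str | None]:
    """Map UniProt-numbered RAGE residues to their interaction surface."""
    out: dict[int, str | None] = {}
    for r in residues:
        out[r] = None
        for label, members in INTERACTION_SURFACES.items():
            if r in members:
                out[r] = label
                break
    return out


# --------------------------------------------------------------------------
# chemistry tables for specific-contact classification
# --------------------------------------------------------------------------

#: Side-chain atoms carrying formal charge at physiological pH.  The
#: carboxymethyl-lysine adduct is zwitterionic: its carboxylate is
#: deprotonated and the secondary amine nitrogen remains protonated.
NEGATIVE_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "CML": {"OX1", "OX2"},
}
POSITIVE_ATOMS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "CML": {"NZ"},
}
#: Histidine is treated as charged only when both ring protons are present.
_HIS_RING_N = {"ND1", "NE2"}

HB_DONORS: dict[str, set[str]] = {
    "*": {"N"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "CML": {"NZ"},
}
HB_ACCEPTORS: dict[str, set[str]] = {
    "*": {"O", "OXT"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"}, "CML": {"OX1", "OX2"},
}

AROMATIC_RINGS: dict[str, list[set[str]]] = {
    "PHE": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}],
    "TYR": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}],
    "HIS": [{"CG", "ND1", "CD2", "CE1", "NE2"}],
    "TRP": [{"CG", "CD1", "CD2", "NE1", "CE2"},
            {"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}],
}

_RES_KEY = tuple[str, int]  # (chain_id, res_id)


# --------------------------------------------------------------------------
# records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactRecord:
    """One interprotein atom pair within the census cutoff."""

    atom_a: int  # atom indices into the frame
    atom_b: int
    res_a: _RES_KEY
    res_b: _RES_KEY
    distance: float
    kind: str = "steric"


@dataclass(frozen=True)
class PersistenceRecord:
    """A classified residue-pair contact and its trajectory lifetime."""

    res_a: str  # e.g. 'Glu45'
    res_b: str  # e.g. 'Arg48'
    kind: str  # SB | HB | PP
    lifetime: float  # percent of frames, 0..100

    def __post_init__(self) -> None:
        if not 0.0 <= self.lifetime <= 100.0:
            raise ValueError("lifetime must be within 0..100 percent")


@dataclass
class CensusResult:
    records: list[ContactRecord]
    n_atoms_a: int
    n_atoms_b: int

    def residue_pairs(self) -> set[tuple[_RES_KEY, _RES_KEY]]:
        return {(r.res_a, r.res_b) for r in self.records}

    def residues_a(self) -> set[_RES_KEY]:
        return {r.res_a for r in self.records}

    def residues_b(self) -> set[_RES_KEY]:
        return {r.res_b for r in self.records}


@dataclass
class InterfaceReport:
    """Per-complex interface summary in the published table's schema."""

    label: str
    n_atoms_a: int
    n_atoms_b: int
    residues_a: list[str]
    residues_b: list[str]
    persistence: list[PersistenceRecord] = field(default_factory=list)
    cml_engaged: bool = False
    is_tags: dict[str, str] = field(default_factory=dict)


# --------------------------------------------------------------------------
# contact census
# --------------------------------------------------------------------------


def contact_census(
    frame: struc.AtomArray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    cutoff: float = DEFAULT_THRESHOLDS.contact,
    include_hydrogens: bool = True,
) -> CensusResult:
    """All inter-group atom pairs within ``cutoff``, via a spatial grid.

    Per-side atom counts are the numbers of *distinct* atoms appearing in at
    least one pair.  Raises on overlapping or empty selections.
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if np.any(mask_a & mask_b):
        raise ValueError("selections overlap")
    if not include_hydrogens:
        heavy = frame.element != "H"
        mask_a = mask_a & heavy
        mask_b = mask_b & heavy
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both selections must be non-empty")
    tree = cKDTree(frame.coord[idx_b])
    neighbours = tree.query_ball_point(frame.coord[idx_a], r=cutoff)
    records = []
    for ia, hits in zip(idx_a, neighbours):
        for j in hits:
            ib = idx_b[j]
            d = float(np.linalg.norm(frame.coord[ia] - frame.coord[ib]))
            records.append(
                ContactRecord(
                    atom_a=int(ia),
                    atom_b=int(ib),
                    res_a=(str(frame.chain_id[ia]), int(frame.res_id[ia])),
                    res_b=(str(frame.chain_id[ib]), int(frame.res_id[ib])),
                    distance=d,
                )
            )
    return CensusResult(
        records=records,
        n_atoms_a=len({r.atom_a for r in records}),
        n_atoms_b=len({r.atom_b for r in records}),
    )


# --------------------------------------------------------------------------
# specific-contact classification
# --------------------------------------------------------------------------


def _residue_atoms(frame: struc.AtomArray, key: _RES_KEY) -> np.ndarray:
    return np.flatnonzero((frame.chain_id == key[0]) & (frame.res_id == key[1]))


def _charged_atom_indices(
    frame: struc.AtomArray, idx: np.ndarray, sign: str
) -> np.ndarray:
    table = NEGATIVE_ATOMS if sign == "neg" else POSITIVE_ATOMS
    res_name = str(frame.res_name[idx[0]])
    names = set(table.get(res_name, set()))
    if res_name == "HIS" and sign == "pos":
        # protonated (charged) only when both ring protons are modelled
        present = {str(frame.atom_name[i]) for i in idx}
        if {"HD1", "HE2"} <= present:
            names |= _HIS_RING_N
    if not names:
        return np.array([], dtype=int)
    return np.array(
        [i for i in idx if str(frame.atom_name[i]) in names], dtype=int
    )


def _polar_atom_indices(
    frame: struc.AtomArray, idx: np.ndarray, role: str
) -> np.ndarray:
    table = HB_DONORS if role == "donor" else HB_ACCEPTORS
    res_name = str(frame.res_name[idx[0]])
    names = set(table.get("*", set())) | set(table.get(res_name, set()))
    return np.array(
        [i for i in idx if str(frame.atom_name[i]) in names], dtype=int
    )


def _ring_centroids(frame: struc.AtomArray, idx: np.ndarray) -> list[np.ndarray]:
    res_name = str(frame.res_name[idx[0]])
    centroids = []
    for ring in AROMATIC_RINGS.get(res_name, []):
        members = [i for i in idx if str(frame.atom_name[i]) in ring]
        if len(members) == len(ring):
            centroids.append(frame.coord[members].mean(axis=0))
    return centroids


def _donor_hydrogen_ok(
    frame: struc.AtomArray,
    donor: int,
    acceptor: int,
    min_angle: float,
) -> bool:
    """Donor-H...acceptor angle test; vacuously true when no H is modelled."""
    res_idx = _residue_atoms(frame, (str(frame.chain_id[donor]), int(frame.res_id[donor])))
    d_pos = frame.coord[donor]
    hydrogens = [
        i
        for i in res_idx
        if frame.element[i] == "H"
        and np.linalg.norm(frame.coord[i] - d_pos) < 1.3
    ]
    if not hydrogens:
        return True
    a_pos = frame.coord[acceptor]
    for h in hydrogens:
        h_pos = frame.coord[h]
        v1 = d_pos - h_pos
        v2 = a_pos - h_pos
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= min_angle:
            return True
    return False


def _pair_is_salt_bridge(
    frame: struc.AtomArray, ia: np.ndarray, ib: np.ndarray, cutoff: float
) -> bool:
    for sa, sb in (("neg", "pos"), ("pos", "neg")):
        ca = _charged_atom_indices(frame, ia, sa)
        cb = _charged_atom_indices(frame, ib, sb)
        if len(ca) and len(cb):
            d = np.linalg.norm(
                frame.coord[ca][:, None, :] - frame.coord[cb][None, :, :], axis=-1
            )
            if np.min(d) <= cutoff:
                return True
    return False


def _pair_is_hbond(
    frame: struc.AtomArray,
    ia: np.ndarray,
    ib: np.ndarray,
    cutoff: float,
    min_angle: float,
) -> bool:
    for donors_idx, acceptors_idx in ((ia, ib), (ib, ia)):
        donors = _polar_atom_indices(frame, donors_idx, "donor")
        acceptors = _polar_atom_indices(frame, acceptors_idx, "acceptor")
        for d in donors:
            for a in acceptors:
                if np.linalg.norm(frame.coord[d] - frame.coord[a]) <= cutoff:
                    if _donor_hydrogen_ok(frame, d, a, min_angle):
                        return True
    return False


def _pair_is_pipi(
    frame: struc.AtomArray, ia: np.ndarray, ib: np.ndarray, cutoff: float
) -> bool:
    for ca in _ring_centroids(frame, ia):
        for cb in _ring_centroids(frame, ib):
            if np.linalg.norm(ca - cb) <= cutoff:
                return True
    return False


def classify_pair(
    frame: struc.AtomArray,
    res_a: _RES_KEY,
    res_b: _RES_KEY,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Interaction kind of a residue pair: SB > HB > PP > steric."""
    ia = _residue_atoms(frame, res_a)
    ib = _residue_atoms(frame, res_b)
    if len(ia) == 0 or len(ib) == 0:
        raise KeyError(f"residue {res_a} or {res_b} missing from frame")
    if _pair_is_salt_bridge(frame, ia, ib, thresholds.salt_bridge):
        return "SB"
    if _pair_is_hbond(frame, ia, ib, thresholds.hbond, thresholds.hbond_angle):
        return "HB"
    if _pair_is_pipi(frame, ia, ib, thresholds.pipi):
        return "PP"
    return "steric"


def classify_specific(
    frame: struc.AtomArray,
    census: CensusResult,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> dict[tuple[_RES_KEY, _RES_KEY], str]:
    """Kind of every residue pair appearing in a contact census."""
    out = {}
    for pair in sorted(census.residue_pairs()):
        try:
            out[pair] = classify_pair(frame, *pair, thresholds=thresholds)
        except KeyError:
            out[pair] = "steric"
    return out


def specific_contacts(
    frame: struc.AtomArray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    include_hydrogens: bool = True,
) -> dict[tuple[_RES_KEY, _RES_KEY], str]:
    """Residue pairs forming specific contacts, each at its own threshold.

    A pi-stack is legitimate out to the centroid cutoff (5.5 Angstrom) even
    though no atom pair enters the 3.5 Angstrom steric census, so candidate
    pairs are gathered with a census at the largest specific-contact reach
    and then classified; steric-only pairs are dropped.
    """
    reach = max(thresholds.salt_bridge, thresholds.hbond, thresholds.pipi)
    census = contact_census(
        frame, mask_a, mask_b, cutoff=reach, include_hydrogens=include_hydrogens
    )
    kinds = classify_specific(frame, census, thresholds)
    return {pair: kind for pair, kind in kinds.items() if kind != "steric"}


# --------------------------------------------------------------------------
# persistence over trajectories
# --------------------------------------------------------------------------


def _pair_satisfies(
    frame: struc.AtomArray,
    res_a: _RES_KEY,
    res_b: _RES_KEY,
    kind: str,
    thresholds: Thresholds,
) -> bool:
    ia = _residue_atoms(frame, res_a)
    ib = _residue_atoms(frame, res_b)
    if len(ia) == 0 or len(ib) == 0:
        raise KeyError(f"residue {res_a} or {res_b} missing from topology")
    if kind == "SB":
        return _pair_is_salt_bridge(frame, ia, ib, thresholds.salt_bridge)
    if kind == "HB":
        return _pair_is_hbond(frame, ia, ib, thresholds.hbond, thresholds.hbond_angle)
    if kind == "PP":
        return _pair_is_pipi(frame, ia, ib, thresholds.pipi)
    if kind == "steric":
        da = frame.coord[ia]
        db = frame.coord[ib]
        d = np.linalg.norm(da[:, None, :] - db[None, :, :], axis=-1)
        return bool(np.min(d) <= thresholds.contact)
    raise ValueError(f"unknown contact kind {kind!r}")


def persistence(
    traj: Trajectory,
    pairs: list[tuple[_RES_KEY, _RES_KEY, str]],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[PersistenceRecord]:
    """Lifetime of each (residue pair, kind): percent of frames in which the
    kind's geometric criterion holds, all frames weighted equally."""
    n = traj.n_frames
    out = []
    for res_a, res_b, kind in pairs:
        hits = sum(
            _pair_satisfies(traj.structure.model(f), res_a, res_b, kind, thresholds)
            for f in range(n)
        )
        out.append(
            PersistenceRecord(
                res_a=f"{res_a[0]}{res_a[1]}",
                res_b=f"{res_b[0]}{res_b[1]}",
                kind=kind,
                lifetime=100.0 * hits / n,
            )
        )
    return out


# --------------------------------------------------------------------------
# glycation-site engagement
# --------------------------------------------------------------------------


def cml_contacts(
    frame: struc.AtomArray,
    mask_cml: np.ndarray,
    mask_partner: np.ndarray,
    cutoff: float = DEFAULT_THRESHOLDS.contact,
) -> CensusResult:
    """Census restricted to the modified lysine versus the partner protein."""
    return contact_census(frame, mask_cml, mask_partner, cutoff=cutoff)


def cml_engagement(reports: list[InterfaceReport]) -> int:
    """Number of complexes whose modified lysine touches the partner."""
    return sum(bool(r.cml_engaged) for r in reports)


# --------------------------------------------------------------------------
# printed-table ingestion
# --------------------------------------------------------------------------

_ROW_RE = re.compile(
    r"([A-Z][a-z]{2})(\d+)-([A-Z][a-z]{2})(\d+)\s*\((SB|HB|PP),\s*(\d+(?:\.\d+)?)%\)"
)


def parse_contact_table(text: str) -> list[PersistenceRecord]:
    """Parse a printed specific-contacts field.

    Grammar: semicolon-separated ``ResA<n>-ResB<m> (KIND, NN%)`` items, e.g.
    ``Glu45-Arg48 (SB, 100%)``.  Empty input yields no records.
    """
    records = []
    for token in filter(None, (t.strip() for t in text.split(";"))):
        m = _ROW_RE.fullmatch(token)
        if m is None:
            raise ValueError(f"cannot parse contact token {token!r}")
        res_a3, num_a, res_b3, num_b, kind, pct = m.groups()
        records.append(
            PersistenceRecord(
                res_a=f"{res_a3}{num_a}",
                res_b=f"{res_b3}{num_b}",
                kind=kind,
                lifetime=float(pct),
            )
        )
    return records


def load_published_interface_table() -> list[InterfaceReport]:
    """The published per-complex interface summary shipped as package data.

    Engagement of the modified lysine is derived from the row itself: the
    complex is engaged when its glycation site appears among the contacting
    albumin residues.
    """
    raw = resources.files("agekit.data").joinpath("md_interface_table.tsv").read_text()
    lines = [l for l in raw.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    reports = []
    for line in lines[1:]:
        fields = dict(zip(header, line.split("\t")))
        residues_a = [r.strip() for r in fields["ghsa_residues"].split(",")]
        residues_b = [r.strip() for r in fields["rage_residues"].split(",")]
        rage_nums = [int(re.sub(r"\D", "", r)) for r in residues_b]
        tags = {
            r: lab
            for r, lab in zip(
                residues_b, (is_membership(rage_nums)[n] for n in rage_nums)
            )
            if lab
        }
        reports.append(
            InterfaceReport(
                label=fields["site"],
                n_atoms_a=int(fields["ghsa_atoms"]),
                n_atoms_b=int(fields["rage_atoms"]),
                residues_a=residues_a,
                residues_b=residues_b,
                persistence=parse_contact_table(fields["specific_contacts"]),
                cml_engaged=fields["site"] in residues_a,
                is_tags=tags,
            )
        )
    return reports
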