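"""Structure data model, PDB I/O, superposition and structural descriptors.

The in-memory container is a biotite ``AtomArrayStack`` (models x atoms),
wrapped in a thin :class:`Structure` that adds provenance, topology guarantees
and selection helpers.  All coordinates are in Angstrom and residue numbering
follows the source PDB file as-is (author numbering, 1-based); RAGE residues
are handled in UniProt numbering throughout, with the V-domain spanning
residues 23-119, C1 120-233 and C2 234-325.

Descriptors:

* ``radius_of_gyration`` -- mass-weighted spread about the centre of mass; an
  increasing value over a trajectory indicates unfolding.
* ``rmsf`` -- per-atom root-mean-square fluctuation about the time-averaged
  position, after least-squares fitting every frame to a reference frame.
* ``sasa`` -- Shrake-Rupley solvent-accessible surface area with a fixed
  deterministic quadrature point set.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

from .config import PROBE_RADIUS, SASA_POINTS, VDW_RADII


class PdbParseError(ValueError):
    """Malformed PDB record; carries the offending line number."""


class TopologyError(ValueError):
    """Models of a multi-model file disagree in atom count or ordering."""


class DegenerateGeometryError(ValueError):
    """Point set unsuitable for a unique rigid superposition."""


# --------------------------------------------------------------------------
# domain maps
# --------------------------------------------------------------------------

#: RAGE extracellular domain ranges in UniProt Q15109 numbering (inclusive).
RAGE_DOMAINS: dict[str, tuple[int, int]] = {
    "V": (23, 119),
    "C1": (120, 233),
    "C2": (234, 325),
}

#: Serum-albumin subdomain ranges in mature numbering (inclusive, canonical
#: helix-bundle boundaries).
ALBUMIN_SUBDOMAINS: dict[str, tuple[int, int]] = {
    "IA": (1, 107),
    "IB": (108, 196),
    "IIA": (197, 297),
    "IIB": (298, 383),
    "IIIA": (384, 497),
    "IIIB": (498, 585),
}


def domain_of(res_id: int, domains: dict[str, tuple[int, int]]) -> str | None:
    """Name of the domain containing ``res_id``, or None."""
    for name, (lo, hi) in domains.items():
        if lo <= res_id <= hi:
            return name
    return None


# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------

_ELEMENT_FROM_NAME = re.compile(r"([A-Z]{1,2})")

# two-letter elements that actually occur in protein PDB files
_TWO_LETTER = {"FE", "ZN", "MG", "MN", "CA", "NA", "CL", "SE", "BR", "CU", "NI", "CO"}


def infer_element(atom_name: str) -> str:
    """Element symbol from a PDB atom name (used when the element column is blank).

    Follows the PDB convention that the element occupies the first characters
    of the right-justified name; digits and greek-position letters are
    stripped.  Single-letter elements win over accidental two-letter matches
    (``CA`` in a protein residue is a calcium only when it is a lone HETATM,
    which callers handle via the element column instead).
    """
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():  # e.g. 1HB2
        name = name.lstrip("0123456789")
    return name[0].upper()


@dataclass(frozen=True)
class Atom:
    """A single atom of one model."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool
    mass: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.mass <= 0:
            raise ValueError("atom mass must be positive")


@dataclass(frozen=True)
class Residue:
    """One residue of one chain (author numbering)."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: tuple[Atom, ...]


class Structure:
    """A multi-model structure with identical topology across models."""

    def __init__(self, stack: struc.AtomArrayStack, source: str = "") -> None:
        if stack.stack_depth() < 1:
            raise TopologyError("structure needs at least one model")
        self.stack = stack
        self.source = source

    # -- basic properties ---------------------------------------------------

    @property
    def n_models(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    def model(self, index: int = 0) -> struc.AtomArray:
        """One frame as a biotite ``AtomArray``."""
        return self.stack[index]

    @property
    def final_model(self) -> struc.AtomArray:
        """Last frame -- the 'final structure' of an MD export."""
        return self.stack[self.n_models - 1]

    def copy(self) -> "Structure":
        return Structure(self.stack.copy(), self.source)

    # -- selections ---------------------------------------------------------

    def mask(
        self,
        chain: str | None = None,
        res_range: tuple[int, int] | None = None,
        atom_names: set[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Boolean atom mask over the shared topology."""
        arr = self.stack
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= arr.chain_id == chain
        if res_range is not None:
            lo, hi = res_range
            m &= (arr.res_id >= lo) & (arr.res_id <= hi)
        if atom_names is not None:
            m &= np.isin(arr.atom_name, sorted(atom_names))
        if heavy_only:
            m &= arr.element != "H"
        return m

    def select(self, selection: str) -> np.ndarray:
        """Mask from a ``chain[:lo-hi[,lo-hi...]]`` selection string."""
        chain, _, ranges = selection.partition(":")
        if not ranges:
            return self.mask(chain=chain)
        m = np.zeros(self.n_atoms, dtype=bool)
        for part in ranges.split(","):
            lo, _, hi = part.partition("-")
            m |= self.mask(chain=chain, res_range=(int(lo), int(hi or lo)))
        return m

    def residues(self, model_index: int = 0) -> list[Residue]:
        """Residue view of one model, in file order."""
        arr = self.model(model_index)
        out: list[Residue] = []
        for start in struc.get_residue_starts(arr):
            stop = start
            key = (arr.chain_id[start], arr.res_id[start], arr.ins_code[start])
            while stop < len(arr) and (
                arr.chain_id[stop],
                arr.res_id[stop],
                arr.ins_code[stop],
            ) == key:
                stop += 1
            atoms = tuple(
                Atom(
                    serial=int(i + 1),
                    name=str(arr.atom_name[i]),
                    element=str(arr.element[i]),
                    coords=arr.coord[i].copy(),
                    is_hydrogen=arr.element[i] == "H",
                    mass=float(struc_info.mass(str(arr.element[i])) or 1.0),
                )
                for i in range(start, stop)
            )
            out.append(
                Residue(
                    chain_id=str(key[0]),
                    number=int(key[1]),
                    insertion_code=str(key[2]),
                    name=str(arr.res_name[start]),
                    atoms=atoms,
                )
            )
        return out


@dataclass
class Trajectory:
    """A structure with >=2 frames plus a physical time axis (ns)."""

    structure: Structure
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.structure.n_models < 2:
            raise ValueError("a trajectory needs at least two frames")
        if len(self.frame_times) != self.structure.n_models:
            raise ValueError("frame count must equal model count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.structure.n_models

    @property
    def total_length(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------


def _validate_pdb_text(path: Path) -> None:
    """Cheap pre-pass so parse failures report a line number."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PdbParseError(
                        f"{path}:{lineno}: truncated coordinate record"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError as err:
                    raise PdbParseError(
                        f"{path}:{lineno}: unreadable coordinate field ({err})"
                    ) from None


def read_pdb(path: str | Path) -> Structure:
    """Read a (possibly multi-model) PDB file.

    Every MODEL block becomes one frame; files without MODEL records yield a
    single-frame structure.  Elements missing from the element column are
    inferred from the atom name.
    """
    path = Path(path)
    _validate_pdb_text(path)
    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(model=None)
    except Exception as err:  # biotite raises on ragged models
        raise TopologyError(f"{path}: inconsistent models ({err})") from err
    blank = np.char.strip(stack.element.astype(str)) == ""
    if np.any(blank):
        inferred = [infer_element(n) for n in stack.atom_name[blank]]
        element = stack.element.copy()
        element[blank] = inferred
        stack.element = element
    return Structure(stack, source=str(path))


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write all models, coordinates at the format's 3-decimal precision."""
    pdb = PDBFile()
    if structure.n_models == 1:
        pdb.set_structure(structure.model(0))
    else:
        pdb.set_structure(structure.stack)
    pdb.write(str(path))


def read_trajectory(path: str | Path, total_length_ns: float) -> Trajectory:
    """Multi-model PDB as a trajectory with evenly spaced frame times."""
    st = read_pdb(path)
    times = np.linspace(0.0, total_length_ns, st.n_models)
    return Trajectory(st, times)


# --------------------------------------------------------------------------
# rigid-body superposition
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference.

    ``apply`` realises ``x -> rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> SuperpositionResult:
    """Optimal (least-squares RMSD) rigid superposition of two point sets.

    Both inputs are (n, 3) arrays with matching point order, n >= 3 and
    non-collinear.  The returned rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least three points")
    mob_centroid = mobile.mean(axis=0)
    ref_centroid = reference.mean(axis=0)
    mob_c = mobile - mob_centroid
    ref_c = reference - ref_centroid
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("mobile points are (near-)collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    translation = ref_centroid - matrix @ mob_centroid
    return SuperpositionResult(
        rotation=matrix,
        translation=translation,
        rmsd=float(rssd / math.sqrt(n)),
    )


def superpose_structure(
    result: SuperpositionResult, structure: Structure
) -> Structure:
    """Apply a rigid transform to every model of a structure (new copy)."""
    out = structure.copy()
    out.stack.coord = out.stack.coord @ result.rotation.T + result.translation
    return out


# --------------------------------------------------------------------------
# descriptors
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptorSeries:
    """A named per-frame or per-residue descriptor series (Angstrom or A^2)."""

    kind: str  # Rg | SASA | RMSF
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError(f"{self.kind} values must be non-negative")


def _masses(arr: struc.AtomArray) -> np.ndarray:
    return np.array([struc_info.mass(str(e)) or 1.0 for e in arr.element])


def radius_of_gyration(
    frame: struc.AtomArray, mask: np.ndarray | None = None
) -> float:
    """Mass-weighted radius of gyration (Angstrom) of the selected atoms."""
    arr = frame if mask is None else frame[mask]
    if arr.array_length() == 0:
        raise ValueError("empty selection")
    masses = _masses(arr)
    coords = arr.coord.astype(np.float64)
    com = np.average(coords, axis=0, weights=masses)
    dev2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(dev2, weights=masses)))


def rg_series(traj: Trajectory, mask: np.ndarray | None = None) -> DescriptorSeries:
    vals = np.array(
        [radius_of_gyration(traj.structure.model(i), mask) for i in range(traj.n_frames)]
    )
    return DescriptorSeries(kind="Rg", values=vals)


def rmsf(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    fit_reference: int = 0,
    fit_mask: np.ndarray | None = None,
) -> DescriptorSeries:
    """Per-atom RMSF (Angstrom) of the selected atoms.

    Each frame is least-squares fitted to frame ``fit_reference`` before
    fluctuations about the time-averaged position are computed.  The fit uses
    ``fit_mask`` when given (e.g. to anchor on a rigid core), otherwise the
    analysed selection itself.
    """
    stack = traj.structure.stack
    if mask is None:
        mask = np.ones(stack.array_length(), dtype=bool)
    if not np.any(mask):
        raise ValueError("selection matches no atoms")
    if fit_mask is None:
        fit_mask = mask
    sub = stack[:, mask | fit_mask]
    within = np.flatnonzero(mask | fit_mask)
    fit_local = np.isin(within, np.flatnonzero(fit_mask))
    ref = sub[fit_reference]
    fitted, _ = struc.superimpose(ref, sub, atom_mask=fit_local)
    keep_local = np.isin(within, np.flatnonzero(mask))
    analysed = fitted[:, keep_local]
    values = struc.rmsf(struc.average(analysed), analysed)
    return DescriptorSeries(kind="RMSF", values=values, labels=analysed.res_id[:])


def ca_mask(structure: Structure, chain: str | None = None) -> np.ndarray:
    return structure.mask(chain=chain, atom_names={"CA"}, heavy_only=True)


def sasa(
    frame: struc.AtomArray,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA (A^2) on the heavy atoms of ``frame``.

    Hydrogens receive zero area (their surface is subsumed by the declared
    heavy-atom radii).  Deterministic for a fixed ``n_points``.
    """
    radii = radii or VDW_RADII
    heavy = frame.element != "H"
    arr = frame[heavy]
    try:
        vdw = np.array([radii[str(e)] for e in arr.element])
    except KeyError as err:
        raise KeyError(f"no van der Waals radius declared for element {err}") from None
    per_heavy = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=n_points,
        point_distr="Fibonacci",
        vdw_radii=vdw,
        ignore_ions=False,
    )
    out = np.zeros(frame.array_length())
    out[heavy] = np.nan_to_num(per_heavy)
    return out


def sasa_per_residue(
    frame: struc.AtomArray,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> dict[tuple[str, int], float]:
    """Residue-aggregated SASA keyed by (chain_id, res_id)."""
    per_atom = sasa(frame, probe_radius=probe_radius, n_points=n_points)
    out: dict[tuple[str, int], float] = {}
    for i in range(frame.array_length()):
        key = (str(frame.chain_id[i]), int(frame.res_id[i]))
        out[key] = out.get(key, 0.0) + float(per_atom[i])
    return out


def atom_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance (Angstrom) between two coordinate triples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))
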