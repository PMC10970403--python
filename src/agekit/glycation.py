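"""Carboxymethyl-lysine (CML) modelling and glycation-relevant lysine
enumeration.

Non-enzymatic glycation condenses a sugar carbonyl with the lysine side-chain
amine; the dominant stable adduct found on serum albumin in vivo is
N(epsilon)-carboxymethyl-lysine.  ``graft_cml`` builds the adduct geometrically:
four heavy atoms (the methylene carbon CW, carboxyl carbon CX and carboxylate
oxygens OX1/OX2) are placed at ideal internal coordinates off the lysine
N-zeta, replacing one zeta-hydrogen when hydrogens are modelled.  The adduct
is zwitterionic at physiological pH: carboxylate deprotonated, amine
protonated.

``surface_lysines`` implements the premise that only surface-exposed lysines
can be glycated and reach the receptor: a lysine counts as surface when its
side-chain solvent accessibility is at least a threshold fraction of the free
reference value (computed on an extended Gly-Lys-Gly tripeptide, a declared,
reproducible reference rather than a literature table).

``attack_distance`` measures the nucleophilic-attack geometry between a sugar
anomeric carbon (C1) and the lysine N-zeta.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import biotite.structure as struc

from .config import DEFAULT_THRESHOLDS, PROBE_RADIUS, SASA_POINTS
from .structures import Structure, atom_distance, sasa
from .synthetic import make_extended_tripeptide, place_atom

#: Ideal internal coordinates of the carboxymethyl group.
CML_GEOMETRY = {
    "N_C_BOND": 1.47,   # N(zeta)-CW
    "C_C_BOND": 1.52,   # CW-CX
    "C_O_BOND": 1.25,   # CX-OX1 / CX-OX2 (delocalised carboxylate)
    "TETRAHEDRAL": 109.47,
    "TRIGONAL": 120.0,
}

_CLASH_CUTOFF = 2.0  # Angstrom, new heavy atom vs existing heavy atom
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


class GlycationError(ValueError):
    """Target residue unsuitable for carboxymethylation."""


def _residue_indices(arr: struc.AtomArray, chain: str, res_id: int) -> np.ndarray:
    idx = np.flatnonzero((arr.chain_id == chain) & (arr.res_id == res_id))
    if len(idx) == 0:
        raise GlycationError(f"no residue {chain}:{res_id} in structure")
    return idx


def _atom_index(arr: struc.AtomArray, idx: np.ndarray, name: str) -> int:
    for i in idx:
        if arr.atom_name[i] == name:
            return int(i)
    raise GlycationError(f"atom {name} missing from target residue")


def graft_cml(
    structure: Structure,
    chain: str,
    res_id: int,
    torsion_step: float = 30.0,
) -> Structure:
    """Carboxymethylate one lysine, returning a new structure.

    The four adduct heavy atoms are placed at the ideal geometry declared in
    :data:`CML_GEOMETRY`; the two free torsions (about N-zeta and the new
    methylene carbon) are scanned on a grid until no new atom lies within
    2.0 Angstrom of an existing heavy atom.  All pre-existing atom
    coordinates are preserved exactly; one zeta-hydrogen is removed when
    present; the residue is renamed CML.
    """
    if structure.n_models != 1:
        raise GlycationError("grafting expects a single-model structure")
    arr = structure.model(0).copy()
    idx = _residue_indices(arr, chain, res_id)
    res_name = str(arr.res_name[idx[0]])
    if res_name == "CML":
        raise GlycationError(
            f"{chain}:{res_id} already carries a carboxymethyl group"
        )
    if res_name != "LYS":
        raise GlycationError(
            f"can only graft onto lysine, {chain}:{res_id} is {res_name}"
        )
    nz = _atom_index(arr, idx, "NZ")
    ce = _atom_index(arr, idx, "CE")
    cd = _atom_index(arr, idx, "CD")
    heavy = np.flatnonzero(arr.element != "H")
    heavy_coords = arr.coord[heavy]

    geo = CML_GEOMETRY
    best = None
    closest_overall = (np.inf, None)
    for t1 in np.arange(180.0, 180.0 + 360.0, torsion_step):
        cw = place_atom(
            arr.coord[cd], arr.coord[ce], arr.coord[nz],
            geo["N_C_BOND"], geo["TETRAHEDRAL"], t1,
        )
        for t2 in np.arange(180.0, 180.0 + 360.0, torsion_step):
            cx = place_atom(
                arr.coord[ce], arr.coord[nz], cw,
                geo["C_C_BOND"], geo["TETRAHEDRAL"], t2,
            )
            ox1 = place_atom(arr.coord[nz], cw, cx, geo["C_O_BOND"], geo["TRIGONAL"], 0.0)
            ox2 = place_atom(arr.coord[nz], cw, cx, geo["C_O_BOND"], geo["TRIGONAL"], 180.0)
            new = np.stack([cw, cx, ox1, ox2])
            d = np.linalg.norm(new[:, None, :] - heavy_coords[None, :, :], axis=-1)
            # bonded neighbour N-zeta is legitimately inside the cutoff
            d[0, np.where(heavy == nz)[0]] = np.inf
            dmin = float(d.min())
            if dmin < closest_overall[0]:
                flat = np.unravel_index(int(d.argmin()), d.shape)
                closest_overall = (
                    dmin,
                    str(arr.atom_name[heavy[flat[1]]]),
                )
            if dmin >= _CLASH_CUTOFF:
                best = new
                break
        if best is not None:
            break
    if best is None:
        raise GlycationError(
            "no clash-free torsion for the carboxymethyl group; closest "
            f"contact {closest_overall[0]:.2f} A to atom {closest_overall[1]}"
        )

    # drop one zeta-hydrogen if modelled
    zeta_h = [
        i for i in idx
        if arr.element[i] == "H"
        and np.linalg.norm(arr.coord[i] - arr.coord[nz]) < 1.3
    ]
    keep = np.ones(arr.array_length(), dtype=bool)
    if zeta_h:
        keep[zeta_h[-1]] = False
    kept = arr[keep]
    res_mask = (kept.chain_id == chain) & (kept.res_id == res_id)
    res_name_col = kept.res_name.copy()
    res_name_col[res_mask] = "CML"
    kept.res_name = res_name_col

    adduct = []
    for name, coord in zip(("CW", "CX", "OX1", "OX2"), best):
        adduct.append(
            struc.Atom(
                coord,
                chain_id=chain,
                res_id=res_id,
                res_name="CML",
                atom_name=name,
                element="O" if name.startswith("O") else "C",
                hetero=False,
            )
        )
    insert_at = int(np.flatnonzero(res_mask)[-1]) + 1
    out = kept[:insert_at] + struc.array(adduct) + kept[insert_at:]
    return Structure(struc.stack([out]), source=structure.source + "+CML")


# --------------------------------------------------------------------------
# surface-lysine accounting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LysineExposure:
    chain: str
    res_id: int
    sidechain_sasa: float
    relative_sasa: float
    surface: bool


@dataclass
class SurfaceLysineReport:
    """Per-lysine side-chain exposure and the surface total for one protein."""

    threshold: float
    lysines: list[LysineExposure]

    @property
    def n_total(self) -> int:
        return len(self.lysines)

    @property
    def n_surface(self) -> int:
        return sum(l.surface for l in self.lysines)


@lru_cache(maxsize=None)
def reference_sidechain_sasa(
    res_letter: str = "K",
    probe_radius: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> float:
    """Free side-chain SASA of residue X in an extended Gly-X-Gly tripeptide."""
    tri = make_extended_tripeptide(res_letter)
    frame = tri.model(0)
    per_atom = sasa(frame, probe_radius=probe_radius, n_points=n_points)
    side = (frame.res_id == 2) & ~np.isin(frame.atom_name, sorted(_BACKBONE))
    return float(per_atom[side].sum())


def surface_lysines(
    structure: Structure,
    threshold: float = DEFAULT_THRESHOLDS.surface_sasa_fraction,
    model_index: int = 0,
) -> SurfaceLysineReport:
    """Classify every lysine of a structure as surface or buried.

    A lysine is surface-exposed when its side-chain SASA is at least
    ``threshold`` times the free reference value.  A structure without
    lysines yields an empty (not erroneous) report.
    """
    frame = structure.model(model_index)
    per_atom = sasa(frame)
    ref = reference_sidechain_sasa("K")
    out = []
    lys_mask = frame.res_name == "LYS"
    keys = sorted(
        {
            (str(frame.chain_id[i]), int(frame.res_id[i]))
            for i in np.flatnonzero(lys_mask)
        }
    )
    for chain, res_id in keys:
        m = (
            (frame.chain_id == chain)
            & (frame.res_id == res_id)
            & ~np.isin(frame.atom_name, sorted(_BACKBONE))
        )
        sc = float(per_atom[m].sum())
        rel = sc / ref
        out.append(
            LysineExposure(
                chain=chain,
                res_id=res_id,
                sidechain_sasa=sc,
                relative_sasa=rel,
                surface=rel >= threshold,
            )
        )
    return SurfaceLysineReport(threshold=threshold, lysines=out)


# --------------------------------------------------------------------------
# attack geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AttackGeometry:
    distance: float
    feasible: bool
    cutoff: float


def attack_distance(
    sugar_c1: np.ndarray,
    lysine_nz: np.ndarray,
    cutoff: float = DEFAULT_THRESHOLDS.attack,
) -> AttackGeometry:
    """Nucleophilic-attack distance between sugar C1 and lysine N-zeta.

    The attack is feasible when the nitrogen sits within ``cutoff`` of the
    anomeric carbon.
    """
    d = atom_distance(sugar_c1, lysine_nz)
    return AttackGeometry(distance=d, feasible=d <= cutoff, cutoff=cutoff)
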