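"""Receptor-dimer assembly on a shared albumin.

Signal transduction by the AGE receptor requires oligomerisation, so a
glycated albumin engaging two receptor monomers at once is the biologically
relevant architecture.  Given two albumin/V-domain complexes, the assembly
scheme is: (1) merge them on their common albumin by a C-alpha least-squares
fit; (2) extend each bound V-domain to the full V+C1+C2 ectodomain by
superposing an experimental full-length reference onto it; (3) test whether
the two V-domain monomers collide (an infeasible dimer) and measure how far
apart the two membrane-proximal C2 domains end up.

The C2-C2 separation is reported as the distance between the C-alpha
centroids of the two C2 regions -- the simplest rotation-invariant
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree

from .config import DEFAULT_THRESHOLDS
from .structures import (
    RAGE_DOMAINS,
    Structure,
    kabsch_superpose,
    superpose_structure,
)


@dataclass
class DimerModel:
    """Two full-length receptor monomers merged onto one albumin."""

    albumin: Structure
    monomer_a: Structure
    monomer_b: Structure
    label_a: str
    label_b: str
    merge_rmsd: float
    extend_rmsd_a: float
    extend_rmsd_b: float
    v_overlap: bool | None = None
    v_clash_count: int | None = None


def _ca_map(
    frame: struc.AtomArray, chain: str, res_range: tuple[int, int] | None = None
) -> dict[int, np.ndarray]:
    mask = (frame.chain_id == chain) & (frame.atom_name == "CA")
    if res_range is not None:
        mask &= (frame.res_id >= res_range[0]) & (frame.res_id <= res_range[1])
    return {int(frame.res_id[i]): frame.coord[i] for i in np.flatnonzero(mask)}


def _matched_coords(
    map_a: dict[int, np.ndarray], map_b: dict[int, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    common = sorted(set(map_a) & set(map_b))
    return (
        np.array([map_a[r] for r in common]),
        np.array([map_b[r] for r in common]),
    )


def assemble_dimer(
    complex_a: Structure,
    complex_b: Structure,
    vc1c2_reference: Structure,
    label_a: str = "A",
    label_b: str = "B",
    albumin_chain: str = "A",
    rage_chain: str = "B",
    reference_chain: str | None = None,
    min_v_match: int = 30,
) -> DimerModel:
    """Build a receptor-dimer model from two albumin/V-domain complexes.

    Both complexes must share albumin residue numbering; the reference must
    span the V, C1 and C2 domains.  All superposition RMSDs are recorded so
    a poor albumin merge or V-domain extension is visible downstream.
    """
    frame_a = complex_a.model(0)
    ref = vc1c2_reference.model(0)
    ref_chain = reference_chain or str(ref.chain_id[0])

    # step 1: merge complex B onto complex A via the shared albumin
    alb_a = _ca_map(frame_a, albumin_chain)
    alb_b = _ca_map(complex_b.model(0), albumin_chain)
    mob, fix = _matched_coords(alb_b, alb_a)
    if len(mob) < 3:
        raise ValueError("albumin chains cannot be matched between complexes")
    merge = kabsch_superpose(mob, fix)
    complex_b_merged = superpose_structure(merge, complex_b)

    # step 2: extend each bound V-domain to the full ectodomain
    v_range = RAGE_DOMAINS["V"]
    ref_v = _ca_map(ref, ref_chain, v_range)
    monomers = []
    extend_rmsds = []
    for cplx in (complex_a, complex_b_merged):
        pose_v = _ca_map(cplx.model(0), rage_chain, v_range)
        mob, fix = _matched_coords(ref_v, pose_v)
        if len(mob) < min_v_match:
            raise ValueError(
                f"V-domain match too short ({len(mob)} C-alpha < {min_v_match})"
            )
        sup = kabsch_superpose(mob, fix)
        monomers.append(superpose_structure(sup, vc1c2_reference))
        extend_rmsds.append(sup.rmsd)

    albumin_only = Structure(
        struc.stack([frame_a[frame_a.chain_id == albumin_chain]]),
        source=complex_a.source,
    )
    return DimerModel(
        albumin=albumin_only,
        monomer_a=monomers[0],
        monomer_b=monomers[1],
        label_a=label_a,
        label_b=label_b,
        merge_rmsd=merge.rmsd,
        extend_rmsd_a=extend_rmsds[0],
        extend_rmsd_b=extend_rmsds[1],
    )


def _domain_heavy_coords(monomer: Structure, domain: str) -> np.ndarray:
    frame = monomer.model(0)
    lo, hi = RAGE_DOMAINS[domain]
    mask = (frame.res_id >= lo) & (frame.res_id <= hi) & (frame.element != "H")
    return frame.coord[mask]


def v_overlap_test(
    dimer: DimerModel, clash_cutoff: float = DEFAULT_THRESHOLDS.clash
) -> tuple[int, bool]:
    """Count heavy-atom clashes between the two V-domain monomers.

    Any pair within ``clash_cutoff`` marks the dimer as sterically
    impossible.
    """
    va = _domain_heavy_coords(dimer.monomer_a, "V")
    vb = _domain_heavy_coords(dimer.monomer_b, "V")
    tree = cKDTree(vb)
    count = int(sum(len(hits) for hits in tree.query_ball_point(va, clash_cutoff)))
    dimer.v_clash_count = count
    dimer.v_overlap = count > 0
    return count, dimer.v_overlap


def c2_distance(dimer: DimerModel) -> float:
    """Distance between the C-alpha centroids of the two C2 domains."""
    out = []
    for monomer in (dimer.monomer_a, dimer.monomer_b):
        frame = monomer.model(0)
        lo, hi = RAGE_DOMAINS["C2"]
        mask = (
            (frame.res_id >= lo) & (frame.res_id <= hi) & (frame.atom_name == "CA")
        )
        if not np.any(mask):
            raise ValueError("monomer lacks C2-domain C-alpha atoms")
        out.append(frame.coord[mask].mean(axis=0))
    return float(np.linalg.norm(out[0] - out[1]))


def membrane_side_heuristic(dimer: DimerModel) -> bool:
    """Do both C2 domains point to the same side of the albumin?

    Heuristic proxy for whether the dimer could dock onto a flat plasma
    membrane without further conformational change: the two C2 centroids
    must lie on the same side of the best-fit plane through the albumin
    C-alpha atoms.  Reported for orientation only; not a validated
    membrane model.
    """
    alb = dimer.albumin.model(0)
    ca = alb.coord[alb.atom_name == "CA"]
    center = ca.mean(axis=0)
    _, _, vh = np.linalg.svd(ca - center)
    normal = vh[2]
    sides = []
    for monomer in (dimer.monomer_a, dimer.monomer_b):
        frame = monomer.model(0)
        lo, hi = RAGE_DOMAINS["C2"]
        mask = (frame.res_id >= lo) & (frame.res_id <= hi) & (frame.atom_name == "CA")
        centroid = frame.coord[mask].mean(axis=0)
        sides.append(np.sign(np.dot(centroid - center, normal)))
    return sides[0] == sides[1] and sides[0] != 0.0
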