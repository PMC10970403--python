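"""Filtering and ranking of docked glycated-albumin / V-domain poses.

Macromolecular docking proposes many orientations of the albumin on the
receptor V-domain; two structural criteria prune them.  First, after
superposing the pose's V-domain onto an experimental V+C1 reference, the
albumin must not overlap the C1 domain (docking used the isolated V-domain,
so poses occupying the V/C1 junction are artefacts).  Second, the modified
lysine should touch one of the experimentally mapped interaction surfaces
(IS1-IS3).  Survivors are ranked by their externally supplied docking score
(higher = more favourable); the score is opaque input, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree

from .config import DEFAULT_THRESHOLDS
from .interface import INTERACTION_SURFACES
from .structures import (
    RAGE_DOMAINS,
    Structure,
    kabsch_superpose,
)


@dataclass
class DockPose:
    """One docked complex: albumin chain + V-domain chain + external score."""

    structure: Structure
    score: float
    site: str  # glycated-lysine label, e.g. 'Lys233'
    albumin_chain: str = "A"
    rage_chain: str = "B"
    c1_clash: bool | None = None
    c1_clash_count: int | None = None
    cml_is_contact: bool | None = None
    matched_is: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")


def _ca_coords_by_resid(
    frame: struc.AtomArray, chain: str, lo: int, hi: int
) -> dict[int, np.ndarray]:
    mask = (
        (frame.chain_id == chain)
        & (frame.atom_name == "CA")
        & (frame.res_id >= lo)
        & (frame.res_id <= hi)
    )
    return {
        int(frame.res_id[i]): frame.coord[i] for i in np.flatnonzero(mask)
    }


def c1_overlap_test(
    pose: DockPose,
    vc1_reference: Structure,
    clash_cutoff: float = DEFAULT_THRESHOLDS.clash,
    reference_chain: str | None = None,
) -> tuple[int, bool]:
    """Albumin clash count against the reference C1 domain.

    The pose is carried into the reference frame by a Kabsch fit of its
    V-domain C-alpha atoms onto the reference V-domain (matched by residue
    number); albumin heavy atoms within ``clash_cutoff`` of any reference C1
    heavy atom count as clashes.
    """
    frame = pose.structure.model(0)
    ref = vc1_reference.model(0)
    ref_chain = reference_chain or str(ref.chain_id[0])
    v_lo, v_hi = RAGE_DOMAINS["V"]
    pose_v = _ca_coords_by_resid(frame, pose.rage_chain, v_lo, v_hi)
    ref_v = _ca_coords_by_resid(ref, ref_chain, v_lo, v_hi)
    common = sorted(set(pose_v) & set(ref_v))
    if len(common) < 3:
        raise ValueError(
            "V-domain C-alpha sets cannot be matched between pose and reference"
        )
    sup = kabsch_superpose(
        np.array([pose_v[r] for r in common]),
        np.array([ref_v[r] for r in common]),
    )
    alb_mask = (frame.chain_id == pose.albumin_chain) & (frame.element != "H")
    alb = sup.apply(frame.coord[alb_mask])
    c1_lo, c1_hi = RAGE_DOMAINS["C1"]
    c1_mask = (
        (ref.chain_id == ref_chain)
        & (ref.res_id >= c1_lo)
        & (ref.res_id <= c1_hi)
        & (ref.element != "H")
    )
    if not np.any(c1_mask):
        raise ValueError("reference carries no C1-domain heavy atoms")
    tree = cKDTree(ref.coord[c1_mask])
    clashes = int(np.sum(tree.query(alb, k=1)[0] <= clash_cutoff))
    pose.c1_clash_count = clashes
    pose.c1_clash = clashes > 0
    return clashes, pose.c1_clash


def cml_is_contact_test(
    pose: DockPose,
    cutoff: float = DEFAULT_THRESHOLDS.contact,
) -> tuple[bool, list[str]]:
    """Does the modified lysine touch an interaction surface?

    True when any CML atom lies within ``cutoff`` of any atom of an IS
    residue on the receptor chain; returns the matched residues as
    ``'IS2:Arg48'``-style labels.
    """
    frame = pose.structure.model(0)
    cml_mask = (frame.chain_id == pose.albumin_chain) & (frame.res_name == "CML")
    if not np.any(cml_mask):
        raise ValueError(f"pose {pose.site}: no CML residue on the albumin chain")
    matched = []
    tree = cKDTree(frame.coord[cml_mask])
    for label, members in INTERACTION_SURFACES.items():
        for res_id, res3 in members.items():
            m = (frame.chain_id == pose.rage_chain) & (frame.res_id == res_id)
            if not np.any(m):
                continue
            d, _ = tree.query(frame.coord[m], k=1)
            if np.min(d) <= cutoff:
                matched.append(f"{label}:{res3}{res_id}")
    pose.cml_is_contact = bool(matched)
    pose.matched_is = matched
    return pose.cml_is_contact, matched


@dataclass
class SelectionResult:
    ranked: list[DockPose]
    dropped_clashing: list[DockPose]
    used_is_criterion: bool
    diagnostic: str = ""


def select_poses(
    poses: list[DockPose],
    vc1_reference: Structure | None = None,
    clash_cutoff: float = DEFAULT_THRESHOLDS.clash,
    contact_cutoff: float = DEFAULT_THRESHOLDS.contact,
) -> SelectionResult:
    """Apply both selection criteria and rank survivors by score.

    Clashing poses are dropped outright.  If any survivor's modified lysine
    touches an interaction surface, only those poses are kept (ranked by
    score, descending); otherwise all non-clashing poses are ranked by score
    alone -- the published behaviour for sites whose adduct never reaches an
    IS.  Ordering is independent of input order (ties broken by site label).
    """
    if not poses:
        raise ValueError("no poses to select from")
    for pose in poses:
        if pose.c1_clash is None:
            if vc1_reference is None:
                raise ValueError(
                    "poses lack clash flags and no V+C1 reference was given"
                )
            c1_overlap_test(pose, vc1_reference, clash_cutoff)
        if pose.cml_is_contact is None:
            cml_is_contact_test(pose, contact_cutoff)
    clashing = [p for p in poses if p.c1_clash]
    clean = [p for p in poses if not p.c1_clash]
    if not clean:
        return SelectionResult(
            ranked=[],
            dropped_clashing=clashing,
            used_is_criterion=False,
            diagnostic="all poses overlap the C1 domain",
        )
    keyed = sorted(clean, key=lambda p: (-p.score, p.site))
    preferred = [p for p in keyed if p.cml_is_contact]
    if preferred:
        return SelectionResult(
            ranked=preferred, dropped_clashing=clashing, used_is_criterion=True
        )
    return SelectionResult(
        ranked=keyed,
        dropped_clashing=clashing,
        used_is_criterion=False,
        diagnostic="no pose contacts an interaction surface; "
        "falling back to score-only ranking",
    )


def read_scores(path: str | Path) -> dict[str, float]:
    """Sidecar TSV of external docking scores (columns: site, score)."""
    scores = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("site"):
            continue
        site, value = line.split("\t")[:2]
        scores[site.strip()] = float(value)
    return scores
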