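# Methods

This note documents the models, conventions and numerical choices behind
`agekit`, and what its tests do and do not demonstrate.

## Structure model and I/O

Structures are held as biotite `AtomArrayStack`s (models × atoms) wrapped in
a thin `Structure` class guaranteeing identical topology across models.
Trajectories are consumed as multi-model PDB with a strictly increasing time
axis; native binary trajectory formats are out of scope. Coordinates and
residue numbering follow the source file as-is (author numbering, 1-based);
no renumbering is performed. Receptor residues are always handled in
UniProt numbering with V = 23–119, C1 = 120–233, C2 = 234–325. Albumin
residues are reported in mature numbering (signal peptide and propeptide
removed; the precursor→mature offset for human albumin is 24, made explicit
by `NumberingMap`). The "final structure" of an MD export is the last model
of the file.

PDB reading pre-validates coordinate fields so parse failures carry a line
number; elements missing from the element column are inferred from the atom
name. Writing uses the format's fixed 3-decimal coordinate precision, which
bounds round-trip fidelity at ~5·10⁻⁴ Å; a second write of re-read records
is byte-identical.

## Superposition

Rigid superposition minimises least-squares RMSD via
`scipy.spatial.transform.Rotation.align_vectors` on centred point sets, with
an explicit rank check rejecting (near-)collinear inputs; the returned
rotation is always proper. The test suite cross-checks RMSDs against an
independently implemented Horn quaternion solution (agreement ≤ 10⁻⁹) and
against 1000 random rigid transforms (Monte-Carlo optimality bound).

## Descriptors

* **Rg** is mass-weighted, computed in float64 about the centre of mass.
  Whether heavy atoms only or all atoms enter is decided by the caller's
  selection; the default selection is all atoms. This is a declared choice —
  sources rarely state their weighting convention.
* **RMSF** fits every frame to frame 0 (configurable) by least squares
  before measuring fluctuations about the time-averaged position. The fit
  selection may differ from the analysed selection so fluctuating atoms can
  be measured against a rigid-core anchor. Fitting to frame 0 is a declared
  convention.
* **SASA** is Shrake–Rupley with probe radius 1.4 Å and a fixed 960-point
  Fibonacci quadrature per atom, making results reproducible bit-for-bit.
  Van der Waals radii are a declared table in `config.VDW_RADII`
  (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å); hydrogens are excluded from
  the quadrature (their surface is subsumed by the heavy-atom radii) and
  report zero area. Quadrature error against the closed-form isolated-sphere
  and two-intersecting-spheres areas is well under 1%; doubling the point
  count moves totals by <0.5%.

## Interface analysis

The short-range contact census collects all inter-group atom pairs within
3.5 Å using a k-d tree (exhaustively verified against an O(n²) scan on
randomized fixtures); per-side counts are distinct atoms appearing in at
least one pair. Hydrogen participation in the census is a config flag. The
shipped default includes hydrogens: MD-derived structures model them
explicitly, and interface sizes in the hundred-atom range arise only when
they are counted. The frame/hydrogen convention used by any external table
one compares against is rarely stated, so the flag is echoed into every
report. The published per-complex table shipped as package data could not be
re-derived here (the underlying structures were never publicly deposited),
so the census convention remains declared rather than calibrated.

Specific contacts are classified per residue pair with common-practice
geometric criteria (published interface tables typically name the
interaction types without defining them):

* **Salt bridge** — any charged-group nitrogen···oxygen pair ≤ 4.0 Å.
  Negative: Asp/Glu carboxylates and the CML carboxylate (OX1/OX2).
  Positive: Lys Nζ, Arg NE/NH1/NH2, and the CML Nζ (the adduct is
  zwitterionic at physiological pH). Histidine counts as positive only when
  both ring protons are modelled.
* **Hydrogen bond** — donor heavy atom···acceptor ≤ 3.5 Å with
  D–H···A ≥ 120°; the angle test is skipped when no donor hydrogen is
  modelled (minimised/docked structures often lack them).
* **π–π stack** — aromatic ring centroids ≤ 5.5 Å (Phe/Tyr/His/Trp rings).

Priority on a residue pair is SB > HB > PP > steric. Because a legitimate
π-stack can lie outside the 3.5 Å census, candidate pairs for specific
contacts are gathered at the largest specific-contact reach (5.5 Å) —
`specific_contacts` — while interface *size* is always reported at 3.5 Å.
Unknown residue types classify as steric.

Persistence weights all frames equally: lifetime = 100 × (frames satisfying
the kind's criterion)/(total frames). Lifetimes are held as exact floats and
rounded to integer percent only at the reporting layer; published lifetime
values appear quantised (mostly multiples of 5), so comparisons against
them should allow ±5 points.

A complex's modified lysine is *engaged* when at least one of its atoms has
a census contact with the partner. When working from the printed interface
table instead of structures, engagement is equivalently derived from
whether the glycation site appears among the listed contacting residues.

## Pose filtering

The C1-overlap criterion superposes the pose's V-domain Cα set onto a
V+C1 reference (matched by residue number) and counts albumin heavy atoms
within 2.5 Å of reference C1 heavy atoms. 2.5 Å between heavy atoms flags
genuine steric impossibility while tolerating surface grazing — a bare
no-overlap requirement needs a concrete distance to be computable. The
IS-contact criterion tests
CML atoms against all atoms of IS1/IS2/IS3 residues at 3.5 Å. Ranking uses
the externally supplied docking score (higher = better); re-implementing
the docking scoring function is out of scope, and "most populated
conformation" selection for sites whose adduct never reaches an IS implies
a clustering that is likewise out of scope — the fallback is score-only
ranking of non-clashing poses. Filtering is order-independent (ties broken
by site label).

## Dimer assembly

Assembly is a three-superposition scheme: albumin↔albumin merge, then
reference→V extension for each monomer; all step RMSDs are recorded. V–V
feasibility uses the same 2.5 Å heavy-atom clash criterion. The C2–C2
separation is the distance between Cα centroids of residues 234–325 of each
monomer — the simplest rotation-invariant convention; published distance
tables rarely state their metric (centroids, termini or closest atoms), so
comparisons against them should be correlational, not exact. The
membrane-dockability report (both C2 centroids on the same side of the
best-fit plane through the albumin Cα atoms) is a flagged heuristic,
excluded from any acceptance comparison.

## Glycation layer

CML grafting uses ideal internal coordinates (N–C 1.47 Å, C–C 1.52 Å,
C–O 1.25 Å, tetrahedral nitrogen/carbon, trigonal carboxylate) and scans the
two free torsions in 30° steps from anti until all four new heavy atoms
clear 2.0 Å from every existing heavy atom; failure raises an error naming
the closest contact. Pre-existing coordinates are preserved bit-identically,
one ζ-hydrogen is removed when present, and grafting an existing CML raises
rather than double-adding.

Surface lysines: a lysine is surface-exposed when its side-chain SASA is at
least θ = 0.25 of the free reference value, computed on an extended
Gly-Lys-Gly tripeptide built by the synthetic module — a declared,
reproducible reference rather than a literature table. θ = 0.25 is the
package default; the intended calibration against a crystal-structure
lysine count could not be run because the calibration structure is not
bundled, so θ remains a declared default.

The nucleophilic-attack criterion (sugar C1 to lysine Nζ) uses a 4.0 Å
cutoff: reported attack geometries of 3.5 and 3.7 Å are both described as
sufficient, and 4.0 Å is the smallest round bound covering both.

## Conservation layer

Alignments are consumed, never computed (Clustal or aligned FASTA, read via
Biopython). Per-column symbols follow the Clustal convention: '*' identical
and gap-free, ':' all residues in one strong group, '.' one weak group,
blank otherwise; the strong/weak groups are stored as auditable package
data, not code. Any gap in a column forces blank; reports render blank as
'-', matching the printed convention for non-conserved positions. Adding
sequences to a subset can only move a column down the order * > : > . >
blank (enforced and property-tested).

The shipped mature albumin sequences are offline transcriptions of the
human and bovine UniProt entries, each verified against published length
and composition checksums (HSA: 585 aa, K=59, R=24, H=16; BSA: 583 aa,
K=59) plus positional anchors; transcriptions of the rat, horse, rabbit and
chicken entries failed those checksums and are deliberately not shipped —
an unverified sequence under a database accession would be worse than an
absent one.

## Synthetic fixtures

The generators produce exactly what the analysis layer inspects and nothing
more: planted complexes carry minimal residues (carboxylate oxygens,
charged nitrogens, ring carbons, four-atom backbones) with each defining
distance exact to <0.01 Å and 14 Å spacing preventing cross-plant contacts;
trajectories realise boolean on/off schedules by displacing the partner
residue 12 Å (beyond twice any detection threshold) in off frames, with
optional Gaussian jitter (σ = 0 reproduces the base coordinates exactly);
alignments realise prescribed per-column symbol classes and are verified
against the conservation module before being returned. Helices use ideal
backbone dihedrals (φ = −57°, ψ = −47°) with simplified side chains.
Every generator is a pure function of (spec, seed).

What passing these tests shows: the geometric criteria, bookkeeping and
closed-loop consistency of the pipeline are correct. What they do not show:
behaviour on real structures with alternate conformations, missing atoms,
non-ideal protonation or crystallographic artefacts — fixtures have none of
those features.

## Problem sizes

Tests and the acceptance script run on deliberately small inputs: planted
complexes of ≲10 residue pairs, 10-frame trajectories, 100 random census
fixtures of ≲80 atoms, 20 superposition trials, 960-point SASA quadrature,
and ~100-residue synthetic chains for pose/dimer assembly. These sizes make
every check exact or closed-form while keeping the full suite under a few
minutes on one CPU.

## Known limitations

* No energetics anywhere: docking scores are opaque inputs; force-field
  interaction energies and binding free energies are out of scope.
* Specific-contact thresholds are conventions; agreement with any published
  table that used different (unstated) definitions is approximate by
  construction.
* The C1-overlap and V-overlap criteria test hard sphere clash only; they
  do not model induced fit.
* Histidine protonation is inferred from modelled hydrogens only.
* The membrane-dockability heuristic ignores the membrane entirely except
  as a plane.
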