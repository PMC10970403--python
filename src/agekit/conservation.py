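"""Cross-species sequence layer: alignment ingestion, Clustal-style
per-column conservation symbols, interface-residue variability tables and
residue-composition accounting for serum albumins.

Residue numbering convention: all albumin residues are reported in *mature*
numbering (signal peptide and propeptide removed), the convention used when
naming glycation sites such as Lys525.  :class:`NumberingMap` makes the
precursor-to-mature offset explicit per species.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import AlignIO, SeqIO

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

_ORDER = {"*": 0, ":": 1, ".": 2, " ": 3}


def _load_groups() -> tuple[list[frozenset[str]], list[frozenset[str]]]:
    """Clustal strong/weak residue groups, stored as auditable package data."""
    raw = json.loads(
        resources.files("agekit.data").joinpath("clustal_groups.json").read_text()
    )
    return (
        [frozenset(g) for g in raw["strong"]],
        [frozenset(g) for g in raw["weak"]],
    )


STRONG_GROUPS, WEAK_GROUPS = _load_groups()


@dataclass
class AlignedSequenceSet:
    """Equal-length aligned sequences with optional species labels."""

    labels: list[str]
    rows: list[str]
    symbol_line: str | None = None  # symbol line read from a Clustal file

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for label, row in zip(self.labels, self.rows):
            bad = set(row) - AMINO_ALPHABET - {GAP}
            if bad:
                raise ValueError(
                    f"row {label!r} contains unknown characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def subset(self, labels: list[str]) -> "AlignedSequenceSet":
        if not labels:
            raise ValueError("subset must name at least one sequence")
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels not in alignment: {missing}")
        return AlignedSequenceSet(
            labels=list(labels),
            rows=[self.rows[index[lab]] for lab in labels],
        )

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.rows]


def read_alignment(path: str | Path) -> AlignedSequenceSet:
    """Read a Clustal or aligned-FASTA file.

    The format is sniffed from the first line; an existing Clustal symbol
    line is preserved for cross-checking against recomputed symbols.
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0] if path.stat().st_size else ""
    fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    symbol_line = None
    if fmt == "clustal":
        ann = getattr(aln, "column_annotations", {})
        symbol_line = ann.get("clustal_consensus")
    return AlignedSequenceSet(
        labels=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
        symbol_line=symbol_line,
    )


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Aligned-FASTA output (row content is preserved byte-exactly)."""
    with open(path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n{row}\n")


def _column_symbol(column: list[str]) -> str:
    residues = set(column)
    if GAP in residues:
        return " "
    if len(residues) == 1:
        return "*"
    if any(residues <= g for g in STRONG_GROUPS):
        return ":"
    if any(residues <= g for g in WEAK_GROUPS):
        return "."
    return " "


def conservation_symbols(
    aln: AlignedSequenceSet, subset: list[str] | None = None
) -> str:
    """Per-column Clustal symbols over the given species subset.

    '*' -- identical, gap-free column; ':' -- all residues within one strong
    group; '.' -- within one weak group; ' ' -- otherwise.
    """
    sub = aln if subset is None else aln.subset(subset)
    return "".join(_column_symbol(sub.column(j)) for j in range(sub.length))


# --------------------------------------------------------------------------
# numbering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NumberingMap:
    """Offset between precursor (UniProt) and mature residue numbering.

    mature = precursor - offset.  For human serum albumin the mature chain
    starts after an 18-residue signal peptide and 6-residue propeptide, so
    the offset is 24 (mature Lys525 = precursor Lys549).
    """

    species: str
    offset: int
    mature_length: int

    def to_precursor(self, mature: int) -> int:
        self._check(mature)
        return mature + self.offset

    def to_mature(self, precursor: int) -> int:
        mature = precursor - self.offset
        self._check(mature)
        return mature

    def _check(self, mature: int) -> None:
        if not 1 <= mature <= self.mature_length:
            raise ValueError(
                f"mature position {mature} outside 1..{self.mature_length} "
                f"for {self.species}"
            )


HSA_NUMBERING = NumberingMap(species="HSA", offset=24, mature_length=585)
BSA_NUMBERING = NumberingMap(species="BSA", offset=24, mature_length=583)


# --------------------------------------------------------------------------
# variability tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VariabilityRow:
    """Conservation class of one interface residue over two species subsets."""

    residue: str  # e.g. 'Lys233' (mature numbering of the reference row)
    class_subset: str
    class_superset: str

    def __post_init__(self) -> None:
        if _ORDER[self.class_superset] < _ORDER[self.class_subset]:
            raise ValueError(
                "conservation over a superset cannot be stricter than over "
                "its subset"
            )


_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def mature_to_column(aln: AlignedSequenceSet, ref_label: str, mature_pos: int) -> int:
    """Alignment column index (0-based) of a mature position in the
    reference row."""
    row = aln.rows[aln.labels.index(ref_label)]
    count = 0
    for j, ch in enumerate(row):
        if ch != GAP:
            count += 1
            if count == mature_pos:
                return j
    raise ValueError(
        f"mature position {mature_pos} beyond the end of row {ref_label!r}"
    )


def variability_table(
    aln: AlignedSequenceSet,
    residues: list[int],
    subset: list[str],
    superset: list[str],
    ref_label: str = "HSA",
) -> list[VariabilityRow]:
    """Conservation class of each reference residue over two species lists.

    ``residues`` are mature positions on the reference row; the class is the
    Clustal symbol of the corresponding alignment column restricted to each
    species list.
    """
    sub_syms = conservation_symbols(aln, subset)
    super_syms = conservation_symbols(aln, superset)
    ref_row = aln.rows[aln.labels.index(ref_label)]
    out = []
    for pos in residues:
        col = mature_to_column(aln, ref_label, pos)
        letter = ref_row[col]
        out.append(
            VariabilityRow(
                residue=f"{_ONE_TO_THREE[letter]}{pos}",
                class_subset=sub_syms[col],
                class_superset=super_syms[col],
            )
        )
    return out


# --------------------------------------------------------------------------
# composition accounting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionResult:
    """Residue-type counts for one mature sequence."""

    species: str
    length: int
    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, letter: str) -> int:
        return self.counts.get(letter, 0)


def residue_composition(
    sequence: str, types: str = "KRH", species: str = ""
) -> CompositionResult:
    """Exact residue counts over a mature protein sequence."""
    sequence = sequence.strip().upper()
    for i, ch in enumerate(sequence):
        if ch not in AMINO_ALPHABET:
            raise ValueError(f"non-standard residue {ch!r} at position {i + 1}")
    tally = Counter(sequence)
    return CompositionResult(
        species=species,
        length=len(sequence),
        counts={t: tally.get(t, 0) for t in types},
    )


def load_reference_albumins() -> dict[str, str]:
    """Mature albumin sequences shipped with the package.

    Only entries whose offline transcription could be verified against
    published composition and length checksums are included (see the data
    file header); verify against the live UniProt entries before production
    use.
    """
    path = resources.files("agekit.data").joinpath("albumin_mature.fasta")
    with resources.as_file(path) as p:
        records = list(SeqIO.parse(str(p), "fasta"))
    return {rec.id.split("|")[0]: str(rec.seq) for rec in records}
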