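"""Tyrosine-based sorting-motif discovery and conservation scoring.

Clathrin adaptor mu subunits recognise YXXPhi motifs (a tyrosine, two
arbitrary residues, then a bulky hydrophobic residue) in the cytosolic tails
of transmembrane cargo.  This module scans protein sequences for such motifs,
projects motif positions onto a multiple sequence alignment of orthologs, and
scores how well the motif tyrosine and Phi positions are conserved across the
family.

Residue numbering is 1-based throughout and ranges are inclusive on both
ends, matching the conventions of RefSeq/UniProt coordinates (e.g. Y536 of
mouse pendrin).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

#: Default bulky-hydrophobic (Phi) residue set for YXXPhi sorting signals.
DEFAULT_PHI_SET = frozenset("LIMFV")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with an explicit full-length numbering offset.

    ``numbering_offset`` is the 1-based index (in full-length coordinates)
    of the first residue in ``residues``; a fragment covering residues
    512-780 of a protein carries offset 512.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")
        bad = set(self.residues.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non amino-acid characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first_position(self) -> int:
        return self.numbering_offset

    @property
    def last_position(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """One-letter code at a full-length 1-based position."""
        if not self.first_position <= position <= self.last_position:
            raise IndexError(
                f"position {position} outside sequence numbering "
                f"[{self.first_position}, {self.last_position}]"
            )
        return self.residues[position - self.numbering_offset].upper()

    def subsequence(self, start: int, end: int) -> str:
        if start > end:
            raise ValueError("start must be <= end")
        return "".join(self.residue_at(p) for p in range(start, end + 1))


@dataclass(frozen=True)
class MotifHit:
    """One YXXPhi occurrence; ``y_position`` is the tyrosine's full-length index."""

    seq_id: str
    y_position: int
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != 4 or self.window[0] != "Y":
            raise ValueError(f"window must be a 4-mer starting with Y, got {self.window!r}")

    @property
    def phi_residue(self) -> str:
        return self.window[3]

    @property
    def phi_position(self) -> int:
        return self.y_position + 3


@dataclass
class Alignment:
    """A gap-aware multiple sequence alignment (consumed, never computed here).

    Rows are (sequence id, gapped residue string) with per-row numbering
    offsets so fragment alignments keep full-length coordinates.
    """

    rows: list[tuple[str, str]]
    offsets: dict[str, int] = field(default_factory=dict)

    GAP_CHARS = frozenset("-.")

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0][1])
        for rid, gapped in self.rows:
            if len(gapped) != ncol:
                raise ValueError(f"row {rid!r} length {len(gapped)} != {ncol}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for rid, gapped in self.rows:
            if rid == seq_id:
                return gapped
        raise KeyError(f"sequence id {seq_id!r} not in alignment")

    def offset(self, seq_id: str) -> int:
        return self.offsets.get(seq_id, 1)

    def ungapped(self, seq_id: str) -> ProteinSequence:
        gapped = self.row(seq_id)
        residues = "".join(c for c in gapped if c not in self.GAP_CHARS)
        return ProteinSequence(seq_id, residues, self.offset(seq_id))

    def column(self, index: int) -> str:
        """1-based alignment column as a string over rows."""
        if not 1 <= index <= self.n_columns:
            raise IndexError(f"column {index} outside [1, {self.n_columns}]")
        return "".join(gapped[index - 1] for _, gapped in self.rows)


@dataclass(frozen=True)
class ConservationProfile:
    """Column conservation of one motif across an ortholog alignment."""

    hit: MotifHit
    y_fraction: float
    phi_fraction: float
    n_sequences: int

    def __post_init__(self) -> None:
        for frac in (self.y_fraction, self.phi_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("conservation fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ClassifiedMotif:
    hit: MotifHit
    profile: ConservationProfile
    y_conserved: bool
    phi_conserved: bool

    @property
    def conserved(self) -> bool:
        return self.y_conserved and self.phi_conserved


def scan_yxxphi(
    seq: ProteinSequence,
    phi_set: Iterable[str] = DEFAULT_PHI_SET,
    region: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """Find every YXXPhi motif in ``seq`` (optionally within an inclusive region).

    A hit is a position p with Y at p and a Phi-set residue at p+3, both inside
    the region.  Overlapping hits are all reported, sorted by position.  'X'
    never matches Y nor Phi.
    """
    phi = {r.upper() for r in phi_set}
    if "X" in phi:
        raise ValueError("'X' (unknown residue) cannot be a Phi-set member")
    if region is None:
        start, end = seq.first_position, seq.last_position
    else:
        start, end = region
        if start > end:
            raise ValueError("region start must be <= end")
        if start < seq.first_position or end > seq.last_position:
            raise IndexError(
                f"region {start}:{end} outside sequence numbering "
                f"[{seq.first_position}, {seq.last_position}]"
            )
    hits: list[MotifHit] = []
    for p in range(start, end - 2):
        if p + 3 > end:
            break
        if seq.residue_at(p) == "Y" and seq.residue_at(p + 3) in phi:
            hits.append(MotifHit(seq.id, p, seq.subsequence(p, p + 3)))
    return hits


def scan_yxxphi_regex(
    seq: ProteinSequence,
    phi_set: Iterable[str] = DEFAULT_PHI_SET,
    region: tuple[int, int] | None = None,
) -> list[int]:
    """Independent regular-expression oracle for :func:`scan_yxxphi`.

    Returns sorted tyrosine positions of Y..[Phi] matches (overlaps included
    via a lookahead).  Kept deliberately separate from the scanner so the two
    can cross-check each other in tests.
    """
    phi = "".join(sorted({r.upper() for r in phi_set}))
    if region is None:
        start, end = seq.first_position, seq.last_position
    else:
        start, end = region
    text = seq.subsequence(start, end)
    pattern = re.compile(rf"(?=(Y..[{re.escape(phi)}]))")
    return [start + m.start() for m in pattern.finditer(text)]


def map_position_to_column(aln: Alignment, seq_id: str, position: int) -> int:
    """Alignment column (1-based) that holds full-length ``position`` of a row."""
    gapped = aln.row(seq_id)
    offset = aln.offset(seq_id)
    target = position - offset  # 0-based index among ungapped residues
    if target < 0:
        raise IndexError(f"position {position} precedes row offset {offset}")
    seen = 0
    for col, char in enumerate(gapped, start=1):
        if char not in Alignment.GAP_CHARS:
            if seen == target:
                return col
            seen += 1
    raise IndexError(
        f"position {position} beyond end of row {seq_id!r} (ungapped length {seen})"
    )


def map_column_to_position(aln: Alignment, seq_id: str, column: int) -> int:
    """Inverse of :func:`map_position_to_column`; errors if the column is a gap."""
    gapped = aln.row(seq_id)
    if not 1 <= column <= aln.n_columns:
        raise IndexError(f"column {column} outside [1, {aln.n_columns}]")
    if gapped[column - 1] in Alignment.GAP_CHARS:
        raise ValueError(f"column {column} is a gap in row {seq_id!r}")
    n_residues = sum(1 for c in gapped[:column] if c not in Alignment.GAP_CHARS)
    return aln.offset(seq_id) + n_residues - 1


def score_motif_conservation(
    aln: Alignment,
    ref_id: str,
    hit: MotifHit,
    phi_set: Iterable[str] = DEFAULT_PHI_SET,
) -> ConservationProfile:
    """Fraction of rows conserving the motif Y and Phi columns.

    Gap characters count as non-matching (they stay in the denominator), the
    conservative convention for sparse ortholog panels.
    """
    phi = {r.upper() for r in phi_set}
    y_col = map_position_to_column(aln, ref_id, hit.y_position)
    phi_col = map_position_to_column(aln, ref_id, hit.phi_position)
    y_column = aln.column(y_col).upper()
    phi_column = aln.column(phi_col).upper()
    n = aln.n_sequences
    y_fraction = sum(1 for c in y_column if c == "Y") / n
    phi_fraction = sum(1 for c in phi_column if c in phi) / n
    return ConservationProfile(hit, y_fraction, phi_fraction, n)


def classify_motifs(
    profiles: Sequence[ConservationProfile],
    y_threshold: float = 0.8,
    phi_threshold: float = 0.8,
) -> list[ClassifiedMotif]:
    """Flag motifs whose Y / Phi columns meet the conservation thresholds."""
    for t in (y_threshold, phi_threshold):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    return [
        ClassifiedMotif(
            hit=p.hit,
            profile=p,
            y_conserved=p.y_fraction >= y_threshold,
            phi_conserved=p.phi_fraction >= phi_threshold,
        )
        for p in profiles
    ]


def pairwise_identity(a: ProteinSequence, b: ProteinSequence,
                      region: tuple[int, int] | None = None) -> float:
    """Percent identity of two equal-numbering sequences over a shared region.

    Positions are compared in full-length coordinates; the region defaults to
    the numbering overlap of the two sequences.
    """
    if region is None:
        start = max(a.first_position, b.first_position)
        end = min(a.last_position, b.last_position)
    else:
        start, end = region
    if start > end:
        raise ValueError("sequences share no overlapping positions")
    n = end - start + 1
    same = sum(1 for p in range(start, end + 1) if a.residue_at(p) == b.residue_at(p))
    return 100.0 * same / n


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, numbering_offset: int = 1) -> list[ProteinSequence]:
    """Read (possibly line-wrapped) FASTA into :class:`ProteinSequence` records."""
    return [
        ProteinSequence(rec.id, str(rec.seq).upper(), numbering_offset)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, fmt: str = "fasta",
                   offsets: dict[str, int] | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal file (``fmt`` = 'fasta' or 'clustal')."""
    msa = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper()) for rec in msa]
    return Alignment(rows, offsets or {})


def motif_report(classified: Sequence[ClassifiedMotif]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "seq_id": [c.hit.seq_id for c in classified],
            "y_position": [c.hit.y_position for c in classified],
            "window": [c.hit.window for c in classified],
            "y_fraction": [c.profile.y_fraction for c in classified],
            "phi_fraction": [c.profile.phi_fraction for c in classified],
            "conserved": [c.conserved for c in classified],
        }
    )
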