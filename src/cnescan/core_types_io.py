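"""Sequence and interval primitives shared by all pipeline stages.

Coordinates follow the GenBank convention externally: 1-based, inclusive on
both ends, as printed in genome annotations. Internal arithmetic converts to
0-based half-open form at the boundary and back, so off-by-one drift against
published coordinates cannot accumulate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "NucleotideSequence",
    "GenomicInterval",
    "IupacPattern",
    "Alignment",
    "AlphabetError",
    "FormatError",
    "reverse_complement",
    "iupac_match",
    "iupac_find",
    "interval_length",
    "expand_flanks",
    "contains",
    "to_zero_based",
    "from_zero_based",
    "read_fasta",
    "write_fasta",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "write_bed",
    "read_bed",
    "read_intervals_tsv",
]

# The 15 IUPAC nucleotide codes and the base sets they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMP_TABLE = str.maketrans(IUPAC_COMPLEMENT)


class AlphabetError(ValueError):
    """A residue outside the IUPAC nucleotide alphabet."""


class FormatError(ValueError):
    """Malformed input file (ragged alignment, empty FASTA, bad BED...)."""


@dataclasses.dataclass
class NucleotideSequence:
    """A named DNA sequence, uppercased on construction.

    Residues are restricted to {A,C,G,T,N}; genome inputs may carry N, which
    never satisfies a strict {A,C,G,T} requirement except through IUPAC
    pattern logic.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - set("ACGTN")
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise AlphabetError(
                f"sequence {self.id!r}: invalid residue {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, iv: "GenomicInterval") -> str:
        """Extract residues for a 1-based inclusive interval; minus-strand
        intervals return the reverse complement (transcriptional orientation)."""
        if iv.end > len(self.residues):
            raise IndexError(
                f"interval {iv.start}-{iv.end} beyond sequence of "
                f"length {len(self.residues)}"
            )
        s = self.residues[iv.start - 1: iv.end]
        return reverse_complement(s) if iv.strand == "-" else s


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """1-based, both-ends-inclusive span on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}-{self.end}: need 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclasses.dataclass(frozen=True)
class IupacPattern:
    """A degenerate motif over the 15 IUPAC codes, e.g. WTTWTG."""

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols.upper()
        object.__setattr__(self, "symbols", s)
        for i, c in enumerate(s):
            if c not in IUPAC_SETS:
                raise AlphabetError(f"invalid IUPAC code {c!r} at position {i + 1}")

    def __len__(self) -> int:
        return len(self.symbols)

    def reverse_complement(self) -> "IupacPattern":
        return IupacPattern(reverse_complement(self.symbols))


@dataclasses.dataclass
class Alignment:
    """A gapped family matrix: equal-length rows over {A,C,G,T,N,-}."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least 2 records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: record lengths {sorted(lengths)}")
        self.records = [(i, s.upper()) for i, s in self.records]

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def ungapped(self, idx: int) -> str:
        return self.records[idx][1].replace("-", "")

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.records)


# ---------------------------------------------------------------------------
# Sequence operations

def reverse_complement(seq: "NucleotideSequence | str") -> str:
    """Reverse complement over the full IUPAC alphabet (e.g. TTTTTG -> CAAAAA)."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    for i, c in enumerate(s):
        if c not in IUPAC_COMPLEMENT:
            raise AlphabetError(f"invalid IUPAC code {c!r} at position {i + 1}")
    return s.translate(_COMP_TABLE)[::-1]


def iupac_match(pattern: "IupacPattern | str", window: str) -> bool:
    """True iff every window base lies in the corresponding code's base set.

    The window must be concrete {A,C,G,T}; length must equal the pattern's.
    """
    p = pattern.symbols if isinstance(pattern, IupacPattern) else pattern.upper()
    w = window.upper()
    if len(p) != len(w):
        raise ValueError(f"pattern length {len(p)} != window length {len(w)}")
    for pc, wc in zip(p, w):
        allowed = IUPAC_SETS.get(pc)
        if allowed is None:
            raise AlphabetError(f"invalid IUPAC code {pc!r} in pattern")
        if wc not in allowed:
            return False
    return True


def iupac_find(pattern: "IupacPattern | str", seq: str) -> list[int]:
    """All 0-based start offsets where the pattern matches (strict bases only)."""
    p = pattern.symbols if isinstance(pattern, IupacPattern) else pattern.upper()
    s = seq.upper()
    k = len(p)
    sets = [IUPAC_SETS[c] for c in p]
    hits = []
    for i in range(len(s) - k + 1):
        if all(s[i + j] in sets[j] for j in range(k)):
            hits.append(i)
    return hits


# ---------------------------------------------------------------------------
# Interval operations

def interval_length(iv: GenomicInterval) -> int:
    return iv.end - iv.start + 1


def expand_flanks(iv: GenomicInterval, up: int, down: int) -> GenomicInterval:
    """Widen an interval by `up` bp upstream and `down` bp downstream in
    transcriptional orientation (mirrored on the minus strand)."""
    if up < 0 or down < 0:
        raise ValueError("flank extensions must be non-negative")
    if iv.strand == "+":
        new_start, new_end = iv.start - up, iv.end + down
    else:
        new_start, new_end = iv.start - down, iv.end + up
    if new_start < 1:
        raise ValueError(f"expansion past position 1 (start would be {new_start})")
    return GenomicInterval(iv.seq_id, new_start, new_end, iv.strand)


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff inner lies fully within outer (strandless comparison)."""
    if outer.seq_id != inner.seq_id:
        raise ValueError(
            f"seq_id mismatch: {outer.seq_id!r} vs {inner.seq_id!r}"
        )
    return outer.start <= inner.start and inner.end <= outer.end


def to_zero_based(iv: GenomicInterval) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (BED convention)."""
    return iv.start - 1, iv.end


def from_zero_based(seq_id: str, start: int, end: int, strand: str = "+") -> GenomicInterval:
    """0-based half-open -> 1-based inclusive."""
    return GenomicInterval(seq_id, start + 1, end, strand)


# ---------------------------------------------------------------------------
# File I/O

def read_fasta(path: "str | Path") -> list[NucleotideSequence]:
    """Read plain FASTA. IDs are the token before the first whitespace;
    duplicate IDs are rejected; an empty file is a format error."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(NucleotideSequence(rec.id, str(rec.seq), rec.description))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: "str | Path",
                width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id,
                  description=s.description if s.description != s.id else "")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_aligned_fasta(path: "str | Path") -> Alignment:
    """Read a gapped FASTA alignment ('-' gaps); ragged input is rejected."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        s = str(rec.seq).upper()
        bad = set(s) - set("ACGTN-")
        if bad:
            raise FormatError(f"record {rec.id!r}: invalid characters {sorted(bad)}")
        records.append((rec.id, s))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(records)


def write_aligned_fasta(aln: Alignment, path: "str | Path", width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, gapped in aln.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(gapped), width):
                fh.write(gapped[i:i + width] + "\n")


def write_bed(intervals: Sequence[tuple[GenomicInterval, str, float]],
              path: "str | Path") -> None:
    """Write BED6: (interval, name, score) triples; 0-based half-open."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            b_start, b_end = to_zero_based(iv)
            fh.write(
                f"{iv.seq_id}\t{b_start}\t{b_end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_bed(path: "str | Path") -> list[tuple[GenomicInterval, str, float]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected 6 BED columns")
            seq_id, s, e, name, score, strand = parts[:6]
            out.append((from_zero_based(seq_id, int(s), int(e), strand),
                        name, float(score)))
    return out


def read_intervals_tsv(path: "str | Path") -> list[GenomicInterval]:
    """Interval fixtures: seq_id <tab> start <tab> end <tab> strand,
    1-based inclusive; '#' comment lines and a header row are skipped."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "seq_id":
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 TSV columns")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                       parts[3]))
    return out
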