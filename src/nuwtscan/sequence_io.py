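"""Reading and writing the formats the screen touches, plus paired-end
linker splitting.

All coordinates in the package are 0-based, half-open. Sequences are
upper-cased on read; IUPAC ambiguity codes are accepted but everything
outside ``ACGT`` is treated as ``N`` by the aligner (never a match).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")

#: default 454 FLX paired-end linker (44 nt)
DEFAULT_PE_LINKER = "GTTGGAACCGAAAGGGTTTGAATTCAAACCCTTTCGGTTCCAAC"


class FastaParseError(ValueError):
    """Raised for empty files, duplicate ids, or non-IUPAC characters."""


class LinkerAmbiguityError(ValueError):
    """Raised when the paired-end linker occurs more than once in a read."""

    def __init__(self, read_id: str, positions: list[int]):
        self.read_id = read_id
        self.positions = positions
        super().__init__(
            f"linker occurs {len(positions)} times in read {read_id!r} "
            f"at positions {positions}"
        )


@dataclass(frozen=True)
class Contig:
    """An assembled nucleotide fragment under screening."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairedEndRead:
    id: str
    sequence: str
    linker: str = DEFAULT_PE_LINKER


@dataclass(frozen=True)
class SplitResult:
    """Outcome of linker splitting: one unsplit record or two mates."""

    records: tuple[Contig, ...]
    split: bool
    short_mate: bool = False  # a mate < 20 nt survived splitting; kept, flagged


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _validate(rec_id: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_NT
    if bad:
        raise FastaParseError(
            f"record {rec_id!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into :class:`Contig` records.

    Sequences are upper-cased. Duplicate ids, non-IUPAC characters and empty
    files raise :class:`FastaParseError`.
    """
    records: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(Contig(rec.id, _validate(rec.id, str(rec.seq))))
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[Contig], path: str | Path) -> None:
    seqrecs = (
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    )
    SeqIO.write(seqrecs, str(path), "fasta")


def split_paired_end_read(read: PairedEndRead, min_mate_len: int = 20) -> SplitResult:
    """Split a 454-style paired-end read on its 44 bp linker.

    The linker must occur exactly once (exact match) for the read to split
    into two mates (linker removed). A read without the linker is returned
    whole and flagged unsplit; two or more occurrences raise
    :class:`LinkerAmbiguityError`. Mates shorter than ``min_mate_len`` are
    kept but flagged.
    """
    if not read.sequence:
        raise ValueError("empty read sequence")
    if not read.linker:
        raise ValueError("empty linker")
    seq = read.sequence.upper()
    linker = read.linker.upper()
    positions = []
    start = 0
    while True:
        i = seq.find(linker, start)
        if i < 0:
            break
        positions.append(i)
        start = i + len(linker)
    if not positions:
        return SplitResult((Contig(read.id, seq),), split=False)
    if len(positions) > 1:
        raise LinkerAmbiguityError(read.id, positions)
    i = positions[0]
    left = Contig(f"{read.id}/1", seq[:i])
    right = Contig(f"{read.id}/2", seq[i + len(linker):])
    short = min(left.length, right.length) < min_mate_len
    return SplitResult((left, right), split=True, short_mate=short)


# --- minimal GFF3 support (the pipeline's truth tables and feature dumps) ---

@dataclass
class Gff3Record:
    seqid: str
    source: str
    type: str
    start: int  # 0-based inclusive; written as 1-based
    end: int    # 0-based exclusive
    score: float | None = None
    strand: str = "."
    frame: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


def _esc(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(records: Sequence[Gff3Record], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(f"{k}={_esc(v)}" for k, v in r.attributes.items())
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(
                f"{r.seqid}\t{r.source}\t{r.type}\t{r.start + 1}\t{r.end}\t"
                f"{score}\t{r.strand}\t{r.frame}\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[Gff3Record]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = {}
            for item in f[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attrs[k] = v.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")
            records.append(
                Gff3Record(
                    seqid=f[0], source=f[1], type=f[2],
                    start=int(f[3]) - 1, end=int(f[4]),
                    score=None if f[5] == "." else float(f[5]),
                    strand=f[6], frame=f[7], attributes=attrs,
                )
            )
    return records
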