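"""Synthetic genomes with planted, degenerate endosymbiont insertions.

This module builds the benchmark the screen is exercised on: a circular
donor (endosymbiont-like) gene panel, a host genome, and a composite genome
carrying scattered donor fragments that have been degraded the way ancient
horizontal transfers degrade — point substitutions down to ~80% nucleotide
identity, frameshifting indels, nonsense codons, poly(A) tract remnants and
inverted-repeat flanks. Every planted insert is described exactly by a
machine-readable truth record whose edit script can be replayed to
reconstruct the original-vs-planted alignment without re-aligning.

Insertions are modelled as independent scattered fragments; whether they
derive from one large transfer subsequently fragmented or from many small
transfers is not distinguishable from the data this emulates, and a
single-block mode is deliberately not provided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference_data import WBM_COG_SPECTRUM
from .sequence_io import (
    DEFAULT_PE_LINKER,
    Contig,
    Gff3Record,
    PairedEndRead,
    read_gff3,
    reverse_complement,
    write_gff3,
)

NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)


class PanelPlacementError(ValueError):
    """Donor genome too small to place the requested genes, or insert
    placement failed after bounded retries."""


# ---------------------------------------------------------------------------
# panels

@dataclass(frozen=True)
class DonorGene:
    locus_tag: str
    start: int          # 0-based on the circular genome
    end: int            # half-open; may exceed genome_length (origin wrap)
    strand: str
    cog_category: str
    taxon_class: str    # "filarial" or "arthropod"
    cds: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DonorPanel:
    """A compact circular donor genome: CDS panel with COG labels."""

    genome_length: int
    genes: tuple[DonorGene, ...]

    def __post_init__(self):
        tags = [g.locus_tag for g in self.genes]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate locus tags in donor panel")
        for g in self.genes:
            if len(g.cds) % 3:
                raise ValueError(f"{g.locus_tag}: CDS length not divisible by 3")
            codons = [g.cds[i:i + 3] for i in range(0, len(g.cds), 3)]
            if codons[-1] not in STOP_CODONS or any(
                c in STOP_CODONS for c in codons[:-1]
            ):
                raise ValueError(
                    f"{g.locus_tag}: CDS must have exactly one stop, at the 3' end"
                )
            if not (0 <= g.start < self.genome_length):
                raise ValueError(f"{g.locus_tag}: start outside genome")

    def get(self, locus_tag: str) -> DonorGene:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)

    @property
    def total_cds_length(self) -> int:
        return sum(len(g.cds) for g in self.genes)

    def protein_panel(self) -> list[tuple[str, str]]:
        """Locus tags with translated CDSs (terminal stop removed)."""
        from Bio.Seq import Seq

        return [
            (g.locus_tag, str(Seq(g.cds[:-3]).translate())) for g in self.genes
        ]


@dataclass(frozen=True)
class HostGene:
    gene_id: str
    sequence: str
    kind: str = "gene"  # "gene" or "retroelement"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list(NUCLEOTIDES))[rng.integers(0, 4, n)])


def generate_donor_panel(
    n_genes: int,
    genome_length: int,
    cog_spectrum: dict[str, int] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_codons: int = 100,
    max_codons: int = 400,
    filarial_fraction: float = 0.4,
) -> DonorPanel:
    """Generate a circular donor CDS panel.

    Gene COG categories are drawn proportional to ``cog_spectrum`` (default:
    the wBm genome spectrum). Genes are placed non-overlapping on the circle;
    one gene may wrap the origin. CDSs are random sense codons closed by a
    single stop.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    spectrum = dict(cog_spectrum or WBM_COG_SPECTRUM)
    if sum(spectrum.values()) <= 0:
        raise ValueError("cog_spectrum counts must sum > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)

    n_codons = rng.integers(min_codons, max_codons + 1, n_genes)
    lengths = 3 * n_codons
    total = int(lengths.sum())
    if total + n_genes > genome_length:
        raise PanelPlacementError(
            f"genome of {genome_length} bp cannot hold {n_genes} genes "
            f"totalling {total} bp"
        )
    slack = genome_length - total
    gaps = rng.multinomial(slack, [1.0 / n_genes] * n_genes)
    rotation = int(rng.integers(0, genome_length))

    cats = list(spectrum)
    weights = np.array([spectrum[c] for c in cats], dtype=float)
    weights /= weights.sum()

    genes = []
    cursor = rotation
    codon_arr = np.asarray(SENSE_CODONS)
    for i in range(n_genes):
        ln = int(lengths[i])
        ncod = int(n_codons[i])
        cds = "".join(codon_arr[rng.integers(0, len(SENSE_CODONS), ncod - 1)])
        cds += STOP_CODONS[rng.integers(0, 3)]
        start = cursor % genome_length
        genes.append(
            DonorGene(
                locus_tag=f"wDON_{i:04d}",
                start=start,
                end=start + ln,
                strand="+" if rng.random() < 0.5 else "-",
                cog_category=cats[int(rng.choice(len(cats), p=weights))],
                taxon_class="filarial" if rng.random() < filarial_fraction
                else "arthropod",
                cds=cds,
            )
        )
        cursor += ln + int(gaps[i])
    return DonorPanel(genome_length=genome_length, genes=tuple(genes))


def generate_host_panel(
    n_genes: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mean_length: int = 700,
    include_retroelement: bool = True,
) -> list[HostGene]:
    """Random host (nematode-like) gene panel, plus one retroelement entry."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    genes = [
        HostGene(f"HOST_{i:04d}", _random_seq(rng, int(max(300, rng.normal(mean_length, 150)))))
        for i in range(n_genes)
    ]
    if include_retroelement:
        genes.append(HostGene("HOST_retro_pao", _random_seq(rng, 1000), kind="retroelement"))
    return genes


def build_host_genome(
    length: int,
    host_panel: Sequence[HostGene],
    rng: np.random.Generator,
) -> tuple[str, dict[str, int]]:
    """Random host genome with exact copies of the host panel genes embedded
    at non-overlapping positions. Returns (genome, gene_id -> start)."""
    genome = list(_random_seq(rng, length))
    placed: dict[str, int] = {}
    occupied: list[tuple[int, int]] = []
    for gene in host_panel:
        for _ in range(1000):
            pos = int(rng.integers(0, length - len(gene.sequence)))
            iv = (pos, pos + len(gene.sequence))
            if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
                occupied.append(iv)
                genome[iv[0]:iv[1]] = gene.sequence
                placed[gene.gene_id] = pos
                break
        else:
            raise PanelPlacementError(f"could not place host gene {gene.gene_id}")
    return "".join(genome), placed


# ---------------------------------------------------------------------------
# mutation machinery

@dataclass(frozen=True)
class MutationEvent:
    """One edit applied to a planted fragment.

    ``offset`` is 0-based. Substitution and nonsense offsets refer to the
    original fragment; insertion/deletion offsets refer to the sequence state
    at the time the event is applied (events are applied in list order,
    substitutions first).
    """

    type: str    # substitution | insertion | deletion | nonsense
    offset: int
    detail: str  # "A>G", inserted bases, deleted bases, or "TAC>TAA"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_inserts: int = 20
    insert_length_mean: float = 180.0
    insert_length_sd: float = 140.0
    insert_length_min: int = 60
    substitution_rate: float = 0.20
    frameshift_prob: float = 0.30
    nonsense_prob: float = 0.30
    polyA_prob: float = 0.15
    polyA_length_min: int = 21
    polyA_length_max: int = 40
    polyA_max_distance: int = 300
    ir_prob: float = 0.15
    ir_arm_length: int = 40
    host_genome_length: int = 100_000
    contig_length_mean: float = 900.0
    contig_length_sd: float = 250.0
    contig_length_min: int = 150
    min_insert_gap: int = 200
    pe_linker: str = DEFAULT_PE_LINKER

    def __post_init__(self):
        for name in ("substitution_rate", "frameshift_prob", "nonsense_prob",
                     "polyA_prob", "ir_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.pe_linker:
            raise ValueError("pe_linker must be non-empty")
        if self.polyA_length_min <= 20:
            raise ValueError("polyA tracts must exceed 20 nt")


def mutate_fragment(
    seq: str,
    substitution_rate: float,
    indel_events: Sequence[tuple[str, int, object]] = (),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[str, list[MutationEvent]]:
    """Apply point substitutions then an explicit indel/nonsense script.

    Substituted bases are drawn uniformly from the three non-original
    nucleotides, so a substitution never silently recreates the original
    base. ``indel_events`` entries are ``(type, offset, detail)`` where
    detail is an int length or a base string for insertions, an int length
    for deletions, and an optional stop codon for nonsense events.
    Returns the mutated sequence and the exact edit script applied.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)

    events: list[MutationEvent] = []
    bases = list(seq.upper())
    if substitution_rate > 0:
        hit = np.nonzero(rng.random(len(bases)) < substitution_rate)[0]
        for i in hit:
            old = bases[i]
            if old not in NUCLEOTIDES:
                continue
            choices = [b for b in NUCLEOTIDES if b != old]
            new = choices[int(rng.integers(0, 3))]
            bases[i] = new
            events.append(MutationEvent("substitution", int(i), f"{old}>{new}"))

    for etype, offset, detail in indel_events:
        if etype == "insertion":
            ins = detail if isinstance(detail, str) else _random_seq(rng, int(detail))
            if not 0 <= offset <= len(bases):
                raise ValueError(f"insertion offset {offset} outside sequence")
            bases[offset:offset] = list(ins)
            events.append(MutationEvent("insertion", offset, ins))
        elif etype == "deletion":
            n = int(detail)
            if not 0 <= offset or offset + n > len(bases):
                raise ValueError(f"deletion at {offset}+{n} outside sequence")
            deleted = "".join(bases[offset:offset + n])
            del bases[offset:offset + n]
            events.append(MutationEvent("deletion", offset, deleted))
        elif etype == "nonsense":
            stop = detail or STOP_CODONS[int(rng.integers(0, 3))]
            if offset + 3 > len(bases):
                raise ValueError(f"nonsense codon at {offset} outside sequence")
            old = "".join(bases[offset:offset + 3])
            bases[offset:offset + 3] = list(stop)
            events.append(MutationEvent("nonsense", offset, f"{old}>{stop}"))
        else:
            raise ValueError(f"unknown event type {etype!r}")
    return "".join(bases), events


def replay_alignment(original: str, events: Sequence[MutationEvent]) -> tuple[str, str]:
    """Replay an edit script into a gapped (original, mutated) alignment.

    This is the exact column-level correspondence implied by the script; no
    re-alignment is involved, so it serves as ground truth for identity and
    reading-frame bookkeeping.
    """
    orig = list(original.upper())
    mut = list(original.upper())
    # apply substitutions / nonsense first on the 1:1 alignment
    for ev in events:
        if ev.type == "substitution":
            mut[ev.offset] = ev.detail.split(">")[1]
        elif ev.type == "nonsense":
            new = ev.detail.split(">")[1]
            for d in range(3):
                mut[ev.offset + d] = new[d]
    # indels operate on mutated-side ungapped coordinates, in order
    for ev in events:
        if ev.type not in ("insertion", "deletion"):
            continue
        # map ungapped mutated offset -> column index
        cols = [i for i, b in enumerate(mut) if b != "-"]
        col = cols[ev.offset] if ev.offset < len(cols) else len(mut)
        if ev.type == "insertion":
            orig[col:col] = ["-"] * len(ev.detail)
            mut[col:col] = list(ev.detail)
        else:
            n = len(ev.detail)
            take = [c for c in cols if c >= col][:n]
            for c in take:
                mut[c] = "-"
    return "".join(orig), "".join(mut)


def alignment_identity(orig_gapped: str, mut_gapped: str) -> float:
    """Percent identity over all alignment columns, gaps included."""
    cols = len(orig_gapped)
    matches = sum(
        1 for a, b in zip(orig_gapped, mut_gapped) if a == b and a != "-"
    )
    return 100.0 * matches / cols if cols else 0.0


# ---------------------------------------------------------------------------
# planting

@dataclass
class InsertionTruthRecord:
    insert_id: str
    host_coordinate: int          # position in the original host genome
    donor_locus_tag: str
    donor_start: int              # half-open interval within the donor CDS
    donor_end: int
    strand: str                   # orientation of the planted fragment
    applied_events: list[MutationEvent] = field(default_factory=list)
    percent_identity: float = 100.0
    has_polyA: bool = False
    polyA_tract_length: int = 0
    polyA_distance: int = 0
    has_inverted_repeat: bool = False
    ir_arm_length: int = 0
    ir_arm_identity: float = 0.0
    # coordinates in the composite genome
    block_start: int = 0          # whole planted block (arms/tract included)
    block_end: int = 0
    fragment_start: int = 0       # the mutated donor fragment itself
    fragment_end: int = 0
    fragment_sequence: str = ""   # as planted (already strand-oriented)


@dataclass(frozen=True)
class OrfStatus:
    frameshift_count: int
    premature_stop_count: int

    @property
    def is_intact(self) -> bool:
        return self.frameshift_count == 0 and self.premature_stop_count == 0


def codon_walk(
    orig_gapped: str,
    mut_gapped: str,
    cds_offset: int,
) -> OrfStatus:
    """Count frameshifts and premature stops from a gapped alignment whose
    original side starts at CDS coordinate ``cds_offset``.

    Frameshifts are gap runs whose length is not a multiple of three.
    Premature stops are stop codons read from the mutated side at complete,
    ungapped, CDS-frame codons, strictly before the last such codon.
    """
    # frameshifts: runs of '-' on either side
    fs = 0
    for gapped in (orig_gapped, mut_gapped):
        run = 0
        for ch in gapped + "$":
            if ch == "-":
                run += 1
            else:
                if run and run % 3:
                    fs += 1
                run = 0
    # codons in the CDS frame
    codons: list[tuple[int, str]] = []
    spos = cds_offset
    i = 0
    n = len(orig_gapped)
    while i < n:
        if orig_gapped[i] == "-":
            i += 1
            continue
        if spos % 3 == 0 and i + 3 <= n:
            window_o = orig_gapped[i:i + 3]
            window_m = mut_gapped[i:i + 3]
            if "-" not in window_o and "-" not in window_m:
                codons.append((spos, window_m))
        spos += 1
        i += 1
    stops = 0
    if codons:
        last = codons[-1][0]
        stops = sum(
            1 for pos, cod in codons if cod in STOP_CODONS and pos < last
        )
    return OrfStatus(frameshift_count=fs, premature_stop_count=stops)


def truth_orf_status(record: InsertionTruthRecord, panel: DonorPanel) -> OrfStatus:
    """Ground-truth reading-frame status of a planted insert, by replaying
    its edit script (no alignment search involved)."""
    gene = panel.get(record.donor_locus_tag)
    fragment = gene.cds[record.donor_start:record.donor_end]
    og, mg = replay_alignment(fragment, record.applied_events)
    return codon_walk(og, mg, cds_offset=record.donor_start)


def _sample_insert_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    m, s = cfg.insert_length_mean, cfg.insert_length_sd
    sigma2 = math.log(1.0 + (s * s) / (m * m))
    mu = math.log(m) - sigma2 / 2.0
    ln = int(round(rng.lognormal(mu, math.sqrt(sigma2))))
    return max(cfg.insert_length_min, ln)


def plant_insertions(
    host_genome: str,
    panel: DonorPanel,
    cfg: SimulationConfig,
) -> tuple[str, list[InsertionTruthRecord]]:
    """Plant degenerate donor fragments into the host genome.

    Returns the composite genome and one truth record per insert. Composite
    length equals host length plus the total planted material (fragments,
    repeat arms, spacers and poly(A) tracts).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    if cfg.n_inserts == 0:
        return host_genome, []
    if cfg.n_inserts * cfg.min_insert_gap >= len(host_genome):
        raise PanelPlacementError("host genome too short for requested inserts")

    positions: list[int] = []
    for _ in range(cfg.n_inserts):
        for _attempt in range(1000):
            pos = int(rng.integers(0, len(host_genome) + 1))
            if all(abs(pos - p) >= cfg.min_insert_gap for p in positions):
                positions.append(pos)
                break
        else:
            raise PanelPlacementError("insert placement failed after retries")
    positions.sort()

    records: list[InsertionTruthRecord] = []
    blocks: list[str] = []
    for idx, pos in enumerate(positions):
        gene = panel.genes[int(rng.integers(0, len(panel.genes)))]
        flen = min(_sample_insert_length(cfg, rng), len(gene.cds))
        dstart = int(rng.integers(0, len(gene.cds) - flen + 1))
        fragment = gene.cds[dstart:dstart + flen]

        script: list[tuple[str, int, object]] = []
        if rng.random() < cfg.nonsense_prob:
            eligible = [
                c - dstart
                for c in range(dstart, dstart + flen - 2)
                if c % 3 == 0 and fragment[c - dstart:c - dstart + 3] not in STOP_CODONS
            ]
            if eligible:
                off = eligible[int(rng.integers(0, len(eligible)))]
                script.append(("nonsense", off, STOP_CODONS[int(rng.integers(0, 3))]))
        if rng.random() < cfg.frameshift_prob:
            ln = int(rng.integers(1, 3))  # 1 or 2 -> guaranteed frame break
            if rng.random() < 0.5:
                script.append(("insertion", int(rng.integers(0, flen + 1)), ln))
            else:
                script.append(("deletion", int(rng.integers(0, flen - ln + 1)), ln))

        mutated, events = mutate_fragment(
            fragment, cfg.substitution_rate, script, rng=rng
        )
        og, mg = replay_alignment(fragment, events)
        identity = alignment_identity(og, mg)
        strand = "+" if rng.random() < 0.5 else "-"
        core = mutated if strand == "+" else reverse_complement(mutated)

        rec = InsertionTruthRecord(
            insert_id=f"ins{idx:03d}",
            host_coordinate=pos,
            donor_locus_tag=gene.locus_tag,
            donor_start=dstart,
            donor_end=dstart + flen,
            strand=strand,
            applied_events=events,
            percent_identity=identity,
            fragment_sequence=core,
        )

        left = ""
        right = ""
        if rng.random() < cfg.ir_prob:
            arm = _random_seq(rng, cfg.ir_arm_length)
            left = arm
            right = reverse_complement(arm)
            rec.has_inverted_repeat = True
            rec.ir_arm_length = cfg.ir_arm_length
            rec.ir_arm_identity = 100.0
        if rng.random() < cfg.polyA_prob:
            tract_len = int(
                rng.integers(cfg.polyA_length_min, cfg.polyA_length_max + 1)
            )
            dist = int(
                rng.integers(0, max(1, cfg.polyA_max_distance - tract_len - 39))
            )
            right += _random_seq(rng, dist) + "A" * tract_len
            rec.has_polyA = True
            rec.polyA_tract_length = tract_len
            rec.polyA_distance = dist

        blocks.append(left + core + right)
        rec.fragment_start = len(left)          # relative; shifted below
        rec.fragment_end = len(left) + len(core)
        records.append(rec)

    out = []
    prev = 0
    offset = 0
    for rec, block, pos in zip(records, blocks, positions):
        out.append(host_genome[prev:pos])
        rec.block_start = pos + offset
        rec.block_end = rec.block_start + len(block)
        rec.fragment_start += rec.block_start
        rec.fragment_end += rec.block_start
        out.append(block)
        offset += len(block)
        prev = pos
    out.append(host_genome[prev:])
    return "".join(out), records


# ---------------------------------------------------------------------------
# shredding

@dataclass(frozen=True)
class ShredResult:
    contigs: tuple[Contig, ...]
    intervals: dict[str, tuple[int, int]]  # contig id -> composite interval


def shred(
    composite: str,
    cfg: SimulationConfig,
    overlap: int = 0,
) -> ShredResult:
    """Tile the composite genome into assembly-like contigs.

    Contig lengths are normal(contig_length_mean, contig_length_sd), floored
    at ``contig_length_min``; a short terminal remainder is merged into the
    last contig. Consecutive contigs overlap by ``overlap`` bp.
    """
    if cfg.contig_length_mean < 100:
        raise ValueError("contig_length_mean must be >= 100 bp")
    if overlap >= cfg.contig_length_min:
        raise ValueError("overlap must be smaller than the minimum contig length")
    rng = np.random.default_rng([cfg.seed, 1])
    contigs = []
    intervals = {}
    start = 0
    i = 0
    L = len(composite)
    while start < L:
        ln = max(cfg.contig_length_min,
                 int(round(rng.normal(cfg.contig_length_mean, cfg.contig_length_sd))))
        end = min(L, start + ln)
        if L - end < cfg.contig_length_min:
            end = L
        cid = f"ctg{i:05d}"
        contigs.append(Contig(cid, composite[start:end]))
        intervals[cid] = (start, end)
        if end >= L:
            break
        start = end - overlap
        i += 1
    return ShredResult(tuple(contigs), intervals)


def shred_paired_end(
    composite: str,
    cfg: SimulationConfig,
    n_reads: int,
    mate_length_mean: float = 250.0,
    mate_length_sd: float = 50.0,
) -> tuple[list[PairedEndRead], dict[str, tuple[Contig, Contig]]]:
    """454-style paired-end reads: two mates joined by the 44 bp linker."""
    rng = np.random.default_rng([cfg.seed, 2])
    L = len(composite)
    reads = []
    mates = {}
    for i in range(n_reads):
        l1 = max(50, int(round(rng.normal(mate_length_mean, mate_length_sd))))
        l2 = max(50, int(round(rng.normal(mate_length_mean, mate_length_sd))))
        span = int(rng.integers(500, 3000))
        p1 = int(rng.integers(0, max(1, L - (l1 + span + l2))))
        p2 = p1 + l1 + span
        m1 = Contig(f"read{i:05d}/1", composite[p1:p1 + l1])
        m2 = Contig(f"read{i:05d}/2", composite[p2:p2 + l2])
        read = PairedEndRead(
            f"read{i:05d}", m1.sequence + cfg.pe_linker + m2.sequence, cfg.pe_linker
        )
        reads.append(read)
        mates[read.id] = (m1, m2)
    return reads, mates


def map_truth_to_contigs(
    truth: Iterable[InsertionTruthRecord],
    intervals: dict[str, tuple[int, int]],
) -> dict[str, list[tuple[str, int, int]]]:
    """For each insert, the contigs its fragment overlaps, with the fragment
    interval expressed in contig coordinates."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    for rec in truth:
        hits = []
        for cid, (cs, ce) in intervals.items():
            s = max(rec.fragment_start, cs)
            e = min(rec.fragment_end, ce)
            if e > s:
                hits.append((cid, s - cs, e - cs))
        out[rec.insert_id] = hits
    return out


# ---------------------------------------------------------------------------
# panel serialization

def write_donor_panel_json(panel: DonorPanel, path: str | Path) -> None:
    data = {
        "genome_length": panel.genome_length,
        "genes": [
            {
                "locus_tag": g.locus_tag, "start": g.start, "end": g.end,
                "strand": g.strand, "cog_category": g.cog_category,
                "taxon_class": g.taxon_class, "cds": g.cds,
            }
            for g in panel.genes
        ],
    }
    Path(path).write_text(__import__("json").dumps(data, indent=1))


def read_donor_panel_json(path: str | Path) -> DonorPanel:
    import json

    data = json.loads(Path(path).read_text())
    return DonorPanel(
        genome_length=data["genome_length"],
        genes=tuple(DonorGene(**g) for g in data["genes"]),
    )


def write_host_panel(host_panel: Sequence[HostGene], path: str | Path) -> None:
    from .sequence_io import write_fasta

    write_fasta([Contig(h.gene_id, h.sequence) for h in host_panel], path)


def read_host_panel(path: str | Path) -> list[HostGene]:
    from .sequence_io import read_fasta

    return [
        HostGene(c.id, c.sequence,
                 kind="retroelement" if "retro" in c.id else "gene")
        for c in read_fasta(path)
    ]


# ---------------------------------------------------------------------------
# truth table serialization (GFF3)

def _events_to_str(events: Sequence[MutationEvent]) -> str:
    return "|".join(f"{e.type}:{e.offset}:{e.detail}" for e in events)


def _events_from_str(s: str) -> list[MutationEvent]:
    events = []
    if s:
        for item in s.split("|"):
            etype, off, detail = item.split(":", 2)
            events.append(MutationEvent(etype, int(off), detail))
    return events


def write_truth_gff3(
    truth: Sequence[InsertionTruthRecord], path: str | Path,
    seqid: str = "composite",
) -> None:
    records = []
    for r in truth:
        records.append(
            Gff3Record(
                seqid=seqid, source="nuwtscan-sim", type="planted_insert",
                start=r.fragment_start, end=r.fragment_end,
                strand=r.strand,
                attributes={
                    "ID": r.insert_id,
                    "locus_tag": r.donor_locus_tag,
                    "donor_start": str(r.donor_start),
                    "donor_end": str(r.donor_end),
                    "host_coordinate": str(r.host_coordinate),
                    "block_start": str(r.block_start),
                    "block_end": str(r.block_end),
                    "percent_identity": repr(r.percent_identity),
                    "events": _events_to_str(r.applied_events),
                    "polyA": f"{int(r.has_polyA)}:{r.polyA_tract_length}:{r.polyA_distance}",
                    "inverted_repeat": f"{int(r.has_inverted_repeat)}:"
                                       f"{r.ir_arm_length}:{r.ir_arm_identity!r}",
                    "sequence": r.fragment_sequence,
                },
            )
        )
    write_gff3(records, path)


def read_truth_gff3(path: str | Path) -> list[InsertionTruthRecord]:
    out = []
    for g in read_gff3(path):
        if g.type != "planted_insert":
            continue
        a = g.attributes
        pa = a["polyA"].split(":")
        ir = a["inverted_repeat"].split(":")
        out.append(
            InsertionTruthRecord(
                insert_id=a["ID"],
                host_coordinate=int(a["host_coordinate"]),
                donor_locus_tag=a["locus_tag"],
                donor_start=int(a["donor_start"]),
                donor_end=int(a["donor_end"]),
                strand=g.strand,
                applied_events=_events_from_str(a["events"]),
                percent_identity=float(a["percent_identity"]),
                has_polyA=bool(int(pa[0])),
                polyA_tract_length=int(pa[1]),
                polyA_distance=int(pa[2]),
                has_inverted_repeat=bool(int(ir[0])),
                ir_arm_length=int(ir[1]),
                ir_arm_identity=float(ir[2]),
                block_start=int(a["block_start"]),
                block_end=int(a["block_end"]),
                fragment_start=g.start,
                fragment_end=g.end,
                fragment_sequence=a["sequence"],
            )
        )
    return out
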