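"""The homology screen: local alignment of contigs against compact donor and
host sequence panels, Karlin–Altschul e-values, top-hit classification at the
1e-5 cutoff, the 600/300 bp contig-splitting rescue pass, translated
(six-frame) homology, and best-hit taxon tallies.

The aligner is exact affine-gap Smith–Waterman (Bio.Align.PairwiseAligner in
local mode) over both strands; suboptimal HSPs are recovered by masking the
query interval of each reported hit with a sentinel character and
re-aligning. An optional shared-k-mer prefilter (k=11 by default) skips
sequence pairs that cannot seed an alignment. Statistics use
E = K·m·n·e^(−λS) with ungapped nucleotide defaults (K=0.711, λ=1.372)
applied to gapped scores as a documented approximation; the effective
database length n is the total panel length.

A gap of length g costs ``gap_open + g·gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .sequence_io import Contig, reverse_complement
from .synthetic_data import DonorPanel, HostGene
from .util import round_half_up

DNA_MASK = "X"
PROTEIN_MASK = "#"


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring plus the Karlin–Altschul statistical parameters.

    ``matrix`` names a protein substitution matrix; when None, nucleotide
    match/mismatch scoring applies.
    """

    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    K: float = 0.711
    lam: float = 1.372
    matrix: str | None = None

    def __post_init__(self):
        if self.matrix is None and not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be positive")


#: legacy blastn-era nucleotide defaults
DNA_SCHEME = ScoringScheme()
#: BLOSUM62 with affine gaps 11/1 (gapped protein statistics)
PROTEIN_SCHEME = ScoringScheme(
    match=1.0, mismatch=-1.0, gap_open=-11.0, gap_extend=-1.0,
    K=0.041, lam=0.267, matrix="BLOSUM62",
)


@dataclass
class AlignmentHit:
    """One local-alignment HSP (or a merged chain of same-subject HSPs)."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    raw_score: float
    percent_identity: float
    alignment_length: int
    n_matches: int
    frame: int | None = None
    bitscore: float | None = None
    evalue: float | None = None


@dataclass
class HomologCall:
    """A classified region on a contig: endosymbiont-like or host-like."""

    contig_id: str
    start: int
    end: int
    klass: str                      # "donor_like" | "host_like"
    best_locus_tag: str
    best_taxon_class: str | None    # "filarial" | "arthropod" | None
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    strand: str
    mode: str = "nucleotide"        # "nucleotide" | "translated"
    subject_start: int = 0
    subject_end: int = 0
    rescued: bool = False           # found only by the splitting pass
    frame: int | None = None


# ---------------------------------------------------------------------------
# aligner plumbing

def _dna_matrix() -> substitution_matrices.Array:
    alpha = "ACGTN" + DNA_MASK
    m = substitution_matrices.Array(alphabet=alpha, dims=2)
    for a in alpha:
        for b in alpha:
            if DNA_MASK in (a, b):
                m[a, b] = -1e6
            elif a in "ACGT" and a == b:
                m[a, b] = DNA_SCHEME.match
            else:
                m[a, b] = DNA_SCHEME.mismatch
    return m


def _protein_matrix(name: str) -> substitution_matrices.Array:
    base = substitution_matrices.load(name)
    alpha = str(base.alphabet) + PROTEIN_MASK
    m = substitution_matrices.Array(alphabet=alpha, dims=2)
    for a in base.alphabet:
        for b in base.alphabet:
            m[a, b] = base[a, b]
    for a in alpha:
        m[a, PROTEIN_MASK] = -1e6
        m[PROTEIN_MASK, a] = -1e6
    return m


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    if scheme.matrix is None:
        mat = _dna_matrix()
        if (scheme.match, scheme.mismatch) != (DNA_SCHEME.match, DNA_SCHEME.mismatch):
            mat = _dna_matrix().copy()
            for a in "ACGT":
                for b in "ACGTN":
                    mat[a, b] = scheme.match if a == b else scheme.mismatch
                    mat[b, a] = mat[a, b]
        al.substitution_matrix = mat
    else:
        al.substitution_matrix = _protein_matrix(scheme.matrix)
    # PairwiseAligner charges open for the first gap symbol: open+extend here
    al.open_gap_score = scheme.gap_open + scheme.gap_extend
    al.extend_gap_score = scheme.gap_extend
    return al


def sanitize_dna(seq: str) -> str:
    """Uppercase and collapse every non-ACGT symbol to N."""
    seq = seq.upper()
    return "".join(c if c in "ACGT" else "N" for c in seq)


def _alignment_stats(q: str, s: str, blocks, protein: bool = False) -> tuple[int, int]:
    """(matches, columns) over aligned blocks; gap columns count, ambiguous
    nucleotides (N) never count as matches."""
    matches = 0
    cols = 0
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in blocks:
        if prev_qe is not None:
            cols += (qs - prev_qe) + (ss - prev_se)
        for off in range(qe - qs):
            a, b = q[qs + off], s[ss + off]
            if a == b and (protein if protein else a in "ACGT"):
                matches += 1
        cols += qe - qs
        prev_qe, prev_se = qe, se
    return matches, cols


def best_local_alignment(
    query: str, subject: str, scheme: ScoringScheme = DNA_SCHEME,
) -> tuple[float, list[tuple[tuple[int, int], tuple[int, int]]]] | None:
    """Optimal local alignment score and aligned blocks, or None if empty."""
    al = _aligner(scheme)
    res = al.align(query, subject)
    if res.score <= 0:
        return None
    aln = res[0]
    blocks = [
        ((int(qs), int(qe)), (int(ss), int(se)))
        for (qs, qe), (ss, se) in zip(aln.aligned[0], aln.aligned[1])
    ]
    return float(res.score), blocks


def align_local(
    query: str,
    subject: str,
    scheme: ScoringScheme = DNA_SCHEME,
    min_score: float = 1.0,
    both_strands: bool = True,
    max_hits: int = 4,
    query_id: str = "query",
    subject_id: str = "subject",
    protein: bool = False,
) -> list[AlignmentHit]:
    """Smith–Waterman local alignment over one or both strands.

    Hits are reported in descending raw score. After each hit the aligned
    query interval is masked and the search repeated, recovering suboptimal
    HSPs, until the score drops below ``min_score`` or ``max_hits`` is
    reached.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    mask = PROTEIN_MASK if protein else DNA_MASK
    if not protein:
        query = sanitize_dna(query)
        subject = sanitize_dna(subject)
    hits: list[AlignmentHit] = []
    strands = ("+", "-") if (both_strands and not protein) else ("+",)
    L = len(query)
    for strand in strands:
        q = query if strand == "+" else reverse_complement(query)
        work = list(q)
        for _ in range(max_hits):
            res = best_local_alignment("".join(work), subject, scheme)
            if res is None or res[0] < min_score:
                break
            score, blocks = res
            matches, cols = _alignment_stats(q, subject, blocks, protein=protein)
            qs, qe = blocks[0][0][0], blocks[-1][0][1]
            ss, se = blocks[0][1][0], blocks[-1][1][1]
            if strand == "+":
                q_iv = (qs, qe)
            else:
                q_iv = (L - qe, L - qs)
            hits.append(
                AlignmentHit(
                    query_id=query_id, subject_id=subject_id,
                    query_start=q_iv[0], query_end=q_iv[1],
                    subject_start=ss, subject_end=se,
                    strand=strand, raw_score=score,
                    percent_identity=100.0 * matches / cols if cols else 0.0,
                    alignment_length=cols, n_matches=matches,
                )
            )
            work[qs:qe] = [mask] * (qe - qs)
    hits.sort(key=lambda h: (-h.raw_score, h.query_start))
    return hits


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics

def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme = DNA_SCHEME) -> float:
    """Expected chance alignments of score >= S in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be positive")
    return scheme.K * m * n * math.exp(-scheme.lam * raw_score)


def bitscore(raw_score: float, scheme: ScoringScheme = DNA_SCHEME) -> float:
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)


def min_score_for_evalue(
    threshold: float, m: int, n: int, scheme: ScoringScheme = DNA_SCHEME
) -> float:
    """Smallest raw score whose e-value is below ``threshold``."""
    return math.log(scheme.K * m * n / threshold) / scheme.lam


# ---------------------------------------------------------------------------
# the screen

@dataclass(frozen=True)
class _Subject:
    sid: str
    seq: str
    source: str                 # "donor" | "host"
    taxon_class: str | None
    cog_category: str | None


def _subjects(donor_panel: DonorPanel, host_panel: Sequence[HostGene]) -> list[_Subject]:
    subs = [
        _Subject(g.locus_tag, sanitize_dna(g.cds), "donor", g.taxon_class, g.cog_category)
        for g in donor_panel.genes
    ]
    subs += [
        _Subject(h.gene_id, sanitize_dna(h.sequence), "host", None, None)
        for h in host_panel
    ]
    return subs


def _kmers(seq: str, k: int) -> set[str]:
    return {
        seq[i:i + k] for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    }


def _merge_hits(hits: list[AlignmentHit], merge_gap: int) -> list[AlignmentHit]:
    """Merge HSPs to the same subject on the same strand within
    ``merge_gap`` bp on the query into one chained hit."""
    out: list[AlignmentHit] = []
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    for group in groups.values():
        group.sort(key=lambda h: h.query_start)
        cur = group[0]
        for h in group[1:]:
            if h.query_start - cur.query_end <= merge_gap:
                n_matches = cur.n_matches + h.n_matches
                length = cur.alignment_length + h.alignment_length
                cur = replace(
                    cur,
                    query_end=max(cur.query_end, h.query_end),
                    subject_start=min(cur.subject_start, h.subject_start),
                    subject_end=max(cur.subject_end, h.subject_end),
                    raw_score=max(cur.raw_score, h.raw_score),
                    n_matches=n_matches,
                    alignment_length=length,
                    percent_identity=100.0 * n_matches / length if length else 0.0,
                )
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    return out


def _components(hits: list[AlignmentHit]) -> list[list[AlignmentHit]]:
    """Group hits whose query intervals overlap into connected components."""
    comps: list[list[AlignmentHit]] = []
    cur: list[AlignmentHit] = []
    cur_end = -1
    for h in sorted(hits, key=lambda x: (x.query_start, x.query_end)):
        if cur and h.query_start < cur_end:
            cur.append(h)
            cur_end = max(cur_end, h.query_end)
        else:
            if cur:
                comps.append(cur)
            cur = [h]
            cur_end = h.query_end
    if cur:
        comps.append(cur)
    return comps


def screen_contigs(
    contigs: Iterable[Contig],
    donor_panel: DonorPanel,
    host_panel: Sequence[HostGene] = (),
    threshold: float = 1e-5,
    scheme: ScoringScheme = DNA_SCHEME,
    merge_gap: int = 30,
    seed_filter: bool = True,
    seed_k: int = 11,
    seed_min_hits: int = 2,
    max_hits_per_pair: int = 4,
) -> list[HomologCall]:
    """Classify homologous regions on contigs against both panels.

    For every region (connected component of overlapping hits) the top hit
    by bitscore decides the class; ties break by e-value, then locus tag. A
    region is ``donor_like`` only when its top hit is a donor locus with
    e-value below ``threshold``.

    The two-hit seeding prefilter skips pairs sharing fewer than
    ``seed_min_hits`` distinct ``seed_k``-mers (either strand); any region
    long and similar enough to clear the e-value cutoff shares many.
    """
    subjects = _subjects(donor_panel, host_panel)
    if not subjects:
        raise ValueError("panels are empty")
    db_len = sum(len(s.seq) for s in subjects)
    subj_kmers = {s.sid: _kmers(s.seq, seed_k) for s in subjects} if seed_filter else {}
    by_sid = {s.sid: s for s in subjects}

    calls: list[HomologCall] = []
    for contig in contigs:
        q = sanitize_dna(contig.sequence)
        if len(q) < seed_k:
            continue
        if seed_filter:
            qk = _kmers(q, seed_k) | _kmers(reverse_complement(q), seed_k)
        min_raw = min_score_for_evalue(threshold, len(q), db_len, scheme)
        hits: list[AlignmentHit] = []
        for s in subjects:
            if seed_filter and len(qk & subj_kmers[s.sid]) < seed_min_hits:
                continue
            found = align_local(
                q, s.seq, scheme, min_score=min_raw,
                max_hits=max_hits_per_pair,
                query_id=contig.id, subject_id=s.sid,
            )
            for h in found:
                h.evalue = evalue(h.raw_score, len(q), db_len, scheme)
                h.bitscore = bitscore(h.raw_score, scheme)
                if h.evalue < threshold:
                    hits.append(h)
        merged = _merge_hits(hits, merge_gap)
        for comp in _components(merged):
            top = sorted(
                comp, key=lambda h: (-(h.bitscore or 0), h.evalue, h.subject_id)
            )[0]
            src = by_sid[top.subject_id]
            calls.append(
                HomologCall(
                    contig_id=contig.id,
                    start=top.query_start, end=top.query_end,
                    klass="donor_like" if src.source == "donor" else "host_like",
                    best_locus_tag=top.subject_id,
                    best_taxon_class=src.taxon_class,
                    percent_identity=top.percent_identity,
                    alignment_length=top.alignment_length,
                    evalue=top.evalue, bitscore=top.bitscore,
                    strand=top.strand,
                    subject_start=top.subject_start,
                    subject_end=top.subject_end,
                )
            )
    calls.sort(key=lambda c: (c.contig_id, c.start))
    return calls


def split_and_rescan(
    contig: Contig, max_len: int = 600, min_len: int = 300
) -> list[tuple[Contig, int]]:
    """Split a contig into balanced pieces for the rescue pass.

    Contigs of at most ``max_len`` bp are returned unsplit. Longer contigs
    are cut into ceil(L/max_len) contiguous pieces whose lengths differ by at
    most one; every piece then lies in [min_len, max_len] and concatenating
    the pieces reconstructs the contig. Returns (piece, offset) pairs.
    """
    L = contig.length
    if L == 0:
        raise ValueError("empty contig")
    if L <= max_len:
        return [(contig, 0)]
    p = math.ceil(L / max_len)
    base, rem = divmod(L, p)
    lengths = [base + 1] * rem + [base] * (p - rem)
    pieces = []
    off = 0
    for i, ln in enumerate(lengths):
        assert min_len <= ln <= max_len
        pieces.append(
            (Contig(f"{contig.id}|split{i}", contig.sequence[off:off + ln]), off)
        )
        off += ln
    return pieces


def screen_with_rescue(
    contigs: Sequence[Contig],
    donor_panel: DonorPanel,
    host_panel: Sequence[HostGene] = (),
    threshold: float = 1e-5,
    max_len: int = 600,
    min_len: int = 300,
    **screen_kwargs,
) -> list[HomologCall]:
    """Full-contig screen plus the splitting rescue pass.

    Long contigs whose strong homology to one gene can shadow a weaker
    endosymbiont-like region are re-screened in [min_len, max_len] pieces;
    donor calls found only in pieces are mapped back to contig coordinates
    and added (flagged ``rescued``).
    """
    base = screen_contigs(contigs, donor_panel, host_panel, threshold, **screen_kwargs)
    pieces: list[Contig] = []
    origin: dict[str, tuple[str, int]] = {}
    for c in contigs:
        if c.length > max_len:
            for piece, off in split_and_rescan(c, max_len, min_len):
                pieces.append(piece)
                origin[piece.id] = (c.id, off)
    if not pieces:
        return base
    rescue = screen_contigs(pieces, donor_panel, host_panel, threshold, **screen_kwargs)
    out = list(base)
    for call in rescue:
        if call.klass != "donor_like":
            continue
        parent, off = origin[call.contig_id]
        mapped_start, mapped_end = call.start + off, call.end + off
        dup = any(
            b.contig_id == parent and b.klass == "donor_like"
            and b.best_locus_tag == call.best_locus_tag
            and min(b.end, mapped_end) > max(b.start, mapped_start)
            for b in out
        )
        if not dup:
            call.contig_id = parent
            call.start, call.end = mapped_start, mapped_end
            call.rescued = True
            out.append(call)
    out.sort(key=lambda c: (c.contig_id, c.start))
    return out


# ---------------------------------------------------------------------------
# translated (protein-level) homology

def translated_hits(
    contig: Contig,
    protein_panel: Sequence[tuple[str, str]],
    threshold: float = 1e-5,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    max_hits_per_pair: int = 4,
) -> list[AlignmentHit]:
    """Six-frame translated HSPs against a donor protein panel.

    Hit coordinates are nucleotide positions on the contig (forward strand);
    ``frame`` is in {±1, ±2, ±3}.
    """
    seq = sanitize_dna(contig.sequence)
    L = len(seq)
    db_len = sum(len(p) for _, p in protein_panel)
    if db_len == 0:
        raise ValueError("empty protein panel")
    hits: list[AlignmentHit] = []
    for frame in (1, 2, 3, -1, -2, -3):
        nt = seq if frame > 0 else reverse_complement(seq)
        off = abs(frame) - 1
        usable = (L - off) // 3
        if usable < 5:
            continue
        aa = str(Seq(nt[off:off + 3 * usable]).translate())
        min_raw = min_score_for_evalue(threshold, len(aa), db_len, scheme)
        for sid, prot in protein_panel:
            found = align_local(
                aa, prot, scheme, min_score=min_raw, both_strands=False,
                max_hits=max_hits_per_pair, query_id=contig.id,
                subject_id=sid, protein=True,
            )
            for h in found:
                h.evalue = evalue(h.raw_score, len(aa), db_len, scheme)
                h.bitscore = bitscore(h.raw_score, scheme)
                if h.evalue >= threshold:
                    continue
                nt_start = off + 3 * h.query_start
                nt_end = off + 3 * h.query_end
                if frame > 0:
                    h.query_start, h.query_end = nt_start, nt_end
                else:
                    h.query_start, h.query_end = L - nt_end, L - nt_start
                h.strand = "+" if frame > 0 else "-"
                h.frame = frame
                hits.append(h)
    hits.sort(key=lambda h: (-h.raw_score, h.query_start))
    return hits


def translated_screen(
    contig: Contig,
    protein_panel: Sequence[tuple[str, str]],
    threshold: float = 1e-5,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    merge_gap: int = 30,
) -> list[HomologCall]:
    """Translated homology calls (mode="translated"), one per region."""
    hits = translated_hits(contig, protein_panel, threshold, scheme)
    calls = []
    for comp in _components(_merge_hits(hits, merge_gap)):
        top = sorted(comp, key=lambda h: (-(h.bitscore or 0), h.evalue, h.subject_id))[0]
        calls.append(
            HomologCall(
                contig_id=contig.id, start=top.query_start, end=top.query_end,
                klass="donor_like", best_locus_tag=top.subject_id,
                best_taxon_class=None,
                percent_identity=top.percent_identity,
                alignment_length=top.alignment_length,
                evalue=top.evalue, bitscore=top.bitscore,
                strand=top.strand, mode="translated",
                subject_start=top.subject_start, subject_end=top.subject_end,
                frame=top.frame,
            )
        )
    calls.sort(key=lambda c: c.start)
    return calls


def count_frame_changes(hits: Sequence[AlignmentHit]) -> int:
    """Frame changes between chained translated HSPs to the same subject —
    the protein-level frameshift signal."""
    changes = 0
    by_subject: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.frame is not None:
            by_subject.setdefault(h.subject_id, []).append(h)
    for group in by_subject.values():
        group.sort(key=lambda h: h.query_start)
        for a, b in zip(group, group[1:]):
            if a.frame != b.frame and a.strand == b.strand:
                changes += 1
    return changes


def tally_best_hit_taxa(calls: Sequence[HomologCall]) -> tuple[int, int, int]:
    """(filarial count, arthropod count, integer percent filarial)."""
    donor = [c for c in calls if c.klass == "donor_like"]
    if not donor:
        return (0, 0, 0)
    filarial = sum(1 for c in donor if c.best_taxon_class == "filarial")
    arthropod = len(donor) - filarial
    return filarial, arthropod, round_half_up(100.0 * filarial / len(donor))
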