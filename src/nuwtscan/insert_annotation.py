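"""Characterisation of endosymbiont-like regions: junction fragments, ORF
integrity (frameshifts and premature stops), truncation status, poly(A)
tracts and inverted repeats.

A "junction fragment" is a contig carrying both an endosymbiont-like and a
host-like region — the physical evidence of integration. ORF integrity is
judged codon-aware against the donor CDS: a region is an intact potential
open reading frame when its alignment to the donor CDS shows no indel of
length not divisible by three and no in-frame stop codon before the final
aligned codon; a defined start codon is not required. A region is internal
when both ends lie more than 25 bp from the contig ends, otherwise it is
truncated at the end of a contig and its true length is unknowable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .homology_screen import (
    AlignmentHit,
    HomologCall,
    ScoringScheme,
    best_local_alignment,
    count_frame_changes,
    sanitize_dna,
)

#: scoring for codon-aware donor-CDS comparison. Milder than the screening
#: scheme so the alignment spans a whole ~80%-identity fragment instead of
#: trimming to its best-conserved stretch — ORF verdicts need the full extent.
ANNOTATION_SCHEME = ScoringScheme(
    match=1.0, mismatch=-1.0, gap_open=-3.0, gap_extend=-1.0
)
from .sequence_io import Contig, reverse_complement
from .synthetic_data import STOP_CODONS

END_MARGIN_BP = 25  # "more than 25 bp from the end" = internal


@dataclass
class JunctionStatus:
    contig_id: str
    is_junction: bool
    donor_regions: list[tuple[int, int]] = field(default_factory=list)
    host_regions: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class PseudogeneAnnotation:
    call_id: str
    frameshift_count: int
    premature_stop_count: int
    is_internal: bool

    @property
    def is_intact_orf(self) -> bool:
        return self.frameshift_count == 0 and self.premature_stop_count == 0


@dataclass
class SequenceFeature:
    kind: str                     # "polyA" | "inverted_repeat"
    start: int
    end: int
    strand: str = "+"
    tract_length: int | None = None
    arm2_start: int | None = None
    arm2_end: int | None = None
    arm_identity: float | None = None
    distance_to_nearest_donor_call: int | None = None


def find_junction_fragments(calls: Iterable[HomologCall]) -> list[JunctionStatus]:
    """Flag contigs that carry both donor-like and host-like regions."""
    by_contig: dict[str, list[HomologCall]] = {}
    for c in calls:
        by_contig.setdefault(c.contig_id, []).append(c)
    out = []
    for cid in sorted(by_contig):
        group = sorted(by_contig[cid], key=lambda c: c.start)
        donor = [(c.start, c.end) for c in group if c.klass == "donor_like"]
        host = [(c.start, c.end) for c in group if c.klass == "host_like"]
        out.append(
            JunctionStatus(
                contig_id=cid,
                is_junction=bool(donor) and bool(host),
                donor_regions=donor,
                host_regions=host,
            )
        )
    return out


def classify_truncation(call: HomologCall, contig: Contig) -> str:
    """"internal" when both region ends are >25 bp from the contig ends."""
    if call.start <= END_MARGIN_BP or contig.length - call.end <= END_MARGIN_BP:
        return "end_truncated"
    return "internal"


def annotate_orf_integrity(
    call: HomologCall,
    contig: Contig,
    donor_cds: str | None,
    scheme: ScoringScheme = ANNOTATION_SCHEME,
    translated: Sequence[AlignmentHit] = (),
) -> PseudogeneAnnotation:
    """Codon-aware ORF integrity of a donor-like region.

    The region is aligned to its donor CDS (oriented by the call's strand).
    Frameshifts are indels of length not divisible by three; when translated
    HSPs are supplied, frame changes between chained HSPs count too.
    Premature stops are in-frame (CDS-frame) stop codons strictly before the
    final aligned codon. ``is_internal`` applies the 25 bp end rule.
    """
    if donor_cds is None:
        raise ValueError(f"no donor CDS for locus {call.best_locus_tag}")
    region = contig.sequence[call.start:call.end]
    if call.strand == "-":
        region = reverse_complement(region)
    region = sanitize_dna(region)
    res = best_local_alignment(region, sanitize_dna(donor_cds), scheme)
    if res is None:
        raise ValueError(
            f"region {call.contig_id}:{call.start}-{call.end} does not align "
            f"to donor CDS {call.best_locus_tag}"
        )
    _, blocks = res

    frameshifts = 0
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in blocks:
        if prev_qe is not None:
            dq, ds = qs - prev_qe, ss - prev_se
            if (dq - ds) % 3:
                frameshifts += 1
        prev_qe, prev_se = qe, se
    frameshifts += count_frame_changes(
        [h for h in translated if h.subject_id == call.best_locus_tag]
    )

    codons: list[tuple[int, str]] = []
    for (qs, qe), (ss, se) in blocks:
        c = ss + (-ss) % 3
        while c + 3 <= se:
            qoff = qs + (c - ss)
            codons.append((c, region[qoff:qoff + 3]))
            c += 3
    stops = 0
    if codons:
        last = max(c for c, _ in codons)
        stops = sum(1 for c, cod in codons if cod in STOP_CODONS and c < last)

    is_internal = (
        call.start > END_MARGIN_BP and contig.length - call.end > END_MARGIN_BP
    )
    return PseudogeneAnnotation(
        call_id=f"{call.contig_id}:{call.start}-{call.end}",
        frameshift_count=frameshifts,
        premature_stop_count=stops,
        is_internal=is_internal,
    )


def scan_polyA(
    contig: Contig,
    min_run: int = 21,
    donor_calls: Sequence[HomologCall] = (),
) -> list[SequenceFeature]:
    """Maximal homopolymer adenosine runs of at least ``min_run`` nt.

    T runs are reported as minus-strand poly(A). Runs are exact — a single
    interrupting base ends the run. The distance to the nearest donor-like
    call is recorded (0 when overlapping), not used as a filter.
    """
    seq = contig.sequence.upper()
    feats = []
    for base, strand in (("A", "+"), ("T", "-")):
        for m in re.finditer(f"{base}{{{min_run},}}", seq):
            feats.append(
                SequenceFeature(
                    kind="polyA", start=m.start(), end=m.end(), strand=strand,
                    tract_length=m.end() - m.start(),
                )
            )
    for f in feats:
        dists = [
            max(0, max(c.start - f.end, f.start - c.end))
            for c in donor_calls
            if c.klass == "donor_like" and c.contig_id == contig.id
        ]
        f.distance_to_nearest_donor_call = min(dists) if dists else None
    feats.sort(key=lambda f: f.start)
    return feats


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _is_low_complexity(kmer: str) -> bool:
    return len(set(kmer)) <= 2


def find_inverted_repeats(
    contig: Contig,
    min_arm: int = 30,
    max_span: int = 5000,
    min_arm_identity: float = 75.0,
    seed_k: int = 12,
    xdrop: int = 6,
) -> list[SequenceFeature]:
    """Inverted repeats: two arms where the second reverse-complement-matches
    the first.

    Search is by reverse-complement k-mer seeding (low-complexity seeds are
    skipped) followed by gapless paired extension with an X-drop bound and
    trimming back to the best-scoring extent. Arms must be at least
    ``min_arm`` bp, non-overlapping, span at most ``max_span`` bp outer edge
    to outer edge, and match at ``min_arm_identity`` percent or better.
    """
    seq = sanitize_dna(contig.sequence)
    L = len(seq)
    if L < 2 * seed_k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(L - seed_k + 1):
        k = seq[i:i + seed_k]
        if "N" in k or _is_low_complexity(k):
            continue
        index.setdefault(k, []).append(i)

    def comp_match(p: int, q: int) -> bool:
        a, b = seq[p], seq[q]
        return a in "ACGT" and b == a.translate(_COMPLEMENT)

    candidates = []
    seen_seeds: set[tuple[int, int]] = set()
    for j in range(L - seed_k + 1):
        km = seq[j:j + seed_k]
        if "N" in km or _is_low_complexity(km):
            continue
        rc = reverse_complement(km)
        for i in index.get(rc, ()):
            if i + seed_k > j or (j + seed_k) - i > max_span:
                continue
            if (i, j) in seen_seeds:
                continue
            # palindromic correspondence: p on arm1 pairs with c - p on arm2
            c = i + j + seed_k - 1
            # outward extension (left of arm1 start, right of arm2 end)
            def extend(p0: int, step: int) -> int:
                best, ext = 0, 0
                score = 0
                p = p0
                while 0 <= p < L and 0 <= c - p < L:
                    if step > 0 and p >= c - p:   # arms may not cross
                        break
                    score += 1 if comp_match(p, c - p) else -2
                    if score > best:
                        best, ext = score, abs(p - p0) + 1
                    if score < best - xdrop:
                        break
                    p += step
                return ext
            out_ext = extend(i - 1, -1)
            in_ext = extend(i + seed_k, +1)
            a1s = i - out_ext
            a1e = i + seed_k + in_ext
            arm_len = a1e - a1s
            a2s, a2e = c - a1e + 1, c - a1s + 1
            if arm_len < min_arm or a1e > a2s or a2e - a1s > max_span:
                continue
            matches = sum(1 for p in range(a1s, a1e) if comp_match(p, c - p))
            identity = 100.0 * matches / arm_len
            if identity < min_arm_identity:
                continue
            for p in range(a1s, a1e - seed_k + 1):
                seen_seeds.add((p, c - p - seed_k + 1))
            candidates.append(
                SequenceFeature(
                    kind="inverted_repeat", start=a1s, end=a1e,
                    arm2_start=a2s, arm2_end=a2e, arm_identity=identity,
                )
            )
    # keep the longest non-redundant structures
    candidates.sort(key=lambda f: (-(f.end - f.start), f.start))
    kept: list[SequenceFeature] = []
    for f in candidates:
        redundant = any(
            min(f.end, g.end) > max(f.start, g.start)
            and min(f.arm2_end, g.arm2_end) > max(f.arm2_start, g.arm2_start)
            for g in kept
        )
        if not redundant:
            kept.append(f)
    kept.sort(key=lambda f: f.start)
    return kept
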