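"""Run-level summaries, circular donor-genome tick mapping, cross-species
shared-homolog counts, the genome-coverage estimate, and the end-to-end
pipeline driver.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import reference_data
from .cog_enrichment import count_categories, enrichment_screen
from .homology_screen import HomologCall, screen_with_rescue, tally_best_hit_taxa
from .insert_annotation import (
    JunctionStatus,
    PseudogeneAnnotation,
    annotate_orf_integrity,
    find_inverted_repeats,
    find_junction_fragments,
    scan_polyA,
)
from .sequence_io import Contig, Gff3Record, write_fasta, write_gff3
from .synthetic_data import (
    DonorPanel,
    InsertionTruthRecord,
    SimulationConfig,
    build_host_genome,
    generate_donor_panel,
    generate_host_panel,
    plant_insertions,
    read_donor_panel_json,
    read_host_panel,
    shred,
    write_donor_panel_json,
    write_host_panel,
    write_truth_gff3,
)
from .util import round_half_up


@dataclass
class RunSummary:
    n_fragments_with_donor_seq: int
    n_donor_homologs: int
    mean_percent_identity: float
    sd_percent_identity: float
    mean_alignment_length: float
    sd_alignment_length: float
    n_junction_fragments: int
    n_internal: int
    n_end_truncated: int
    n_intact_orf: int
    n_filarial_best_hits: int
    n_arthropod_best_hits: int
    percent_filarial_best_hits: int


@dataclass(frozen=True)
class CircularMapTick:
    locus_tag: str
    midpoint: int


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    if not values:
        return 0.0, 0.0
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd


def summarize_run(
    calls: Sequence[HomologCall],
    annotations: Sequence[PseudogeneAnnotation] = (),
    junctions: Sequence[JunctionStatus] = (),
) -> RunSummary:
    """Headline statistics of a screening run (per-species table row)."""
    donor = [c for c in calls if c.klass == "donor_like"]
    mean_id, sd_id = _mean_sd([c.percent_identity for c in donor])
    mean_len, sd_len = _mean_sd([float(c.alignment_length) for c in donor])
    filarial, arthropod, pct = tally_best_hit_taxa(donor)
    n_internal = sum(1 for a in annotations if a.is_internal)
    return RunSummary(
        n_fragments_with_donor_seq=len({c.contig_id for c in donor}),
        n_donor_homologs=len(donor),
        mean_percent_identity=mean_id,
        sd_percent_identity=sd_id,
        mean_alignment_length=mean_len,
        sd_alignment_length=sd_len,
        n_junction_fragments=sum(1 for j in junctions if j.is_junction),
        n_internal=n_internal,
        n_end_truncated=len(annotations) - n_internal,
        n_intact_orf=sum(1 for a in annotations if a.is_intact_orf),
        n_filarial_best_hits=filarial,
        n_arthropod_best_hits=arthropod,
        percent_filarial_best_hits=pct,
    )


def estimate_coverage(
    assembled_bp: float, genome_size_bp: float, repeat_fraction: float
) -> int:
    """Percent of the non-repetitive genome covered by assembled sequence,
    rounded to an integer and capped at 100."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if not 0.0 <= repeat_fraction < 1.0:
        raise ValueError("repeat fraction must be in [0, 1)")
    if assembled_bp < 0:
        raise ValueError("assembled bp must be non-negative")
    frac = assembled_bp / (genome_size_bp * (1.0 - repeat_fraction))
    return min(100, round_half_up(100.0 * frac))


def circular_ticks(
    calls: Sequence[HomologCall], donor_panel: DonorPanel
) -> list[CircularMapTick]:
    """One tick per distinct best donor locus at the midpoint of its
    (possibly origin-wrapping) interval on the circular donor genome."""
    L = donor_panel.genome_length
    ticks = {}
    for c in calls:
        if c.klass != "donor_like" or c.best_locus_tag in ticks:
            continue
        gene = donor_panel.get(c.best_locus_tag)
        ticks[c.best_locus_tag] = CircularMapTick(
            locus_tag=c.best_locus_tag,
            midpoint=((gene.start + gene.end) // 2) % L,
        )
    return sorted(ticks.values(), key=lambda t: t.midpoint)


def shared_homolog_matrix(
    species_loci: Mapping[str, Iterable[str]]
) -> dict[tuple[str, ...], int]:
    """Exact intersection counts of donor loci for every species subset."""
    from itertools import combinations

    if len(species_loci) < 2:
        raise ValueError("need at least two species")
    sets = {sp: set(loci) for sp, loci in species_loci.items()}
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[s] for s in combo))
            out[combo] = len(inter)
    return out


def published_species_locus_sets() -> dict[str, set[str]]:
    """DNA-level shared-homolog presence sets from the published table."""
    sets: dict[str, set[str]] = {
        reference_data.AV: set(),
        reference_data.OF: set(),
        reference_data.BM: set(),
    }
    for locus, species in reference_data.SHARED_HOMOLOG_DNA_PRESENCE.items():
        for sp in species:
            sets[sp].add(locus)
    return sets


# ---------------------------------------------------------------------------
# truth comparison and pipeline driver

@dataclass
class TruthComparison:
    n_planted: int
    n_recovered: int
    n_donor_calls: int
    n_true_positive_calls: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 0.0

    @property
    def precision(self) -> float:
        return (
            self.n_true_positive_calls / self.n_donor_calls
            if self.n_donor_calls else 0.0
        )


def compare_to_truth(
    truth: Sequence[InsertionTruthRecord],
    calls: Sequence[HomologCall],
    contig_intervals: Mapping[str, tuple[int, int]],
) -> TruthComparison:
    """Recall/precision of donor-like calls against the planted truth table.

    A planted insert is recovered when any donor-like call overlaps its
    fragment in composite coordinates; a donor-like call is a true positive
    when it overlaps any planted fragment.
    """
    donor_calls = [c for c in calls if c.klass == "donor_like"]
    call_ivs = []
    for c in donor_calls:
        cs, _ = contig_intervals[c.contig_id]
        call_ivs.append((cs + c.start, cs + c.end))
    recovered = 0
    for rec in truth:
        if any(
            min(rec.fragment_end, e) > max(rec.fragment_start, s)
            for s, e in call_ivs
        ):
            recovered += 1
    true_pos = sum(
        1 for s, e in call_ivs
        if any(
            min(rec.fragment_end, e) > max(rec.fragment_start, s)
            for rec in truth
        )
    )
    return TruthComparison(
        n_planted=len(truth),
        n_recovered=recovered,
        n_donor_calls=len(donor_calls),
        n_true_positive_calls=true_pos,
    )


def calls_to_frame(calls: Sequence[HomologCall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in calls])


def pipeline_run(
    cfg: SimulationConfig,
    outdir: str | Path,
    n_donor_genes: int = 24,
    donor_genome_length: int = 60_000,
    n_host_genes: int = 8,
    threshold: float = 1e-5,
) -> dict:
    """Simulate, screen, annotate, test enrichment, and report.

    Every stage's output is written under ``outdir`` and listed in a
    manifest; the run is deterministic given ``cfg.seed``.
    """
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng([cfg.seed, 10])
    donor_panel = generate_donor_panel(n_donor_genes, donor_genome_length, rng=rng)
    host_panel = generate_host_panel(n_host_genes, rng=rng)
    host_genome, _ = build_host_genome(cfg.host_genome_length, host_panel, rng)

    composite, truth = plant_insertions(host_genome, donor_panel, cfg)
    shredded = shred(composite, cfg)
    contigs = shredded.contigs

    calls = screen_with_rescue(contigs, donor_panel, host_panel, threshold)
    junctions = find_junction_fragments(calls)
    contig_by_id = {c.id: c for c in contigs}
    annotations = []
    features = []
    for call in calls:
        if call.klass != "donor_like":
            continue
        contig = contig_by_id[call.contig_id]
        cds = donor_panel.get(call.best_locus_tag).cds
        annotations.append(annotate_orf_integrity(call, contig, cds))
    for contig in contigs:
        donor_here = [c for c in calls if c.contig_id == contig.id]
        for f in scan_polyA(contig, donor_calls=donor_here):
            features.append((contig.id, f))
        for f in find_inverted_repeats(contig):
            features.append((contig.id, f))

    counts = count_categories(calls, donor_panel)
    spectrum = {}
    for g in donor_panel.genes:
        spectrum[g.cog_category] = spectrum.get(g.cog_category, 0) + 1
    n_donor_calls = sum(counts.values())
    enrichment = enrichment_screen(
        counts, n_donor_calls, spectrum, len(donor_panel.genes)
    )
    summary = summarize_run(calls, annotations, junctions)
    ticks = circular_ticks(calls, donor_panel)
    comparison = compare_to_truth(truth, calls, shredded.intervals)

    # outputs
    paths = {}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        paths[name] = str(path)

    _write("donor_panel.json", lambda p: write_donor_panel_json(donor_panel, p))
    _write("host_panel.fasta", lambda p: write_host_panel(host_panel, p))
    _write("composite.fasta", lambda p: write_fasta(
        [Contig("composite", composite)], p))
    _write("contigs.fasta", lambda p: write_fasta(contigs, p))
    _write("truth.gff3", lambda p: write_truth_gff3(truth, p))
    _write("calls.tsv", lambda p: calls_to_frame(calls).to_csv(p, sep="\t", index=False))
    _write("annotations.tsv", lambda p: pd.DataFrame(
        [dict(asdict(a), is_intact_orf=a.is_intact_orf) for a in annotations]
    ).to_csv(p, sep="\t", index=False))
    _write("enrichment.tsv", lambda p: pd.DataFrame(
        [asdict(e) for e in enrichment]).to_csv(p, sep="\t", index=False))
    _write("features.gff3", lambda p: write_gff3(
        [
            Gff3Record(
                seqid=cid, source="nuwtscan", type=f.kind,
                start=f.start, end=f.end, strand=f.strand,
                attributes={
                    k: str(v) for k, v in (
                        ("tract_length", f.tract_length),
                        ("arm2_start", f.arm2_start),
                        ("arm2_end", f.arm2_end),
                        ("arm_identity", f.arm_identity),
                        ("distance_to_donor", f.distance_to_nearest_donor_call),
                    ) if v is not None
                },
            )
            for cid, f in features
        ], p))
    _write("summary.json", lambda p: Path(p).write_text(
        json.dumps(asdict(summary), indent=2)))
    _write("ticks.tsv", lambda p: pd.DataFrame(
        [asdict(t) for t in ticks]).to_csv(p, sep="\t", index=False))
    _write("truth_comparison.json", lambda p: Path(p).write_text(json.dumps({
        "n_planted": comparison.n_planted,
        "n_recovered": comparison.n_recovered,
        "n_donor_calls": comparison.n_donor_calls,
        "n_true_positive_calls": comparison.n_true_positive_calls,
        "recall": comparison.recall,
        "precision": comparison.precision,
    }, indent=2)))

    manifest = {
        "seed": cfg.seed,
        "n_contigs": len(contigs),
        "n_calls": len(calls),
        "n_donor_calls": sum(1 for c in calls if c.klass == "donor_like"),
        "outputs": paths,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_run_panels(run_dir: str | Path):
    """Reload the donor and host panels written by :func:`pipeline_run`."""
    run_dir = Path(run_dir)
    donor = read_donor_panel_json(run_dir / "donor_panel.json")
    host = read_host_panel(run_dir / "host_panel.fasta")
    return donor, host
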