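import re

import numpy as np
import pytest

from nuwtscan.reference_data import WBM_COG_SPECTRUM, WBM_TOTAL_LOCI
from nuwtscan.sequence_io import split_paired_end_read, PairedEndRead
from nuwtscan.synthetic_data import (
    PanelPlacementError,
    SimulationConfig,
    alignment_identity,
    build_host_genome,
    generate_donor_panel,
    generate_host_panel,
    map_truth_to_contigs,
    mutate_fragment,
    plant_insertions,
    read_truth_gff3,
    replay_alignment,
    shred,
    shred_paired_end,
    truth_orf_status,
    write_truth_gff3,
    STOP_CODONS,
)


class TestDonorPanel:
    def test_single_gene_panel(self):
        panel = generate_donor_panel(1, 2000, seed=1)
        (gene,) = panel.genes
        assert gene.cog_category in WBM_COG_SPECTRUM
        internal = [gene.cds[i:i + 3] for i in range(0, len(gene.cds) - 3, 3)]
        assert not any(c in STOP_CODONS for c in internal)
        assert gene.cds[-3:] in STOP_CODONS

    def test_same_seed_reproduces_panel(self):
        a = generate_donor_panel(15, 30000, seed=42)
        b = generate_donor_panel(15, 30000, seed=42)
        assert a == b

    def test_category_frequencies_follow_spectrum(self):
        # Translation is 121/805 = 15.0% of the donor spectrum
        panel = generate_donor_panel(200, 400000, seed=5)
        freq = sum(
            g.cog_category == "Translation" for g in panel.genes
        ) / len(panel.genes)
        assert abs(freq - 121 / WBM_TOTAL_LOCI) < 0.05

    def test_genes_non_overlapping_on_circle(self):
        panel = generate_donor_panel(20, 30000, seed=9)
        L = panel.genome_length
        covered = np.zeros(L, dtype=int)
        for g in panel.genes:
            for pos in range(g.start, g.end):
                covered[pos % L] += 1
        assert covered.max() <= 1

    def test_genome_too_small_raises(self):
        with pytest.raises(PanelPlacementError):
            generate_donor_panel(10, 1000, seed=0)


class TestMutateFragment:
    def test_zero_rate_is_identity(self):
        seq = "ACGTACGTAC"
        out, events = mutate_fragment(seq, 0.0, seed=0)
        assert out == seq and events == []

    def test_realized_identity_matches_rate(self):
        # substitutions never recreate the original base, so identity
        # converges to 1 - rate
        ids = []
        rng = np.random.default_rng(77)
        base = "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, 10000)])
        for s in range(200):
            out, events = mutate_fragment(base, 0.2, seed=s)
            og, mg = replay_alignment(base, events)
            ids.append(alignment_identity(og, mg))
        assert abs(np.mean(ids) - 80.0) < 1.0

    def test_single_insertion_forces_frame_break(self):
        seq = "ACGT" * 30
        out, events = mutate_fragment(seq, 0.0, [("insertion", 50, 1)], seed=3)
        assert len(out) - len(seq) == 1
        ev = [e for e in events if e.type == "insertion"]
        assert len(ev) == 1 and len(ev[0].detail) % 3 == 1

    def test_events_describe_edit_script_exactly(self):
        seq = "ACGT" * 25
        out, events = mutate_fragment(
            seq, 0.1, [("deletion", 10, 4), ("insertion", 40, "GGG")], seed=11
        )
        og, mg = replay_alignment(seq, events)
        assert og.replace("-", "") == seq
        assert mg.replace("-", "") == out

    def test_indel_offset_outside_sequence_raises(self):
        with pytest.raises(ValueError):
            mutate_fragment("ACGTACGT", 0.0, [("deletion", 6, 5)], seed=0)

    def test_substitution_never_recreates_base(self):
        out, events = mutate_fragment("A" * 2000, 0.5, seed=2)
        for e in events:
            old, new = e.detail.split(">")
            assert old == "A" and new != "A"


@pytest.fixture(scope="module")
def planted(small_donor_panel):
    cfg = SimulationConfig(seed=13, n_inserts=12, host_genome_length=60000)
    rng = np.random.default_rng(99)
    host, _ = build_host_genome(
        cfg.host_genome_length, generate_host_panel(3, rng=rng), rng
    )
    composite, truth = plant_insertions(host, small_donor_panel, cfg)
    return host, composite, truth


class TestPlantInsertions:
    def test_zero_inserts_leaves_host_unchanged(self, small_donor_panel):
        cfg = SimulationConfig(seed=1, n_inserts=0)
        composite, truth = plant_insertions("ACGT" * 1000, small_donor_panel, cfg)
        assert composite == "ACGT" * 1000 and truth == []

    def test_length_conservation(self, planted):
        host, composite, truth = planted
        added = sum(r.block_end - r.block_start for r in truth)
        assert len(composite) == len(host) + added

    def test_truth_records_reconstruct_fragments(self, planted, small_donor_panel):
        host, composite, truth = planted
        for rec in truth:
            assert composite[rec.fragment_start:rec.fragment_end] == rec.fragment_sequence
            gene = small_donor_panel.get(rec.donor_locus_tag)
            fragment = gene.cds[rec.donor_start:rec.donor_end]
            og, mg = replay_alignment(fragment, rec.applied_events)
            assert alignment_identity(og, mg) == pytest.approx(rec.percent_identity)

    def test_planted_polyA_redetectable(self, small_donor_panel):
        cfg = SimulationConfig(
            seed=5, n_inserts=6, host_genome_length=40000,
            polyA_prob=1.0, polyA_length_min=25, polyA_length_max=25,
        )
        rng = np.random.default_rng(6)
        host, _ = build_host_genome(40000, generate_host_panel(2, rng=rng), rng)
        composite, truth = plant_insertions(host, small_donor_panel, cfg)
        for rec in truth:
            assert rec.has_polyA and rec.polyA_tract_length == 25
            window = composite[rec.fragment_end:rec.block_end + 1]
            assert re.search("A{21,}", window)

    def test_inverted_repeat_flanks_are_reverse_complements(self, small_donor_panel):
        from nuwtscan.sequence_io import reverse_complement

        cfg = SimulationConfig(
            seed=8, n_inserts=5, host_genome_length=40000,
            ir_prob=1.0, polyA_prob=0.0, ir_arm_length=40,
        )
        rng = np.random.default_rng(3)
        host, _ = build_host_genome(40000, generate_host_panel(2, rng=rng), rng)
        composite, truth = plant_insertions(host, small_donor_panel, cfg)
        for rec in truth:
            assert rec.has_inverted_repeat
            left = composite[rec.block_start:rec.block_start + 40]
            right = composite[rec.block_end - 40:rec.block_end]
            assert right == reverse_complement(left)

    def test_deterministic_given_config(self, small_donor_panel):
        cfg = SimulationConfig(seed=21, n_inserts=8, host_genome_length=50000)
        host = "ACGT" * 12500
        a = plant_insertions(host, small_donor_panel, cfg)
        b = plant_insertions(host, small_donor_panel, cfg)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_truth_gff3_round_trip(self, planted, tmp_path):
        _, _, truth = planted
        path = tmp_path / "truth.gff3"
        write_truth_gff3(truth, path)
        assert read_truth_gff3(path) == truth

    def test_truth_orf_status_reflects_planted_events(self, planted, small_donor_panel):
        _, _, truth = planted
        for rec in truth:
            status = truth_orf_status(rec, small_donor_panel)
            n_indel = sum(
                1 for e in rec.applied_events
                if e.type in ("insertion", "deletion") and len(e.detail) % 3
            )
            assert status.frameshift_count >= n_indel
            assert status.premature_stop_count >= 0
            if not rec.applied_events:
                assert status.is_intact

    def test_truth_orf_status_sees_planted_stop(self, small_donor_panel):
        from nuwtscan.synthetic_data import InsertionTruthRecord

        gene = small_donor_panel.genes[0]
        # fragment aligned to the CDS start: in-frame codon 30 becomes TAA
        _, events = mutate_fragment(
            gene.cds[:150], 0.0, [("nonsense", 30, "TAA")], seed=0
        )
        rec = InsertionTruthRecord(
            insert_id="x", host_coordinate=0,
            donor_locus_tag=gene.locus_tag, donor_start=0, donor_end=150,
            strand="+", applied_events=events,
        )
        status = truth_orf_status(rec, small_donor_panel)
        assert status.premature_stop_count == 1
        assert status.frameshift_count == 0


class TestShred:
    def test_contigs_tile_composite(self, rng):
        from conftest import random_dna

        cfg = SimulationConfig(seed=4)
        genome = random_dna(rng, 50000)
        result = shred(genome, cfg)
        assert "".join(c.sequence for c in result.contigs) == genome
        for cid, (s, e) in result.intervals.items():
            assert genome[s:e] == next(
                c.sequence for c in result.contigs if c.id == cid
            )

    def test_realized_mean_length_near_target(self, rng):
        from conftest import random_dna

        cfg = SimulationConfig(seed=4, contig_length_mean=900.0)
        genome = random_dna(rng, 300000)
        result = shred(genome, cfg)
        lengths = [c.length for c in result.contigs]
        assert abs(np.mean(lengths) - 900) < 90  # within 10%

    def test_truth_maps_to_spanning_contig(self, small_donor_panel, rng):
        from conftest import random_dna

        cfg = SimulationConfig(seed=17, n_inserts=5, host_genome_length=40000)
        host = random_dna(rng, 40000)
        composite, truth = plant_insertions(host, small_donor_panel, cfg)
        result = shred(composite, cfg)
        mapping = map_truth_to_contigs(truth, result.intervals)
        for rec in truth:
            assert mapping[rec.insert_id], "every insert lies on some contig"
            total = sum(e - s for _, s, e in mapping[rec.insert_id])
            assert total == rec.fragment_end - rec.fragment_start

    def test_paired_end_round_trip(self, rng):
        from conftest import random_dna

        cfg = SimulationConfig(seed=30)
        genome = random_dna(rng, 200000)
        reads, mates = shred_paired_end(genome, cfg, n_reads=200)
        for read in reads:
            result = split_paired_end_read(read)
            assert result.split
            m1, m2 = mates[read.id]
            assert result.records[0].sequence == m1.sequence
            assert result.records[1].sequence == m2.sequence
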