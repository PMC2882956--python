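import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nuwtscan.homology_screen import (
    DNA_SCHEME,
    HomologCall,
    ScoringScheme,
    align_local,
    bitscore,
    evalue,
    min_score_for_evalue,
    screen_contigs,
    screen_with_rescue,
    split_and_rescan,
    tally_best_hit_taxa,
    translated_hits,
    translated_screen,
    count_frame_changes,
)
from nuwtscan.sequence_io import Contig, reverse_complement
from nuwtscan.synthetic_data import DonorGene, DonorPanel, HostGene, generate_donor_panel

from conftest import mutate_uniform, random_dna
from oracles import sw_affine_score

DNA = st.text(alphabet="ACGT", min_size=8, max_size=40)


class TestAlignLocal:
    def test_identical_sequences_score_full_length(self, rng):
        seq = random_dna(rng, 50)
        (hit, *_) = align_local(seq, seq)
        assert hit.raw_score == 50
        assert hit.percent_identity == 100.0
        assert hit.strand == "+"
        assert (hit.query_start, hit.query_end) == (0, 50)

    def test_reverse_complement_found_on_minus_strand(self, rng):
        subject = random_dna(rng, 60)
        query = reverse_complement(subject)
        hits = align_local(query, subject)
        assert hits[0].strand == "-"
        assert hits[0].percent_identity == 100.0

    def test_small_example_matches_dp_oracle(self):
        q, s = "ACGTACGTTT", "ACGAACGTTT"
        hits = align_local(q, s, both_strands=False, min_score=1)
        assert hits[0].raw_score == sw_affine_score(q, s)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(DNA, DNA)
    def test_best_score_equals_dp_oracle(self, q, s):
        expected = max(sw_affine_score(q, s), sw_affine_score(reverse_complement(q), s))
        hits = align_local(q, s, min_score=1)
        got = hits[0].raw_score if hits else 0.0
        assert got == expected

    def test_suboptimal_hits_found_by_masking(self, rng):
        block = random_dna(rng, 60)
        query = block + random_dna(rng, 100) + block
        hits = align_local(query, block, min_score=30, max_hits=4)
        starts = sorted((h.query_start, h.query_end) for h in hits)
        assert starts == [(0, 60), (160, 220)]

    def test_n_bases_never_count_as_matches(self):
        # the N column aligns (gaps are costlier) but is not a match
        (hit, *_) = align_local("AAAANAAAA", "AAAANAAAA", min_score=1)
        assert (hit.query_start, hit.query_end) == (0, 9)
        assert hit.n_matches == 8
        assert hit.percent_identity == pytest.approx(100 * 8 / 9)


class TestEvalue:
    def test_linear_in_database_length(self):
        assert evalue(30, 300, 2000) * 2 == pytest.approx(evalue(30, 300, 4000))

    def test_score_increase_shrinks_exponentially(self):
        scheme = ScoringScheme(lam=1.37)
        ratio = evalue(20, 100, 1000, scheme) / evalue(30, 100, 1000, scheme)
        assert ratio == pytest.approx(math.exp(13.7))

    def test_closed_form_value(self):
        # independent evaluation of E = K m n exp(-lambda S)
        expected = 0.711 * 300 * 2e5 * math.exp(-1.372 * 30)
        assert evalue(30, 300, 200000) == pytest.approx(expected)

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, 500, 10000) for s in range(10, 60, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_nonpositive_lengths_raise(self):
        with pytest.raises(ValueError):
            evalue(30, 0, 100)
        with pytest.raises(ValueError):
            evalue(30, 100, -1)

    def test_min_score_threshold_consistency(self):
        s = min_score_for_evalue(1e-5, 900, 20000)
        assert evalue(s + 0.01, 900, 20000) < 1e-5 < evalue(s - 0.01, 900, 20000)

    def test_bitscore_increasing(self):
        assert bitscore(40) > bitscore(30)


class TestSplitAndRescan:
    @pytest.mark.parametrize(
        "length,expected",
        [(600, [600]), (601, [301, 300]), (1500, [500, 500, 500]),
         (300, [300]), (1201, [401, 400, 400])],
    )
    def test_piece_lengths(self, length, expected):
        contig = Contig("c", "A" * length)
        pieces = split_and_rescan(contig)
        assert [p.length for p, _ in pieces] == expected

    def test_concatenation_reconstructs_contig(self, rng):
        contig = Contig("c", random_dna(rng, 2777))
        pieces = split_and_rescan(contig)
        assert "".join(p.sequence for p, _ in pieces) == contig.sequence
        offs = [off for _, off in pieces]
        assert offs == sorted(offs) and offs[0] == 0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(min_value=601, max_value=20000))
    def test_pieces_always_within_bounds(self, length):
        pieces = split_and_rescan(Contig("c", "A" * length))
        assert sum(p.length for p, _ in pieces) == length
        assert all(300 <= p.length <= 600 for p, _ in pieces)


@pytest.fixture(scope="module")
def screen_setup():
    rng = np.random.default_rng(314)
    panel = generate_donor_panel(8, 15000, seed=314)
    host_panel = [HostGene("HOST_0", random_dna(rng, 800))]

    def fresh_rng():
        return np.random.default_rng(2718)

    return fresh_rng, panel, host_panel


class TestScreen:
    def test_host_only_contig_yields_no_donor_calls(self, screen_setup):
        fresh_rng, panel, host_panel = screen_setup
        rng = fresh_rng()
        contig = Contig("h1", random_dna(rng, 900))
        calls = screen_contigs([contig], panel, host_panel)
        assert not [c for c in calls if c.klass == "donor_like"]

    def test_planted_fragment_called_with_accurate_region(self, screen_setup):
        fresh_rng, panel, host_panel = screen_setup
        rng = fresh_rng()
        gene = panel.genes[2]
        fragment = mutate_uniform(gene.cds[30:330], 0.2, rng)
        contig = Contig("p1", random_dna(rng, 300) + fragment + random_dna(rng, 300))
        calls = [
            c for c in screen_contigs([contig], panel, host_panel)
            if c.klass == "donor_like"
        ]
        assert len(calls) == 1
        call = calls[0]
        assert call.best_locus_tag == gene.locus_tag
        inter = min(call.end, 600) - max(call.start, 300)
        union = max(call.end, 600) - min(call.start, 300)
        assert inter / union >= 0.5

    def test_junction_contig_gets_both_calls(self, screen_setup):
        fresh_rng, panel, host_panel = screen_setup
        rng = fresh_rng()
        gene = panel.genes[0]
        fragment = mutate_uniform(gene.cds[:250], 0.2, rng)
        contig = Contig(
            "j1",
            host_panel[0].sequence + random_dna(rng, 120) + fragment,
        )
        kinds = {c.klass for c in screen_contigs([contig], panel, host_panel)}
        assert kinds == {"donor_like", "host_like"}

    def test_strong_host_hit_shadows_donor_until_split(self):
        # a contig covered end-to-end by a strong host-gene alignment hides
        # the weaker endosymbiont fragment; the splitting pass recovers it
        rng = np.random.default_rng(11)
        panel = generate_donor_panel(1, 5000, seed=3, min_codons=150, max_codons=200)
        gene = panel.genes[0]
        planted = mutate_uniform(gene.cds[60:360], 0.05, rng)
        contig_seq = random_dna(rng, 450) + planted + random_dna(rng, 150)
        host_panel = [HostGene("HOST_sim", mutate_uniform(contig_seq, 0.15, rng))]
        contig = Contig("c1", contig_seq)

        base = screen_contigs([contig], panel, host_panel)
        assert not [c for c in base if c.klass == "donor_like"]
        rescued = screen_with_rescue([contig], panel, host_panel)
        donor = [c for c in rescued if c.klass == "donor_like"]
        assert len(donor) == 1 and donor[0].rescued
        assert donor[0].best_locus_tag == gene.locus_tag


class TestTranslatedScreen:
    def test_exact_fragment_hits_in_correct_frame(self, screen_setup):
        fresh_rng, panel, _ = screen_setup
        rng = fresh_rng()
        gene = panel.genes[1]
        # place at an offset congruent to 1 (mod 3): frame +2
        contig = Contig("t1", random_dna(rng, 199) + gene.cds[:300] + random_dna(rng, 200))
        calls = translated_screen(contig, panel.protein_panel())
        assert calls
        best = max(calls, key=lambda c: c.bitscore)
        assert best.best_locus_tag == gene.locus_tag
        assert best.frame == 2
        # local extension may pick up a few chance residues past the fragment
        assert best.percent_identity > 90.0
        assert best.start <= 199 and best.end >= 499

    def test_planted_frameshift_chains_hsps_across_frames(self, screen_setup):
        fresh_rng, panel, _ = screen_setup
        rng = fresh_rng()
        gene = panel.genes[1]
        frag = gene.cds[:300]
        shifted = frag[:150] + "G" + frag[150:]
        contig = Contig("t2", random_dna(rng, 198) + shifted + random_dna(rng, 200))
        hits = [
            h for h in translated_hits(contig, panel.protein_panel())
            if h.subject_id == gene.locus_tag
        ]
        assert len({h.frame for h in hits}) >= 2
        assert count_frame_changes(hits) >= 1

    def test_random_sequence_rarely_hits(self, screen_setup):
        _, panel, _ = screen_setup
        n_hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            contig = Contig(f"r{seed}", random_dna(r, 400))
            n_hits += len(translated_screen(contig, panel.protein_panel()))
        assert n_hits == 0


class TestTaxonTally:
    def _calls(self, n_fil, n_arth):
        mk = lambda i, t: HomologCall(
            f"c{i}", 0, 100, "donor_like", f"L{i}", t, 80.0, 100, 1e-9, 50.0, "+"
        )
        return [mk(i, "filarial") for i in range(n_fil)] + [
            mk(1000 + i, "arthropod") for i in range(n_arth)
        ]

    def test_published_proportions_round_correctly(self):
        assert tally_best_hit_taxa(self._calls(19, 30)) == (19, 30, 39)
        assert tally_best_hit_taxa(self._calls(47, 67)) == (47, 67, 41)

    def test_empty_and_zero_cases(self):
        assert tally_best_hit_taxa([]) == (0, 0, 0)
        assert tally_best_hit_taxa(self._calls(0, 12)) == (0, 12, 0)
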