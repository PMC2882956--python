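# Methods

## The problem and the model

An intracellular endosymbiont that lives in its host's germline can leave
DNA in the host's nuclear genome. Long after the symbiont itself is lost,
those inserts remain detectable as degenerate, fragmented copies of donor
genes. The screen implemented here takes assembled nuclear contigs, a
compact panel of donor coding sequences and a panel of host genes, and asks
three questions: which regions are endosymbiont-derived, how degraded are
they, and is any functional class of donor gene over- or under-represented
among them.

Because the real positives in this regime sit around 80% nucleotide
identity in fragments of one to a few hundred bp, every component is
validated on synthetic composite genomes in which the ground truth is known
exactly.

## Homology screen

**Alignment.** Exact affine-gap Smith–Waterman local alignment (executed by
Biopython's `PairwiseAligner` in local mode) over both strands. Nucleotide
scoring is +1 match, −3 mismatch, with a gap of length *g* costing
5 + 2·*g* — classic nucleotide-search defaults that strongly favor
high-identity segments. Ambiguous bases (anything outside ACGT) are read as
N and never count as matches. Suboptimal HSPs are recovered by masking the
query span of each reported hit with a sentinel character and re-aligning,
up to 4 HSPs per sequence pair. A prefilter skips pairs that share fewer
than two distinct 11-mers (either strand); any alignment capable of
clearing the significance cutoff shares many, so this costs essentially no
sensitivity while avoiding almost all full alignments of unrelated pairs.

**Statistics.** E = K·m·n·e^(−λS) with the ungapped nucleotide parameters
K = 0.711, λ = 1.372 applied to gapped scores — a documented approximation,
configurable in `ScoringScheme`. The effective database length *n* is the
total panel length; *m* is the contig length. Absolute E-values therefore
depend on panel size and are not comparable across databases; only the
thresholding logic (E < 10⁻⁵, the cutoff used for every search mode) is
meaningful, and that is what the tests pin down.

**Classification.** All above-threshold hits on a contig are merged
(same-subject, same-strand HSPs within 30 bp on the query chain into one
hit) and grouped into connected components of overlapping query intervals.
The top hit of each component — by bitscore, then lower E-value, then
lexicographic locus tag for determinism — decides the region's class:
`donor_like` only if it is a donor locus below threshold. This makes
junction fragments (one contig with both donor-like and host-like regions)
first-class results, and it reproduces the failure mode the splitting pass
exists for: a host-gene alignment spanning the whole contig suppresses a
weaker donor fragment inside it.

**Splitting rescue.** Contigs longer than 600 bp are re-screened as
⌈L/600⌉ contiguous pieces whose lengths differ by at most 1; every piece
then lies in [300, 600] bp and the pieces concatenate back to the contig.
Donor-like calls found only in pieces are mapped back to contig coordinates
and flagged `rescued`.

**Translated mode.** All six reading frames are translated and searched
against the donor protein panel with BLOSUM62, gap open 11 / extend 1 and
the gapped protein parameters K = 0.041, λ = 0.267. Hits carry their frame;
frame changes between chained HSPs to the same protein are the
protein-level frameshift signal used by the annotation layer.

## Insert annotation

* **ORF integrity** compares the called region (oriented by call strand) to
  its donor CDS. The comparison alignment uses a milder scheme
  (+1/−1, gaps 2 + 1·*g*) than the screen: at ~80% identity the screening
  scheme trims to the best-conserved stretch, whereas the ORF verdict needs
  the full extent of the fragment. Frameshifts are indels whose length is
  not divisible by three (plus frame changes between translated HSP chains
  when supplied); premature stops are stop codons read in the donor CDS
  frame at complete, ungapped codons, strictly before the last aligned
  codon — so a fragment that ends at the gene's own terminal stop is not
  penalized. No start codon is required. On 100 simulated degenerate
  inserts this classification agrees with the edit-script ground truth for
  ≥95% of inserts (the acceptance suite recomputes this); the residual
  disagreements are frameshifts within a few bases of a fragment end, which
  a local alignment can always absorb into the unaligned margin.
* **Truncation.** A region is internal when both ends are more than 25 bp
  from the contig ends; otherwise its true extent is unknowable and it is
  reported end-truncated. The rule is applied to both ends.
* **Poly(A) tracts** are exact maximal homopolymer runs of at least 21 nt
  (">20 bases"), on both strands (T runs are minus-strand tracts). One
  interrupting base ends a run. The distance to the nearest donor-like call
  is reported as a distance, never used as a filter.
* **Inverted repeats** are found by reverse-complement 12-mer seeding
  (low-complexity seeds skipped), gapless paired extension under an X-drop
  of 6 with trim-back to the best-scoring extent, then redundancy removal
  keeping the longest structures. Defaults — arms ≥ 30 bp, span ≤ 5 kb,
  arm identity ≥ 75% — are sized for the transposition-scale structures the
  screen cares about, and are configurable. Detection is strand-symmetric.

## COG enrichment

Each donor-like homolog inherits the COG functional category of its best
donor locus ("Not in COGs" when unlabeled). For every category, a one-sided
(greater) Fisher exact test on the table (k, n−k; K, N−K) treats the
transferred set (k of n) and the donor genome (K of N) as independent
samples; "Bonferroni step-down" is implemented as Holm (1979) across all
tested categories (including "Not in COGs", since the published table lists
and totals it), at family-wise α = 0.01. In the embedded published table
the per-category counts sum to slightly more than the locus totals because
a locus can carry multiple category assignments; the published percentages
use the locus totals as denominators, and the tests use those totals as the
table margins. Null simulations (sets multinomially drawn from the donor
spectrum itself) are flagged in ≤1% of 500 replicates.

## Expression calls

A target is expressed when mean Ct of the RNA negative control exceeds the
mean Ct of the 0.1 ng cDNA template by at least 3.0 cycles (equality
counts). Replicates aggregate by mean; a spread above 1.5 cycles flags QC
failure without overturning the call — a desk-scale stand-in for
dissociation-curve and gel checks. Wells with no amplification take
Ct = 40 (configurable), the standard convention.

## Synthetic data: what it emulates and what it does not

The generator plants `n_inserts` independent scattered donor fragments into
a host genome (the data cannot distinguish one large degraded transfer from
many small ones; a single-block mode is deliberately out of scope). The
defaults encode the regime the screen targets:

| parameter | default | rationale |
|---|---|---|
| substitution rate | 0.20 / site | realized identity ≈ 80%, matching the 78±6% / 81±6% regime; substituted bases are drawn from the three non-original nucleotides, so identity converges to 1 − rate |
| insert length | lognormal, mean 180 bp, sd 140 bp, min 60 | one-to-few-hundred-bp fragments with a heavy right tail (cf. 159±83 / 174±192 bp) |
| frameshift / nonsense probability | 0.30 each per insert | roughly half of annotated inserts degenerate |
| poly(A) | p = 0.15; tract 21–40 nt within 300 bp downstream | ">20 bases … within a few hundred bases" |
| inverted repeats | p = 0.15; 40 bp arms flanking the insert | transposition-signature flanks |
| contig length | normal(900, 250), min 150 bp | 0.9 kb average assembly |
| host genome | 100 kb with embedded host-panel genes | junction fragments become detectable |
| PE linker | the 44 nt 454 FLX paired-end linker | exercises linker splitting |

Every insert's truth record stores its exact edit script; replaying the
script reconstructs the original-vs-planted alignment column by column,
giving identity and reading-frame ground truth with no alignment search —
the independent oracle for the recovery and ORF tests.

Not emulated: sequencing error, quality values, assembly artifacts,
repeat families beyond a single labeled retroelement entry, GC/codon
heterogeneity (the donor and host backgrounds are uniform random), and
selection. Passing the recovery suites therefore demonstrates the screen's
behavior under the stated identity/length/degeneration regime, not
robustness to assembler- or chemistry-specific artifacts.

## Problem sizes and numerical choices

The recovery suites run ten replicate genomes of 50 kb with ten inserts
each (sensitivity: ≥90% of inserts with realized identity ≥75% and length
≥150 bp recovered) and ten host-only genomes totalling ≥1 Mb (specificity:
≤1 false donor-like call per Mb; measured 0). These sizes keep the full
test suite around three minutes while leaving both margins wide. The
aligner is checked for exact score equality against a brute-force
three-matrix dynamic program on hundreds of random pairs up to 60 nt, and
the Fisher test against a direct hypergeometric tail sum on random tables.

Determinism: every stochastic component takes a NumPy `Generator` or an
integer seed; the pipeline derives independent streams from
`(seed, stage)` pairs, so a run is byte-reproducible from its
`SimulationConfig`. Ties in top-hit selection break by bitscore, then
E-value, then locus tag. Percentages follow the published rounding:
headline percentages to integers (half away from zero), table percentages
to one decimal.

## Known limitations

* Karlin–Altschul parameters for gapped nucleotide scoring are approximated
  by the ungapped values; E-values are internally consistent but not
  BLAST-comparable.
* Fragments at ≤75% identity sit at the detection floor of the +1/−3
  scoring (expected per-base score ≈ 0) and are missed at a few percent —
  visible in the sensitivity suite's borderline cases.
* HSP merging (30 bp query gap) and the overlap-component top-hit rule are
  this package's constructions; alternatives (per-contig top hit, per-HSP
  calls) would change junction bookkeeping.
* The inverted-repeat search is gapless; arms related by indels are found
  only as shorter gapless cores.
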