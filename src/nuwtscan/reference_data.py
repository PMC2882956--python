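"""Published reference tables used as fixed inputs by the pipeline.

Two small data sets are embedded here:

* the COG functional-category spectrum of the *Wolbachia* endosymbiont of
  *Brugia malayi* (wBm) together with the category counts of the
  *Wolbachia*-like locus sets recovered from the two endobacteria-free
  filarial species, and
* the DNA-level presence/absence of *Wolbachia* homologs shared between
  species.

Counts are locus-level category assignments; a locus may carry more than one
category, so per-species column sums can exceed the stated locus totals. All
published percentages use the locus totals as denominators, and the
enrichment tests here do the same.
"""

from __future__ import annotations

# category -> (O. flexuosa HGT loci, A. viteae HGT loci, wBm genome loci)
COG_CATEGORY_COUNTS: dict[str, tuple[int, int, int]] = {
    "Translation": (15, 10, 121),
    "Transcription": (3, 2, 18),
    "Replication, recombination and repair": (7, 6, 54),
    "Cell cycle control, mitosis and meiosis": (3, 2, 9),
    "Defense mechanisms": (0, 0, 2),
    "Signal transduction mechanisms": (2, 0, 10),
    "Cell wall/membrane biogenesis": (6, 3, 33),
    "Cell motility": (0, 0, 1),
    "Intracellular trafficking and secretion": (7, 0, 29),
    "Posttranslational modification, protein turnover, chaperones": (8, 1, 51),
    "Energy production and conversion": (10, 3, 68),
    "Carbohydrate transport and metabolism": (1, 3, 24),
    "Amino acid transport and metabolism": (10, 5, 38),
    "Nucleotide transport and metabolism": (8, 2, 37),
    "Coenzyme transport and metabolism": (2, 3, 33),
    "Lipid transport and metabolism": (5, 2, 26),
    "Inorganic ion transport and metabolism": (5, 0, 35),
    "Secondary metabolites biosynthesis, transport and catabolism": (1, 0, 11),
    "General function prediction only": (6, 3, 63),
    "Function unknown": (5, 1, 31),
    "Not in COGs": (8, 1, 176),
}

# Locus totals used as denominators for the published percentages and as the
# sample sizes of the 2x2 enrichment tables.
OF_TOTAL_LOCI = 114
AV_TOTAL_LOCI = 49
WBM_TOTAL_LOCI = 805

#: wBm category spectrum alone, the default donor-panel sampling weights.
WBM_COG_SPECTRUM: dict[str, int] = {
    cat: wbm for cat, (_, _, wbm) in COG_CATEGORY_COUNTS.items()
}

# published percentage columns (category -> (Of %, Av %, wBm %)), 1 decimal
COG_CATEGORY_PERCENTS: dict[str, tuple[float, float, float]] = {
    "Translation": (13.2, 20.4, 15.0),
    "Transcription": (2.6, 4.1, 2.2),
    "Replication, recombination and repair": (6.1, 12.2, 6.7),
    "Cell cycle control, mitosis and meiosis": (2.6, 4.1, 1.1),
    "Defense mechanisms": (0.0, 0.0, 0.2),
    "Signal transduction mechanisms": (1.8, 0.0, 1.2),
    "Cell wall/membrane biogenesis": (5.3, 6.1, 4.1),
    "Cell motility": (0.0, 0.0, 0.1),
    "Intracellular trafficking and secretion": (6.1, 0.0, 3.6),
    "Posttranslational modification, protein turnover, chaperones": (7.0, 2.0, 6.3),
    "Energy production and conversion": (8.8, 6.1, 8.4),
    "Carbohydrate transport and metabolism": (0.9, 6.1, 3.0),
    "Amino acid transport and metabolism": (8.8, 10.2, 4.7),
    "Nucleotide transport and metabolism": (7.0, 4.1, 4.6),
    "Coenzyme transport and metabolism": (1.8, 6.1, 4.1),
    "Lipid transport and metabolism": (4.4, 4.1, 3.2),
    "Inorganic ion transport and metabolism": (4.4, 0.0, 4.3),
    "Secondary metabolites biosynthesis, transport and catabolism": (0.9, 0.0, 1.4),
    "General function prediction only": (5.3, 6.1, 7.8),
    "Function unknown": (4.4, 2.0, 3.9),
    "Not in COGs": (7.0, 2.0, 21.9),
}

# DNA-level presence of shared Wolbachia homologs across species nuclear
# genomes (annotation -> set of species with the locus present in genomic DNA).
AV, OF, BM = "A_viteae", "O_flexuosa", "B_malayi"

SHARED_HOMOLOG_DNA_PRESENCE: dict[str, frozenset[str]] = {
    "rod shape-determining protein RodA": frozenset({AV, OF}),
    "4-Hydroxy-3-methylbut-2-enyl diphosphate reductase, IspH": frozenset({AV, OF}),
    "ATP-binding subunit of Clp protease and DnaK/DnaJ chaperones": frozenset({AV, OF}),
    "methionyl-tRNA synthetase": frozenset({AV, OF}),
    "ribosomal large subunit pseudouridine synthase C, putative": frozenset({AV, OF}),
    "ribosomal protein L27": frozenset({AV, OF}),
    "DNA-directed RNA polymerase, beta/beta' subunits": frozenset({AV, OF}),
    "valyl-tRNA synthetase": frozenset({OF, BM}),
    "type IV secretion system protein VirB4, putative": frozenset({OF, BM}),
    "ATP-dependent Zn protease, HflB": frozenset({OF, BM}),
    "dimethyladenosine transferase": frozenset({OF, BM}),
    "DNA polymerase III, beta subunit": frozenset({OF, BM}),
    "cell cycle protein (ftsZ) gene": frozenset({OF, BM}),
    "DNA polymerase III, gamma/tau subunit": frozenset({AV, BM}),
    "IMP dehydrogenase, GuaB": frozenset({AV, BM}),
}

# Best-hit taxon tallies of the recovered Wolbachia-like loci
# (filarial-strain best hits, total loci) per species.
TAXON_TALLIES = {AV: (19, 49), OF: (47, 114)}

# headline genome numbers used by the coverage estimate
BM_GENOME_SIZE_BP = 95_000_000
BM_REPEAT_FRACTION = 0.14
AV_ASSEMBLED_BP = 31_000_000
WBM_GENOME_LENGTH_BP = 1_100_000
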