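"""COG functional-category enrichment of transferred loci.

Each donor-like homolog inherits the COG functional category of its best
donor locus. Category over-representation against the donor genome spectrum
is tested with a one-sided (greater) Fisher's exact test on the 2x2 table
(k, n−k; K, N−K) — the transferred set and the donor genome treated as
independent samples — with Holm step-down ("Bonferroni step-down")
correction across all tested categories at a family-wise alpha of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .homology_screen import HomologCall
from .synthetic_data import DonorPanel
from .util import percent1

UNCLASSIFIED = "Not in COGs"


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int   # category count in the transferred set
    n: int   # transferred-set total
    K: int   # category count in the donor genome
    N: int   # donor genome total
    p_one_sided: float
    p_adjusted: float
    significant: bool


def assign_cog(call: HomologCall, donor_panel: DonorPanel) -> str:
    """COG category of the call's best donor locus; unlabeled loci map to
    "Not in COGs"."""
    if call.klass != "donor_like":
        raise ValueError("COG assignment applies to donor-like calls only")
    gene = donor_panel.get(call.best_locus_tag)  # KeyError if absent
    return gene.cog_category or UNCLASSIFIED


def count_categories(
    calls: Sequence[HomologCall], donor_panel: DonorPanel
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in calls:
        if c.klass != "donor_like":
            continue
        cat = assign_cog(c, donor_panel)
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def fisher_one_sided(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) under the hypergeometric null for the table (k, n−k; K, N−K)."""
    if min(k, n, K, N) < 0:
        raise ValueError("counts must be non-negative")
    if k > n or K > N:
        raise ValueError("category count cannot exceed its total")
    _, p = fisher_exact([[k, n - k], [K, N - K]], alternative="greater")
    return float(p)


def holm_step_down(
    pvalues: Sequence[float], alpha: float = 0.01
) -> tuple[list[float], list[bool]]:
    """Holm (1979) step-down adjustment: sorted p(i) scaled by (m−i+1),
    cumulative-maximum enforced, capped at 1."""
    if any(not 0.0 <= p <= 1.0 for p in pvalues):
        raise ValueError("p-values must be in [0, 1]")
    if len(pvalues) == 0:
        return [], []
    reject, adjusted, _, _ = multipletests(pvalues, alpha=alpha, method="holm")
    return [float(p) for p in adjusted], [bool(r) for r in reject]


def enrichment_screen(
    category_counts: Mapping[str, int],
    n_total: int,
    genome_spectrum: Mapping[str, int],
    genome_total: int,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided Fisher tests for every category of the genome spectrum,
    Holm-corrected across all of them.

    ``n_total`` and ``genome_total`` are the locus totals used as the table
    margins; they may differ from the column sums when loci carry multiple
    category assignments.
    """
    cats = list(genome_spectrum)
    ps = [
        fisher_one_sided(
            int(category_counts.get(c, 0)), n_total,
            int(genome_spectrum[c]), genome_total,
        )
        for c in cats
    ]
    adjusted, significant = holm_step_down(ps, alpha)
    return [
        EnrichmentResult(
            category=c,
            k=int(category_counts.get(c, 0)), n=n_total,
            K=int(genome_spectrum[c]), N=genome_total,
            p_one_sided=p, p_adjusted=pa, significant=sig,
        )
        for c, p, pa, sig in zip(cats, ps, adjusted, significant)
    ]


def category_percent(count: int, total: int) -> float:
    """Published-table style percentage (one decimal place)."""
    return percent1(count, total)
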