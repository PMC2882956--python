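"""qRT-PCR expression decision rule and its QC gates.

A target is called expressed when the 0.1 ng cDNA template crosses the
cycle threshold at least ``delta`` (default 3.0) cycles before the RNA
negative control. Replicate wells are aggregated by mean; wells with no
amplification take Ct = ``max_cycles``. A replicate spread above 1.5 cycles
flags (but does not overturn) the call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

TEMPLATES = ("gDNA_10ng", "cDNA_10ng", "cDNA_1ng", "cDNA_0.1ng", "RNA_neg")
MAX_REPLICATE_SPREAD = 1.5  # cycles


@dataclass
class QpcrAssay:
    """Replicate Ct values (cycles) for one target across the template
    series: 10 ng gDNA positive control, 10/1/0.1 ng cDNA dilutions, and a
    10 ng RNA negative control. ``None`` encodes no amplification."""

    target_id: str
    gdna_10ng: tuple[float | None, ...] = ()
    cdna_10ng: tuple[float | None, ...] = ()
    cdna_1ng: tuple[float | None, ...] = ()
    cdna_01ng: tuple[float | None, ...] = ()
    rna_neg: tuple[float | None, ...] = ()
    max_cycles: int = 40


@dataclass
class ExpressionCall:
    target_id: str
    delta_ct: float
    expressed: bool
    qc_fail: bool = False
    qc_notes: list[str] = field(default_factory=list)


def _cts(values: Sequence[float | None], max_cycles: int) -> list[float]:
    out = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(float(max_cycles))
        else:
            if not 0.0 < v <= max_cycles:
                raise ValueError(f"Ct {v} outside (0, {max_cycles}]")
            out.append(float(v))
    return out


def call_expression(assay: QpcrAssay, delta: float = 3.0) -> ExpressionCall:
    """Apply the ΔCt decision rule to one assay.

    expressed iff mean(Ct, RNA negative) − mean(Ct, 0.1 ng cDNA) >= delta.
    A difference of exactly ``delta`` counts as expressed ("at least").
    """
    if not assay.cdna_01ng or not assay.rna_neg:
        raise ValueError(
            f"{assay.target_id}: 0.1 ng cDNA and RNA negative control required"
        )
    notes = []
    qc_fail = False
    for name in ("gdna_10ng", "cdna_10ng", "cdna_1ng", "cdna_01ng", "rna_neg"):
        vals = _cts(getattr(assay, name), assay.max_cycles)
        if len(vals) >= 2 and max(vals) - min(vals) > MAX_REPLICATE_SPREAD:
            qc_fail = True
            notes.append(f"replicate spread > {MAX_REPLICATE_SPREAD} for {name}")
    ct01 = _cts(assay.cdna_01ng, assay.max_cycles)
    ctneg = _cts(assay.rna_neg, assay.max_cycles)
    d = sum(ctneg) / len(ctneg) - sum(ct01) / len(ct01)
    return ExpressionCall(
        target_id=assay.target_id,
        delta_ct=d,
        expressed=d >= delta,
        qc_fail=qc_fail,
        qc_notes=notes,
    )


_COLUMN_FOR_TEMPLATE = {
    "gDNA_10ng": "gdna_10ng",
    "cDNA_10ng": "cdna_10ng",
    "cDNA_1ng": "cdna_1ng",
    "cDNA_0.1ng": "cdna_01ng",
    "RNA_neg": "rna_neg",
}


def read_ct_table(path: str | Path, max_cycles: int = 40) -> list[QpcrAssay]:
    """Read a TSV Ct table with columns target, template, replicate, ct.

    Blank/NA ct means no amplification. Template labels follow the assay
    series: gDNA_10ng, cDNA_10ng, cDNA_1ng, cDNA_0.1ng, RNA_neg.
    """
    df = pd.read_csv(path, sep="\t")
    assays = []
    for target, group in df.groupby("target", sort=True):
        kwargs: dict[str, tuple] = {}
        for template, sub in group.groupby("template"):
            if template not in _COLUMN_FOR_TEMPLATE:
                raise ValueError(f"unknown template label {template!r}")
            sub = sub.sort_values("replicate")
            kwargs[_COLUMN_FOR_TEMPLATE[template]] = tuple(
                None if pd.isna(v) else float(v) for v in sub["ct"]
            )
        assays.append(QpcrAssay(target_id=str(target), max_cycles=max_cycles, **kwargs))
    return assays


def summarize_expression(
    calls: Sequence[ExpressionCall],
    pseudogene_flags: Mapping[str, bool] | None = None,
) -> tuple[int, int, int]:
    """(targets tested, expressed, expressed targets that are pseudogenes).

    ``pseudogene_flags`` maps target id -> True when the target's genomic
    copy is degenerate (not an intact ORF).
    """
    tested = len(calls)
    expressed = [c for c in calls if c.expressed]
    flags = pseudogene_flags or {}
    pseudo = sum(1 for c in expressed if flags.get(c.target_id, False))
    return tested, len(expressed), pseudo
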