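"""TPM normalization, detection filtering, promoter naming and gene-set sums.

The CAGE expression workflow: per-library tag counts are scaled to tags
per million (TPM), TSS clusters never exceeding the detection threshold in
any sample are discarded, promoters are called novel when their reference
position lies more than the novelty distance from every annotated TSS of
the gene, and promoters are named ``p1@GENE, p2@GENE, ...`` (known) or
``pA@GENE, pB@GENE, ...`` (novel) in order of decreasing maximum TPM.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ExpressionTable, GenomicInterval

__all__ = [
    "PromoterRecord",
    "AnalysisConfig",
    "tpm_normalize",
    "filter_detected",
    "expressed_sample_fraction",
    "classify_novelty",
    "assign_promoter_names",
    "aggregate_gene_set",
    "fold_ratio",
]

KNOWN = "known"
NOVEL = "novel"


@dataclass
class PromoterRecord:
    """One CAGE-defined promoter: a TSS cluster with a single reference base.

    ``center`` defaults to the interval midpoint; when a dominant CTSS
    position is known it should be passed explicitly (it is the reference
    point for the TATA/CpG windows and the TFBS summation).
    """

    id: str
    gene: str
    interval: GenomicInterval
    center: int | None = None
    novelty: str = KNOWN

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = self.interval.center
        if not (self.interval.start <= self.center < self.interval.end):
            raise ValueError(
                f"center {self.center} outside [{self.interval.start}, {self.interval.end})"
            )
        if self.novelty not in (KNOWN, NOVEL):
            raise ValueError(f"invalid novelty {self.novelty!r}")


def tpm_normalize(raw_counts: ExpressionTable, library_totals: pd.Series) -> ExpressionTable:
    """Scale raw tag counts to tags per million of each library's total.

    ``value[i, s] = raw[i, s] * 1e6 / total[s]``.
    """
    totals = pd.Series(library_totals, dtype=float)
    missing = [s for s in raw_counts.sample_ids if s not in totals.index]
    if missing:
        raise ValueError(f"missing library totals for samples: {missing}")
    totals = totals.loc[raw_counts.sample_ids]
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive library totals for samples: {bad}")
    tpm = raw_counts.values * 1e6 / totals
    return ExpressionTable(tpm, raw_counts.sample_meta)


def filter_detected(table: ExpressionTable, threshold: float) -> ExpressionTable:
    """Keep rows whose maximum over samples is strictly greater than
    ``threshold`` TPM (a cluster must exceed it in at least one sample)."""
    if table.shape[0] == 0:
        return table
    keep = table.values.max(axis=1) > threshold
    return ExpressionTable(table.values.loc[keep], table.sample_meta)


def expressed_sample_fraction(
    table: ExpressionTable,
    gene: str,
    promoter_map: Mapping[str, Sequence[str]],
    threshold: float,
) -> tuple[int, float]:
    """Count samples in which *any* promoter of ``gene`` exceeds ``threshold``.

    Returns ``(count, count / n_samples)``.
    """
    if gene not in promoter_map or not promoter_map[gene]:
        raise KeyError(f"no promoters mapped for gene {gene!r}")
    sub = table.subset_rows(promoter_map[gene])
    expressed = (sub.values > threshold).any(axis=0)
    count = int(expressed.sum())
    return count, count / sub.shape[1]


def classify_novelty(
    promoter: PromoterRecord, refseq_tss: Sequence[int], distance: int
) -> str:
    """Novel iff the promoter center is strictly more than ``distance`` bp
    from every annotated TSS position of the same gene."""
    if len(refseq_tss) == 0:
        raise ValueError(f"no reference TSS positions for {promoter.id}")
    nearest = min(abs(promoter.center - ref) for ref in refseq_tss)
    return NOVEL if nearest > distance else KNOWN


def _novel_labels() -> Iterable[str]:
    letters = string.ascii_uppercase
    for c in letters:
        yield c
    for c1 in letters:  # pragma: no cover - >26 novel promoters is pathological
        for c2 in letters:
            yield c1 + c2


def assign_promoter_names(
    gene: str, promoters: Sequence[PromoterRecord], table: ExpressionTable
) -> dict[str, str]:
    """Name promoters p1@GENE... (known) / pA@GENE... (novel) by descending
    maximum TPM; ties broken by (chrom, start).  Returns old id -> new id."""
    missing = [p.id for p in promoters if p.id not in table.values.index]
    if missing:
        raise KeyError(f"promoters without expression rows: {missing}")

    def sort_key(p: PromoterRecord):
        return (-float(table.values.loc[p.id].max()), p.interval.chrom, p.interval.start)

    mapping: dict[str, str] = {}
    known = sorted((p for p in promoters if p.novelty == KNOWN), key=sort_key)
    for i, p in enumerate(known, start=1):
        mapping[p.id] = f"p{i}@{gene}"
    novel = sorted((p for p in promoters if p.novelty == NOVEL), key=sort_key)
    for label, p in zip(_novel_labels(), novel):
        mapping[p.id] = f"p{label}@{gene}"
    return mapping


def aggregate_gene_set(table: ExpressionTable, row_ids: Sequence[str]) -> pd.Series:
    """Per-sample sum of expression over the selected rows (e.g. all
    histone H1 transcripts pooled for comparison against a reference gene)."""
    sub = table.subset_rows(row_ids)
    return sub.values.sum(axis=0)


def fold_ratio(aggregate: pd.Series, reference: pd.Series) -> pd.DataFrame:
    """Per-sample ratio aggregate/reference; where the reference is zero the
    ratio is +inf and flagged so summaries can exclude it."""
    reference = reference.loc[aggregate.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = aggregate.to_numpy() / reference.to_numpy()
    ratio = np.where(reference.to_numpy() == 0, np.inf, ratio)
    return pd.DataFrame(
        {"ratio": ratio, "reference_zero": reference.to_numpy() == 0},
        index=aggregate.index,
    )
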