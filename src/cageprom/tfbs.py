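"""Summed-posterior TFBS counts and empirical rank tail probabilities.

Motif-model posteriors ≥ 0.2 are retained; per promoter and TF, the
posteriors of retained sites whose midpoint lies within ±500 bp of the
promoter reference base are summed, giving the estimated number of
binding sites.  Significance is the empirical tail probability of that
count within a genome-wide background population of promoters scored the
same way: rank / N, where rank counts background promoters with a count
greater than or equal to the observed one (ties and the promoter itself
included, so rank ≥ 1 — the conservative maximal rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import AnalysisConfig
from .expression import PromoterRecord
from .io import TfbsSiteRecord

__all__ = [
    "TfbsCount",
    "TfbsSignificance",
    "retain_sites",
    "site_count",
    "tail_probability",
    "shared_tf_report",
]


@dataclass(frozen=True)
class TfbsCount:
    promoter_id: str
    tf: str
    site_count: float  # summed posterior: the estimated number of sites
    n_sites_retained: int

    def __post_init__(self) -> None:
        if self.site_count < 0:
            raise ValueError("negative site count")
        if self.site_count > self.n_sites_retained + 1e-9:
            raise ValueError("summed posterior exceeds number of retained sites")


@dataclass(frozen=True)
class TfbsSignificance:
    promoter_id: str
    tf: str
    site_count: float
    rank: int
    background_n: int
    tail_prob: float

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.background_n):
            raise ValueError(f"rank {self.rank} outside [1, {self.background_n}]")
        if not (0.0 < self.tail_prob <= 1.0):
            raise ValueError(f"tail probability {self.tail_prob} outside (0, 1]")


def retain_sites(
    sites: Iterable[TfbsSiteRecord], min_posterior: float
) -> list[TfbsSiteRecord]:
    """Keep sites with posterior >= ``min_posterior`` (inclusive)."""
    return [s for s in sites if s.posterior >= min_posterior]


def site_count(
    promoter: PromoterRecord,
    sites: Iterable[TfbsSiteRecord],
    window: int,
    tfs: Sequence[str] | None = None,
) -> dict[str, TfbsCount]:
    """Per-TF summed posterior over sites within ±``window`` bp of the
    promoter reference base (site anchor = interval midpoint, closed
    boundary, same chromosome).  TFs listed in ``tfs`` are always reported,
    with count 0 when no site qualifies."""
    sums: dict[str, float] = {tf: 0.0 for tf in (tfs or [])}
    counts: dict[str, int] = {tf: 0 for tf in (tfs or [])}
    for s in sites:
        if s.interval.chrom != promoter.interval.chrom:
            continue
        if abs(s.interval.midpoint - promoter.center) > window:
            continue
        sums[s.tf] = sums.get(s.tf, 0.0) + s.posterior
        counts[s.tf] = counts.get(s.tf, 0) + 1
    return {
        tf: TfbsCount(promoter.id, tf, sums[tf], counts[tf]) for tf in sums
    }


def tail_probability(
    observed: TfbsCount,
    background: np.ndarray,
    observed_included: bool = True,
) -> TfbsSignificance:
    """Empirical tail probability of an observed summed-posterior count.

    ``background`` is the population of counts for the same TF over all
    background promoters; when it does not already contain the promoter of
    interest, pass ``observed_included=False`` and it is appended.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background population")
    if not observed_included:
        bg = np.append(bg, observed.site_count)
    n = int(bg.size)
    rank = int((bg >= observed.site_count).sum())
    rank = max(rank, 1)  # the promoter itself always counts
    return TfbsSignificance(
        promoter_id=observed.promoter_id,
        tf=observed.tf,
        site_count=observed.site_count,
        rank=rank,
        background_n=n,
        tail_prob=rank / n,
    )


def shared_tf_report(
    gene_promoters: Mapping[str, Sequence[PromoterRecord]],
    sites: Sequence[TfbsSiteRecord],
    config: AnalysisConfig | None = None,
    backgrounds: Mapping[str, np.ndarray] | None = None,
) -> dict:
    """Per-gene TF reports and the TFs common to all genes.

    A TF is reported for a gene when at least one retained site with
    posterior strictly greater than ``site_report_min`` lies within the
    TFBS window of any of that gene's promoters.  When per-TF backgrounds
    are provided, each (promoter, TF) summed-posterior count is also
    scored by :func:`tail_probability` and flagged at ``link_alpha``.
    """
    if not gene_promoters:
        raise ValueError("need at least one gene")
    config = config or AnalysisConfig()
    retained = retain_sites(sites, config.posterior_min)
    high = [s for s in retained if s.posterior > config.site_report_min]

    per_gene: dict[str, set[str]] = {}
    for gene, promoters in gene_promoters.items():
        tfs: set[str] = set()
        for p in promoters:
            near = site_count(p, high, config.tfbs_window)
            tfs |= {tf for tf, c in near.items() if c.n_sites_retained > 0}
        per_gene[gene] = tfs
    common = set.intersection(*per_gene.values()) if per_gene else set()

    significance: list[TfbsSignificance] = []
    if backgrounds:
        for gene, promoters in gene_promoters.items():
            for p in promoters:
                counts = site_count(p, retained, config.tfbs_window, tfs=sorted(backgrounds))
                for tf, c in counts.items():
                    significance.append(
                        tail_probability(c, backgrounds[tf], observed_included=False)
                    )
    return {
        "per_gene": per_gene,
        "common": common,
        "significance": significance,
        "alpha": config.link_alpha,
    }
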