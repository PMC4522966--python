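"""Enhancer–promoter linking by expression correlation.

Candidate enhancers are those whose midpoint lies within 500 kb of a
promoter's reference base on the same chromosome.  Each candidate pair is
tested with a Pearson correlation across all shared samples; the family
of all tested pairs is Bonferroni-corrected and links with corrected
P < alpha are called significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .correlation import pearson
from .expression import PromoterRecord
from .io import BedFeature, ExpressionTable

__all__ = ["EnhancerLink", "candidate_pairs", "test_links", "bonferroni_select"]


@dataclass
class EnhancerLink:
    enhancer_id: str
    promoter_id: str
    distance: float  # promoter center to enhancer midpoint, unsigned bp
    r: float
    p_raw: float
    p_adj: float | None = None
    significant: bool | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.p_raw)


def candidate_pairs(
    promoters: Sequence[PromoterRecord],
    enhancers: Sequence[BedFeature],
    max_dist: float,
) -> list[tuple[PromoterRecord, BedFeature, float]]:
    """Promoter × enhancer pairs on the same chromosome with center-to-
    midpoint distance ≤ ``max_dist`` bp."""
    out = []
    for p in promoters:
        for e in enhancers:
            if e.interval.chrom != p.interval.chrom:
                continue
            dist = abs(p.center - e.interval.midpoint)
            if dist <= max_dist:
                out.append((p, e, dist))
    return out


def test_links(
    pairs: Sequence[tuple[PromoterRecord, BedFeature, float]],
    promoter_expr: ExpressionTable,
    enhancer_expr: ExpressionTable,
) -> list[EnhancerLink]:
    """Pearson-test every candidate pair across all shared samples.

    Both tables must carry an identical, identically ordered sample set
    (no silent inner join).  Pairs whose correlation is undefined are
    returned with NaN statistics and excluded from the Bonferroni family.
    """
    if promoter_expr.sample_ids != enhancer_expr.sample_ids:
        raise ValueError("promoter and enhancer tables must share an identical sample set")
    links = []
    for p, e, dist in pairs:
        r, p_raw = pearson(promoter_expr.row(p.id), enhancer_expr.row(e.name))
        links.append(EnhancerLink(e.name, p.id, dist, r, p_raw))
    return links


def bonferroni_select(links: Sequence[EnhancerLink], alpha: float) -> list[EnhancerLink]:
    """Annotate every link with p_adj = min(1, p_raw * m) — m counting
    links with a defined p — and return the significant subset
    (p_adj < alpha)."""
    m = sum(1 for l in links if l.defined)
    significant = []
    for link in links:
        if not link.defined:
            link.p_adj, link.significant = float("nan"), False
            continue
        link.p_adj = min(1.0, link.p_raw * m)
        link.significant = link.p_adj < alpha
        if link.significant:
            significant.append(link)
    return significant
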