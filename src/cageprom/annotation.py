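"""Interval annotation: TATA/CpG promoter status and histone-mark regions.

Rules applied:

* a promoter is **TATA-containing** when a TATA-box annotation overlaps the
  500-bp window immediately upstream of its reference base (strand-aware);
* a promoter is **CpG** when a CpG island overlaps the closed ±500-bp
  window around its reference base (strand-agnostic);
* a H3K27ac peak with no overlapping H3K4me3 is an **active enhancer**; a
  H3K4me3 peak not completely covered by the union of overlapping H3K27ac
  peaks is an **active promoter**; a completely covered H3K4me3 peak is
  **dual** (both marks).

"Within 500 bp" boundaries are closed (distance exactly 500 qualifies);
unstranded annotations match both strands.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import AnalysisConfig
from .expression import PromoterRecord
from .io import BedFeature, GenomicInterval, UNSTRANDED, strands_compatible

__all__ = [
    "PromoterAnnotation",
    "RegulatoryRegion",
    "ACTIVE_ENHANCER",
    "ACTIVE_PROMOTER",
    "DUAL",
    "expand_interval",
    "intersect",
    "classify_tata",
    "classify_cpg",
    "classify_regulatory_regions",
    "promoter_context",
]

TATA_CONTAINING = "TATA-containing"
TATA_LESS = "TATA-less"
CPG = "CpG"
CPG_LESS = "CpG-less"

ACTIVE_ENHANCER = "active_enhancer"
ACTIVE_PROMOTER = "active_promoter"
DUAL = "dual"


@dataclass(frozen=True)
class PromoterAnnotation:
    promoter_id: str
    tata: str
    cpg: str

    def __post_init__(self) -> None:
        if self.tata not in (TATA_CONTAINING, TATA_LESS):
            raise ValueError(f"invalid TATA status {self.tata!r}")
        if self.cpg not in (CPG, CPG_LESS):
            raise ValueError(f"invalid CpG status {self.cpg!r}")


@dataclass(frozen=True)
class RegulatoryRegion:
    interval: GenomicInterval
    label: str
    source_marks: frozenset

    def __post_init__(self) -> None:
        if self.label not in (ACTIVE_ENHANCER, ACTIVE_PROMOTER, DUAL):
            raise ValueError(f"invalid label {self.label!r}")


def expand_interval(interval: GenomicInterval, pad: int) -> GenomicInterval:
    """Pad an interval by ``pad`` bp on either side, clipping at 0."""
    return interval.expand(pad)


def intersect(
    a: Sequence[BedFeature], b: Sequence[BedFeature]
) -> list[tuple[BedFeature, BedFeature, int]]:
    """All overlapping pairs (x from a, y from b) with their overlap length.

    Overlap requires the same chromosome, compatible strands (unstranded
    matches both) and a strictly positive intersection under half-open
    coordinates; abutting intervals do not overlap.
    """
    by_chrom: dict[str, list[BedFeature]] = defaultdict(list)
    for f in b:
        by_chrom[f.interval.chrom].append(f)
    for feats in by_chrom.values():
        feats.sort(key=lambda f: (f.interval.start, f.interval.end))
    starts = {c: [f.interval.start for f in feats] for c, feats in by_chrom.items()}

    out: list[tuple[BedFeature, BedFeature, int]] = []
    for fa in a:
        ia = fa.interval
        feats = by_chrom.get(ia.chrom)
        if not feats:
            continue
        # candidates have start < a.end; right-bound via sorted starts
        hi = bisect_left(starts[ia.chrom], ia.end)
        for fb in feats[:hi]:
            length = ia.overlap(fb.interval)
            if length > 0:
                out.append((fa, fb, length))
    return out


def _window_overlaps(window: GenomicInterval, features: Iterable[BedFeature]) -> bool:
    return any(window.overlap(f.interval) > 0 for f in features)


def classify_tata(
    promoter: PromoterRecord,
    tata_boxes: Sequence[BedFeature],
    config: AnalysisConfig | None = None,
) -> str:
    """TATA status from the strand-aware upstream window of the reference
    base: ``[center-500, center)`` on +, ``(center, center+500]`` on −."""
    config = config or AnalysisConfig()
    strand = promoter.interval.strand
    if strand == UNSTRANDED:
        raise ValueError(f"promoter {promoter.id} is unstranded; TATA needs a direction")
    c, w = promoter.center, config.tata_upstream
    if strand == "+":
        window = GenomicInterval(promoter.interval.chrom, max(0, c - w), c if c > 0 else 1)
        if c == 0:
            return TATA_LESS  # no upstream sequence exists
    else:
        window = GenomicInterval(promoter.interval.chrom, c + 1, c + 1 + w)
    return TATA_CONTAINING if _window_overlaps(window, tata_boxes) else TATA_LESS


def classify_cpg(
    promoter: PromoterRecord,
    cpg_islands: Sequence[BedFeature],
    config: AnalysisConfig | None = None,
) -> str:
    """CpG status: any island overlapping the closed ±500-bp window around
    the reference base (strand-agnostic)."""
    config = config or AnalysisConfig()
    c, w = promoter.center, config.cpg_vicinity
    window = GenomicInterval(promoter.interval.chrom, max(0, c - w), c + w + 1)
    return CPG if _window_overlaps(window, cpg_islands) else CPG_LESS


def _union_covers(target: GenomicInterval, pieces: list[GenomicInterval]) -> bool:
    """True iff the union of ``pieces`` covers every base of ``target``."""
    clipped = sorted(
        (max(p.start, target.start), min(p.end, target.end))
        for p in pieces
        if p.start < target.end and p.end > target.start
    )
    covered = target.start
    for s, e in clipped:
        if s > covered:
            return False
        covered = max(covered, e)
        if covered >= target.end:
            return True
    return covered >= target.end


def classify_regulatory_regions(
    h3k4me3: Sequence[BedFeature], h3k27ac: Sequence[BedFeature]
) -> list[RegulatoryRegion]:
    """Partition histone peaks into active enhancers / promoters / dual
    regions (rule in the module docstring)."""
    regions: list[RegulatoryRegion] = []
    k4_hits = {id(f): [] for f in h3k4me3}
    k27_hit = {id(f): False for f in h3k27ac}
    for fa, fb, _ in intersect(h3k4me3, h3k27ac):
        k4_hits[id(fa)].append(fb.interval)
        k27_hit[id(fb)] = True
    for f in h3k27ac:
        if not k27_hit[id(f)]:
            regions.append(RegulatoryRegion(f.interval, ACTIVE_ENHANCER, frozenset({"H3K27ac"})))
    for f in h3k4me3:
        overlapping = k4_hits[id(f)]
        if overlapping and _union_covers(f.interval, overlapping):
            regions.append(
                RegulatoryRegion(f.interval, DUAL, frozenset({"H3K4me3", "H3K27ac"}))
            )
        else:
            marks = {"H3K4me3"} | ({"H3K27ac"} if overlapping else set())
            regions.append(RegulatoryRegion(f.interval, ACTIVE_PROMOTER, frozenset(marks)))
    return regions


def promoter_context(
    promoter: PromoterRecord,
    regions: Sequence[RegulatoryRegion],
    max_dist: int,
) -> dict[str, tuple[RegulatoryRegion, float] | None]:
    """Nearest region of each label within ``max_dist`` of the promoter
    reference base, with a signed edge-to-center distance (negative =
    upstream of the TSS on its strand; unsigned for unstranded promoters,
    zero when the region covers the reference base)."""
    c = promoter.center
    strand = promoter.interval.strand
    out: dict[str, tuple[RegulatoryRegion, float] | None] = {
        ACTIVE_ENHANCER: None,
        ACTIVE_PROMOTER: None,
        DUAL: None,
    }
    best: dict[str, tuple[float, int, RegulatoryRegion]] = {}
    for region in regions:
        iv = region.interval
        if iv.chrom != promoter.interval.chrom:
            continue
        if iv.start <= c < iv.end:
            dist = 0.0
        else:
            dist = float(min(abs(iv.start - c), abs((iv.end - 1) - c)))
        if dist > max_dist:
            continue
        key = (dist, iv.start, region)
        cur = best.get(region.label)
        if cur is None or (dist, iv.start) < (cur[0], cur[1]):
            best[region.label] = (dist, iv.start, region)
    for label, (dist, _, region) in best.items():
        signed = dist
        if strand != UNSTRANDED and dist > 0:
            downstream = region.interval.midpoint > c
            if strand == "-":
                downstream = not downstream
            signed = dist if downstream else -dist
        out[label] = (region, signed)
    return out
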