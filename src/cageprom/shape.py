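"""Sharp/broad promoter shape classification from per-nucleotide tag counts.

A promoter is *sharp* when the majority of its transcription initiation
events fall on a single dominant TSS or within a 5-nt window, and *broad*
when initiation is dispersed across the TSS cluster (at most a 50-bp
genomic window is considered the cluster).  Operationally: trim the
profile to its densest 50-bp window, find the densest 5-nt window inside
it, and call sharp iff that window holds strictly more than half of the
trimmed signal.  The rule is invariant to count scaling (raw tags or TPM)
and to translation of the coordinate system.

Window arithmetic is in genomic base pairs — gaps between observed CTSS
positions count — and candidate window starts are the observed positions
(any maximal-sum window can be slid right onto one without losing tags);
ties go to the smallest start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import AnalysisConfig
from .io import CtssRecord, GenomicInterval, UNSTRANDED

__all__ = [
    "TagProfile",
    "ShapeCall",
    "SHARP",
    "BROAD",
    "densest_window",
    "classify_shape",
    "pool_profiles",
    "profile_from_ctss",
]

SHARP = "sharp"
BROAD = "broad"


@dataclass
class TagProfile:
    """Per-nucleotide tag counts for one promoter.

    ``positions`` are strictly increasing genomic coordinates; ``counts``
    are the aligned non-negative tag counts (raw or TPM-scaled — the
    classifier only uses proportions).
    """

    promoter_id: str
    strand: str
    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.positions.shape != self.counts.shape:
            raise ValueError("positions and counts must align")
        if self.positions.size and (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("negative tag counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def restrict(self, start: int, end: int) -> "TagProfile":
        """Sub-profile on genomic window [start, end)."""
        mask = (self.positions >= start) & (self.positions < end)
        return TagProfile(self.promoter_id, self.strand, self.positions[mask], self.counts[mask])


@dataclass(frozen=True)
class ShapeCall:
    promoter_id: str
    shape: str
    dominant_fraction: float
    dominant_window_start: int
    cluster_window_start: int
    cluster_fraction: float  # share of the full profile kept after trimming (QC)

    def __post_init__(self) -> None:
        if not (0.0 < self.dominant_fraction <= 1.0):
            raise ValueError("dominant_fraction must be in (0, 1]")
        if self.shape not in (SHARP, BROAD):
            raise ValueError(f"invalid shape {self.shape!r}")


def densest_window(profile: TagProfile, width: int) -> tuple[int, float]:
    """The width-bp genomic window with the maximal tag sum.

    Returns ``(window_start, window_sum)``.  Candidate starts are the
    observed positions; among equal sums the smallest start wins.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if profile.positions.size == 0 or profile.total <= 0:
        raise ValueError(f"empty profile for {profile.promoter_id}")
    pos, cnt = profile.positions, profile.counts
    csum = np.concatenate([[0.0], np.cumsum(cnt)])
    ends = np.searchsorted(pos, pos + width, side="left")
    sums = csum[ends] - csum[np.arange(pos.size)]
    best = int(np.argmax(sums))  # argmax returns the first (= smallest start) maximum
    return int(pos[best]), float(sums[best])


def classify_shape(profile: TagProfile, config: AnalysisConfig | None = None) -> ShapeCall:
    """Call a promoter sharp or broad (see module docstring for the rule)."""
    config = config or AnalysisConfig()
    if profile.total <= 0:
        raise ValueError(f"unclassifiable zero-total profile for {profile.promoter_id}")
    cluster_start, cluster_sum = densest_window(profile, config.cluster_window)
    trimmed = profile.restrict(cluster_start, cluster_start + config.cluster_window)
    dom_start, dom_sum = densest_window(trimmed, config.sharp_window)
    fraction = dom_sum / cluster_sum
    return ShapeCall(
        promoter_id=profile.promoter_id,
        shape=SHARP if fraction > config.sharp_fraction else BROAD,
        dominant_fraction=fraction,
        dominant_window_start=dom_start,
        cluster_window_start=cluster_start,
        cluster_fraction=cluster_sum / profile.total,
    )


def pool_profiles(profiles: Sequence[TagProfile]) -> TagProfile:
    """Position-wise sum of per-sample profiles for one promoter."""
    if not profiles:
        raise ValueError("no profiles to pool")
    pid, strand = profiles[0].promoter_id, profiles[0].strand
    for p in profiles[1:]:
        if p.promoter_id != pid:
            raise ValueError(f"mixed promoter ids: {pid!r} vs {p.promoter_id!r}")
        if p.strand != strand:
            raise ValueError(f"mixed strands for {pid!r}")
    all_pos = np.concatenate([p.positions for p in profiles])
    all_cnt = np.concatenate([p.counts for p in profiles])
    uniq, inverse = np.unique(all_pos, return_inverse=True)
    pooled = np.zeros(uniq.size, dtype=float)
    np.add.at(pooled, inverse, all_cnt)
    return TagProfile(pid, strand, uniq, pooled)


def profile_from_ctss(
    promoter_id: str,
    interval: GenomicInterval,
    ctss: dict[tuple[str, str], list[CtssRecord]],
) -> TagProfile:
    """Extract the tag profile of one promoter from grouped CTSS records
    (records on the matching chrom+strand falling inside the interval;
    an unstranded promoter pools both strands)."""
    strands = ("+", "-") if interval.strand == UNSTRANDED else (interval.strand,)
    pos_count: dict[int, float] = {}
    for strand in strands:
        for rec in ctss.get((interval.chrom, strand), []):
            if interval.start <= rec.position < interval.end:
                pos_count[rec.position] = pos_count.get(rec.position, 0.0) + rec.count
    positions = np.array(sorted(pos_count), dtype=np.int64)
    counts = np.array([pos_count[p] for p in positions], dtype=float)
    return TagProfile(promoter_id, interval.strand, positions, counts)
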