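"""Seeded synthetic CAGE-like data with known ground truth.

The generator emulates the statistical structure every pipeline stage
assumes, so the whole analysis is testable without any download:

* **Expression**: a Gaussian copula plants a target Spearman matrix over
  promoters; marginals are log-normal (CAGE TPM is heavy-tailed), scaled
  so each promoter hits its target maximum TPM, then converted to integer
  tag counts against per-library totals drawn from a realistic CAGE depth
  range (5–20 M mapped tags).  A per-promoter ``restricted_fraction``
  zeroes the samples with the lowest latent values, emulating
  tissue-restricted genes.
* **Profiles**: per-nucleotide CTSS counts with controllable sharp/broad
  shape — sharp profiles put ≥ 0.6 of tags in one 5-nt mode, broad
  profiles keep every 5-nt window ≤ 0.4 of the cluster total.
* **Annotations**: TATA boxes, CpG islands, annotated TSS positions and
  H3K4me3/H3K27ac peaks placed at controlled offsets from each promoter.
* **Enhancers**: expression vectors built as scaled promoter signal plus
  Gaussian noise calibrated to a target Pearson r, placed at specified
  distances (including beyond the 500-kb window); null enhancers are
  independent noise.
* **TFBS**: per-TF background populations of summed-posterior counts with
  planted enrichment at focal promoters, plus negative-control sites
  below the retention cutoff and outside the summation window.

Every generator is a pure function of the spec: the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .config import AnalysisConfig
from .expression import KNOWN, NOVEL, PromoterRecord
from .io import (
    BedFeature,
    CtssRecord,
    ExpressionTable,
    GenomicInterval,
    TfbsSiteRecord,
)
from .shape import BROAD, SHARP, TagProfile, classify_shape, densest_window

__all__ = [
    "PromoterSim",
    "EnhancerSim",
    "TfbsSim",
    "SimulationSpec",
    "default_world_spec",
    "simulate_expression",
    "simulate_profiles",
    "simulate_annotations",
    "simulate_enhancers",
    "simulate_tfbs",
    "write_world",
]

SIM_CHROM = "chrS"


@dataclass(frozen=True)
class PromoterSim:
    """One simulated promoter: gene, target shape, expression ceiling and
    annotation offsets relative to the promoter center (None = absent)."""

    gene: str
    shape: str  # "sharp" | "broad"
    max_tpm: float
    restricted_fraction: float = 0.0  # share of samples forced to zero
    refseq_offset: int = 0  # annotated TSS at center + offset
    tata_offset: int | None = None  # TATA box center at center + offset
    cpg_offset: int | None = 0  # CpG island center at center + offset
    h3k4me3_offset: int | None = 1100
    h3k27ac_offset: int | None = -1000

    def __post_init__(self) -> None:
        if self.shape not in (SHARP, BROAD):
            raise ValueError(f"invalid shape class {self.shape!r}")
        if self.max_tpm <= 0:
            raise ValueError("max_tpm must be positive")
        if not (0.0 <= self.restricted_fraction < 1.0):
            raise ValueError("restricted_fraction must be in [0, 1)")


@dataclass(frozen=True)
class EnhancerSim:
    """A candidate enhancer: distance from its target promoter's center
    (negative = upstream) and a target Pearson r, or None for a null
    (independent) enhancer."""

    distance: int
    target_r: float | None
    target_promoter: int = 0  # index into SimulationSpec.promoters

    def __post_init__(self) -> None:
        if self.target_r is not None and not (-1.0 < self.target_r < 1.0):
            raise ValueError("target_r must be in (-1, 1)")


@dataclass(frozen=True)
class TfbsSim:
    # Exponential background (mean 0.3): a planted +2.0 excess then clears
    # the 1% empirical tail with margin, P(X >= 2.0) = e^(-2/0.3) ~ 1.3e-3.
    background_n: int = 10_000
    tfs: tuple[str, ...] = ("NFY", "SP1", "RREB1", "FOXP1")
    background_mean: float = 0.3
    planted: tuple[tuple[int, str, float], ...] = ()  # (promoter idx, tf, added posterior)

    def __post_init__(self) -> None:
        if self.background_n < 100:
            raise ValueError("background_n must be >= 100")


@dataclass(frozen=True)
class SimulationSpec:
    """The stated world: everything the generators need, seeded."""

    seed: int
    n_samples: int = 457
    promoters: tuple[PromoterSim, ...] = ()
    rank_correlation: tuple[tuple[float, ...], ...] | None = None  # target Spearman
    library_size_range: tuple[int, int] = (5_000_000, 20_000_000)
    promoter_spacing: int = 10_000
    promoter_width: int = 40
    first_center: int = 1_000_000
    tags_per_profile: int = 500
    enhancers: tuple[EnhancerSim, ...] = ()
    tfbs: TfbsSim = field(default_factory=TfbsSim)

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.rank_correlation is not None:
            m = np.asarray(self.rank_correlation, dtype=float)
            if m.shape != (len(self.promoters),) * 2:
                raise ValueError("rank_correlation shape must match promoter count")
            if not np.allclose(m, m.T):
                raise ValueError("rank_correlation must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("rank_correlation must have unit diagonal")

    def promoter_center(self, i: int) -> int:
        return self.first_center + i * self.promoter_spacing

    def promoter_interval(self, i: int) -> GenomicInterval:
        c, hw = self.promoter_center(i), self.promoter_width // 2
        return GenomicInterval(SIM_CHROM, c - hw, c - hw + self.promoter_width, "+")

    def promoter_records(self) -> list[PromoterRecord]:
        recs = []
        for i, p in enumerate(self.promoters):
            novelty = NOVEL if abs(p.refseq_offset) > 500 else KNOWN
            recs.append(
                PromoterRecord(
                    id=f"prom_{i}",
                    gene=p.gene,
                    interval=self.promoter_interval(i),
                    center=self.promoter_center(i),
                    novelty=novelty,
                )
            )
        return recs


# Default world: three genes, six promoters, the reported intra/inter-gene
# Spearman structure of a forebrain-gene promoterome (strong within-gene,
# weak cross-gene correlation), realistic maximum TPM, matching shapes
# and TATA/CpG annotations.
_DEFAULT_RANK_CORR = (
    (1.00, 0.77, 0.76, 0.35, 0.24, 0.29),
    (0.77, 1.00, 0.83, 0.32, 0.22, 0.26),
    (0.76, 0.83, 1.00, 0.30, 0.21, 0.24),
    (0.35, 0.32, 0.30, 1.00, 0.49, 0.56),
    (0.24, 0.22, 0.21, 0.49, 1.00, 0.85),
    (0.29, 0.26, 0.24, 0.56, 0.85, 1.00),
)


def default_world_spec(seed: int, n_samples: int = 457) -> SimulationSpec:
    promoters = (
        # FOXG1-like: one novel broad main promoter, one broad, one sharp known
        PromoterSim("FOXG1", BROAD, 1018.0, refseq_offset=-1200, tata_offset=None),
        PromoterSim("FOXG1", BROAD, 300.0, refseq_offset=-1200, cpg_offset=None),
        PromoterSim("FOXG1", SHARP, 150.0, refseq_offset=-200, cpg_offset=None),
        # MECP2-like: broad, CpG, ubiquitous
        PromoterSim("MECP2", BROAD, 77.0, refseq_offset=60),
        # CDKL5-like: broad + sharp pair, both CpG
        PromoterSim("CDKL5", BROAD, 40.0, refseq_offset=50),
        PromoterSim("CDKL5", SHARP, 30.0, refseq_offset=-50),
    )
    enhancers = (
        EnhancerSim(-7_000, 0.78, target_promoter=0),
        EnhancerSim(53_000, 0.43, target_promoter=3),
        EnhancerSim(-408_000, 0.55, target_promoter=3),
        EnhancerSim(-245_000, 0.20, target_promoter=4),
        EnhancerSim(120_000, None, target_promoter=0),
        EnhancerSim(-600_000, 0.90, target_promoter=0),  # beyond the 500-kb window
    )
    tfbs = TfbsSim(
        planted=(
            (0, "NFY", 1.9),
            (0, "RREB1", 1.5),
            (0, "FOXP1", 1.3),
            (3, "NFY", 1.3),
            (4, "NFY", 0.9),
        )
    )
    return SimulationSpec(
        seed=seed,
        n_samples=n_samples,
        promoters=promoters,
        rank_correlation=_DEFAULT_RANK_CORR,
        enhancers=enhancers,
        tfbs=tfbs,
    )


def _latent_correlation(rank_corr: np.ndarray) -> np.ndarray:
    """Pearson correlation of the Gaussian latents that yields the target
    Spearman after monotone marginal mapping: rho = 2 sin(pi * rho_s / 6)."""
    return 2.0 * np.sin(np.pi * rank_corr / 6.0)


def _sample_copula(rng: np.random.Generator, corr: np.ndarray, n: int) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise ValueError(
            f"correlation target is not positive semi-definite (min eigenvalue {eigval.min():.3g})"
        )
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    z = rng.standard_normal((corr.shape[0], n))
    return root @ z


def simulate_expression(
    spec: SimulationSpec, marginal_sigma: float = 1.5
) -> tuple[ExpressionTable, pd.Series, dict]:
    """Raw tag counts + library totals with a planted Spearman structure.

    Returns ``(raw_counts, library_totals, truth)``; ``truth`` records the
    latent TPM matrix, the latent correlation actually used, the totals
    and the zero masks, enough to score every downstream stage.
    """
    if not spec.promoters:
        raise ValueError("spec has no promoters")
    rng = np.random.default_rng(spec.seed)
    k, n = len(spec.promoters), spec.n_samples
    rank_corr = (
        np.asarray(spec.rank_correlation, dtype=float)
        if spec.rank_correlation is not None
        else np.eye(k)
    )
    latent_corr = _latent_correlation(rank_corr)
    z = _sample_copula(rng, latent_corr, n)

    sample_ids = [f"sample_{j:04d}" for j in range(n)]
    categories = ["tissue", "primary cell", "cell line"]
    meta = pd.DataFrame(
        {
            "species": ["synthetic"] * n,
            "category": [categories[j % 3] for j in range(n)],
            "stage": [f"stage_{j % 5}" for j in range(n)],
        },
        index=sample_ids,
    )

    tpm = np.exp(marginal_sigma * z)
    zero_mask = np.zeros_like(tpm, dtype=bool)
    for i, p in enumerate(spec.promoters):
        if p.restricted_fraction > 0:
            cutoff = np.quantile(z[i], p.restricted_fraction)
            zero_mask[i] = z[i] < cutoff
            tpm[i, zero_mask[i]] = 0.0
        tpm[i] *= p.max_tpm / tpm[i].max()

    totals = pd.Series(
        rng.integers(spec.library_size_range[0], spec.library_size_range[1], size=n),
        index=sample_ids,
        dtype=float,
    )
    counts = np.rint(tpm * totals.to_numpy() / 1e6)
    row_ids = [f"prom_{i}" for i in range(k)]
    raw = ExpressionTable(
        pd.DataFrame(counts, index=row_ids, columns=sample_ids), meta
    )
    truth = {
        "tpm": pd.DataFrame(tpm, index=row_ids, columns=sample_ids),
        "rank_correlation_target": rank_corr,
        "latent_correlation": latent_corr,
        "library_totals": totals,
        "zero_mask": pd.DataFrame(zero_mask, index=row_ids, columns=sample_ids),
    }
    return raw, totals, truth


def _sharp_counts(rng: np.random.Generator, total: int, width: int) -> np.ndarray:
    """Counts over ``width`` positions with >= 0.6 of tags at one mode."""
    frac = rng.uniform(0.65, 0.85)
    mode = int(rng.integers(width // 4, 3 * width // 4))
    counts = np.zeros(width, dtype=np.int64)
    counts[mode] = max(1, int(round(frac * total)))
    rest = total - counts[mode]
    if rest > 0:
        counts += rng.multinomial(rest, np.full(width, 1.0 / width))
    return counts


def _broad_counts(rng: np.random.Generator, total: int, width: int) -> np.ndarray:
    """Counts spread so no 5-nt window holds > 0.4 of the cluster total."""
    for _ in range(100):
        weights = rng.dirichlet(np.full(width, 5.0))
        counts = rng.multinomial(total, weights)
        profile = TagProfile("tmp", "+", np.arange(width), counts.astype(float))
        _, best5 = densest_window(profile, 5)
        if best5 <= 0.4 * counts.sum():
            return counts
    raise RuntimeError("could not construct a broad profile (contract violation)")


def simulate_profiles(
    spec: SimulationSpec,
) -> tuple[list[CtssRecord], dict[str, str]]:
    """Per-nucleotide CTSS records for every promoter plus truth labels."""
    if spec.tags_per_profile <= 0:
        raise ValueError("tags_per_profile must be positive")
    rng = np.random.default_rng(spec.seed + 1)
    records: list[CtssRecord] = []
    truth: dict[str, str] = {}
    for i, p in enumerate(spec.promoters):
        iv = spec.promoter_interval(i)
        width = iv.width
        if p.shape == SHARP:
            counts = _sharp_counts(rng, spec.tags_per_profile, width)
        else:
            counts = _broad_counts(rng, spec.tags_per_profile, width)
        for offset, count in enumerate(counts):
            if count > 0:
                pos = iv.start + offset
                records.append(
                    CtssRecord(GenomicInterval(iv.chrom, pos, pos + 1, iv.strand), int(count))
                )
        truth[f"prom_{i}"] = p.shape
    return records, truth


def _point_feature(chrom: str, center: int, half_width: int, name: str) -> BedFeature:
    return BedFeature(
        GenomicInterval(chrom, max(0, center - half_width), center + half_width + 1),
        name,
    )


def simulate_annotations(spec: SimulationSpec) -> dict[str, list[BedFeature]]:
    """Annotation interval sets at the offsets each promoter specifies."""
    out: dict[str, list[BedFeature]] = {
        "refseq": [],
        "tata": [],
        "cpg": [],
        "h3k4me3": [],
        "h3k27ac": [],
    }
    for i, p in enumerate(spec.promoters):
        c = spec.promoter_center(i)
        chrom = SIM_CHROM
        ref = c + p.refseq_offset
        out["refseq"].append(
            BedFeature(GenomicInterval(chrom, ref, ref + 1, "+"), f"{p.gene}_tss_{i}")
        )
        if p.tata_offset is not None:
            out["tata"].append(_point_feature(chrom, c + p.tata_offset, 4, f"tata_{i}"))
        if p.cpg_offset is not None:
            out["cpg"].append(_point_feature(chrom, c + p.cpg_offset, 300, f"cpg_{i}"))
        if p.h3k4me3_offset is not None:
            out["h3k4me3"].append(
                _point_feature(chrom, c + p.h3k4me3_offset, 400, f"h3k4me3_{i}")
            )
        if p.h3k27ac_offset is not None:
            out["h3k27ac"].append(
                _point_feature(chrom, c + p.h3k27ac_offset, 400, f"h3k27ac_{i}")
            )
    return out


def calibrated_partner(
    rng: np.random.Generator, x: np.ndarray, target_r: float
) -> np.ndarray:
    """A non-negative vector whose population Pearson correlation with
    ``x`` is ``target_r``: r·z_x + sqrt(1-r²)·ε, shifted to min 0."""
    z = (x - x.mean()) / x.std()
    y = target_r * z + np.sqrt(1.0 - target_r**2) * rng.standard_normal(x.size)
    return y - y.min()


def simulate_enhancers(
    spec: SimulationSpec, promoter_tpm: ExpressionTable
) -> tuple[list[BedFeature], ExpressionTable, list[dict]]:
    """Enhancer intervals + expression with planted links.

    Linked enhancers are scaled target-promoter signal plus Gaussian noise
    calibrated to the target Pearson r; null enhancers are independent
    log-normal noise.  Truth lists, per enhancer, the target promoter,
    distance, and target r (None for null).
    """
    rng = np.random.default_rng(spec.seed + 2)
    features: list[BedFeature] = []
    rows: list[np.ndarray] = []
    ids: list[str] = []
    truth: list[dict] = []
    for j, e in enumerate(spec.enhancers):
        pid = f"prom_{e.target_promoter}"
        center = spec.promoter_center(e.target_promoter)
        mid = center + e.distance
        iv = GenomicInterval(SIM_CHROM, max(0, mid - 200), mid + 200)
        name = f"enh_{j}"
        features.append(BedFeature(iv, name))
        x = promoter_tpm.row(pid)
        if e.target_r is None:
            y = np.exp(1.5 * rng.standard_normal(x.size))
        else:
            y = calibrated_partner(rng, x, e.target_r)
        rows.append(y)
        ids.append(name)
        truth.append(
            {
                "enhancer_id": name,
                "promoter_id": pid,
                "distance": abs(center - iv.midpoint),
                "target_r": e.target_r,
            }
        )
    table = ExpressionTable(
        pd.DataFrame(rows, index=ids, columns=promoter_tpm.sample_ids),
        promoter_tpm.sample_meta,
    )
    return features, table, truth


def _split_posterior(total: float) -> list[float]:
    """Split a planted summed posterior into site posteriors in [0.2, 1]."""
    out = []
    remaining = total
    while remaining > 1.0 + 1e-9:
        out.append(0.95)
        remaining -= 0.95
    out.append(max(0.2, round(remaining, 6)))
    return out


def simulate_tfbs(
    spec: SimulationSpec,
) -> tuple[list[TfbsSiteRecord], dict[str, np.ndarray], dict]:
    """Focal-promoter site lists, per-TF background count populations, truth.

    Negative controls: every focal promoter also gets one site below the
    0.2 retention cutoff and one high-posterior site outside the ±500-bp
    window; neither may contribute to any count.
    """
    t = spec.tfbs
    rng = np.random.default_rng(spec.seed + 3)
    backgrounds = {
        tf: rng.exponential(t.background_mean, t.background_n) for tf in t.tfs
    }
    sites: list[TfbsSiteRecord] = []
    planted: dict[tuple[str, str], float] = {}
    for idx, tf, added in t.planted:
        center = spec.promoter_center(idx)
        offsets = np.linspace(-400, 400, num=len(_split_posterior(added)), dtype=int)
        for off, post in zip(offsets, _split_posterior(added)):
            pos = center + int(off)
            sites.append(TfbsSiteRecord(tf, GenomicInterval(SIM_CHROM, pos - 5, pos + 5), post))
        planted[(f"prom_{idx}", tf)] = added
    for i in range(len(spec.promoters)):
        center = spec.promoter_center(i)
        tf = t.tfs[i % len(t.tfs)]
        # below retention cutoff, inside window
        sites.append(
            TfbsSiteRecord(tf, GenomicInterval(SIM_CHROM, center + 95, center + 105), 0.1)
        )
        # retained posterior, outside the ±500 bp window
        far = center + 800
        sites.append(TfbsSiteRecord(tf, GenomicInterval(SIM_CHROM, far - 5, far + 5), 0.9))
    truth = {"planted": planted, "background_n": t.background_n}
    return sites, backgrounds, truth


def write_world(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialize the complete synthetic input set as the plain-text files
    the pipeline reads.  Returns the path of every written file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    raw, totals, expr_truth = simulate_expression(spec)
    records = spec.promoter_records()
    paths["raw_counts"] = out_dir / "raw_counts.tsv"
    raw.to_tsv(paths["raw_counts"])
    paths["library_totals"] = out_dir / "library_totals.tsv"
    gio.write_library_totals(totals, paths["library_totals"])

    paths["promoters"] = out_dir / "promoters.bed"
    gio.write_bed(
        [BedFeature(r.interval, r.id) for r in records], paths["promoters"]
    )
    paths["promoter_map"] = out_dir / "promoter_map.tsv"
    gio.write_promoter_map(
        {
            gene: [r.id for r in records if r.gene == gene]
            for gene in dict.fromkeys(r.gene for r in records)
        },
        paths["promoter_map"],
    )

    ctss, _shape_truth = simulate_profiles(spec)
    paths["ctss"] = out_dir / "ctss.bed"
    gio.write_ctss(ctss, paths["ctss"])

    ann = simulate_annotations(spec)
    for key in ("refseq", "tata", "cpg", "h3k4me3", "h3k27ac"):
        paths[key] = out_dir / f"{key}.bed"
        gio.write_bed(ann[key], paths[key])

    tpm_truth = ExpressionTable(expr_truth["tpm"], raw.sample_meta)
    enh_features, enh_table, _link_truth = simulate_enhancers(spec, tpm_truth)
    paths["enhancers"] = out_dir / "enhancers.bed"
    gio.write_bed(enh_features, paths["enhancers"])
    paths["enhancer_expression"] = out_dir / "enhancer_expression.tsv"
    enh_table.to_tsv(paths["enhancer_expression"])

    sites, backgrounds, _tfbs_truth = simulate_tfbs(spec)
    paths["tfbs_sites"] = out_dir / "tfbs_sites.tsv"
    gio.write_tfbs_sites(sites, paths["tfbs_sites"])
    paths["tfbs_background"] = out_dir / "tfbs_background.tsv"
    gio.write_background_counts(backgrounds, paths["tfbs_background"])
    return paths
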