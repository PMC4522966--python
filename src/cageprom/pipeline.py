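"""End-to-end orchestration: normalize → filter → name/novelty → shape →
annotate → correlate → link enhancers → TFBS, with a run manifest.

Every stage writes a TSV under the output directory; the manifest records
the config snapshot, SHA-256 digests of every input, per-stage row counts
and all warnings.  A rerun against unchanged inputs (identical digests
and config) reuses the existing outputs; any change reruns the whole
pipeline, which keeps resumption conservative and deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .annotation import (
    classify_cpg,
    classify_regulatory_regions,
    classify_tata,
    promoter_context,
)
from .config import AnalysisConfig
from .correlation import correlation_matrix, matrix_to_long
from .enhancers import bonferroni_select, candidate_pairs, test_links
from .expression import (
    PromoterRecord,
    assign_promoter_names,
    classify_novelty,
    filter_detected,
    tpm_normalize,
)
from .io import BedFeature, ExpressionTable
from .shape import classify_shape, profile_from_ctss
from .tfbs import retain_sites, shared_tf_report, site_count, tail_probability

__all__ = ["PipelineInputs", "RunManifest", "run_all"]

logger = logging.getLogger("cageprom")

PACKAGE_VERSION = "0.1.0"


@dataclass(frozen=True)
class PipelineInputs:
    """Paths to every external input of a full run."""

    raw_counts: Path
    library_totals: Path
    promoters: Path  # BED6, name = promoter row id
    promoter_map: Path  # TSV gene -> row id
    ctss: Path
    refseq: Path
    tata: Path
    cpg: Path
    h3k4me3: Path
    h3k27ac: Path
    enhancers: Path | None = None
    enhancer_expression: Path | None = None
    tfbs_sites: Path | None = None
    tfbs_background: Path | None = None

    def paths(self) -> dict[str, Path]:
        return {
            k: Path(v)
            for k, v in dataclasses.asdict(self).items()
            if v is not None
        }


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    version: str
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(path.read_text()))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _resumable(manifest_path: Path, digests: dict, config: dict, out_dir: Path) -> RunManifest | None:
    if not manifest_path.exists():
        return None
    try:
        prev = RunManifest.load(manifest_path)
    except (json.JSONDecodeError, TypeError):
        return None
    if prev.input_digests != digests or prev.config != config:
        return None
    if all((out_dir / name).exists() for name in prev.outputs):
        logger.info("inputs unchanged; reusing existing outputs")
        return prev
    return None


def run_all(
    inputs: PipelineInputs,
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "results",
) -> RunManifest:
    """Run every stage of the promoterome analysis; returns the manifest."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for name, path in inputs.paths().items():
        if not path.exists():
            raise FileNotFoundError(f"stage inputs: missing {name} file {path}")
    digests = {k: _digest(p) for k, p in inputs.paths().items()}
    manifest_path = out_dir / "manifest.json"
    prev = _resumable(manifest_path, digests, config.to_dict(), out_dir)
    if prev is not None:
        return prev

    manifest = RunManifest(config.to_dict(), digests, PACKAGE_VERSION)
    caught: list[str] = []

    def _write(name: str, df: pd.DataFrame, index: bool = False, **kw) -> None:
        df.to_csv(out_dir / name, sep="\t", index=index, float_format="%.6g", **kw)
        manifest.outputs.append(name)

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- normalize -------------------------------------------------
        stage = "normalize"
        try:
            raw = gio.read_expression_table(inputs.raw_counts)
            totals = gio.read_library_totals(inputs.library_totals)
            tpm = tpm_normalize(raw, totals)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        tpm.to_tsv(out_dir / "expression_tpm.tsv")
        manifest.outputs.append("expression_tpm.tsv")
        manifest.row_counts[stage] = tpm.shape[0]

        # --- filter ----------------------------------------------------
        stage = "filter"
        detected = filter_detected(tpm, config.tpm_detect_threshold)
        discarded = tpm.shape[0] - detected.shape[0]
        logger.info("filter: discarded %d of %d clusters (<= %g TPM everywhere)",
                    discarded, tpm.shape[0], config.tpm_detect_threshold)
        detected.to_tsv(out_dir / "expression_detected.tsv")
        manifest.outputs.append("expression_detected.tsv")
        manifest.row_counts[stage] = detected.shape[0]

        # --- name / novelty --------------------------------------------
        stage = "name"
        try:
            prom_bed = gio.read_bed(inputs.promoters)
            prom_map = gio.read_promoter_map(inputs.promoter_map)
            refseq = gio.read_bed(inputs.refseq)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        bed_by_id = {f.name: f for f in prom_bed}
        id_to_gene = {rid: gene for gene, rids in prom_map.items() for rid in rids}
        promoters: list[PromoterRecord] = []
        for rid in detected.row_ids:
            if rid not in bed_by_id or rid not in id_to_gene:
                raise RuntimeError(f"stage {stage} failed: no interval/gene for row {rid!r}")
            promoters.append(PromoterRecord(rid, id_to_gene[rid], bed_by_id[rid].interval))
        refseq_by_gene: dict[str, list[int]] = {}
        for f in refseq:
            gene = f.name.rsplit("_tss", 1)[0] if "_tss" in f.name else f.name
            refseq_by_gene.setdefault(gene, []).append(f.interval.start)
        for p in promoters:
            refs = refseq_by_gene.get(p.gene)
            if refs:
                p.novelty = classify_novelty(p, refs, config.novelty_distance)
        rename: dict[str, str] = {}
        for gene in dict.fromkeys(p.gene for p in promoters):
            gene_proms = [p for p in promoters if p.gene == gene]
            rename.update(assign_promoter_names(gene, gene_proms, detected))
        for p in promoters:
            p.id = rename[p.id]
        detected = detected.rename_rows(rename)
        prom_df = pd.DataFrame(
            {
                "promoter": [p.id for p in promoters],
                "gene": [p.gene for p in promoters],
                "chrom": [p.interval.chrom for p in promoters],
                "start": [p.interval.start for p in promoters],
                "end": [p.interval.end for p in promoters],
                "strand": [p.interval.strand for p in promoters],
                "center": [p.center for p in promoters],
                "novelty": [p.novelty for p in promoters],
            }
        )
        _write("promoters.tsv", prom_df)
        manifest.row_counts[stage] = len(promoters)

        # --- shape -----------------------------------------------------
        stage = "shape"
        ctss = gio.read_ctss(inputs.ctss)
        shape_rows = []
        shapes: dict[str, str] = {}
        for p in promoters:
            profile = profile_from_ctss(p.id, p.interval, ctss)
            if profile.total <= 0:
                caught.append(f"shape: no CTSS signal for {p.id}; skipped")
                continue
            call = classify_shape(profile, config)
            shapes[p.id] = call.shape
            shape_rows.append(dataclasses.asdict(call))
        _write("shapes.tsv", pd.DataFrame(shape_rows))
        manifest.row_counts[stage] = len(shape_rows)

        # --- annotate ---------------------------------------------------
        stage = "annotate"
        tata = gio.read_bed(inputs.tata)
        cpg = gio.read_bed(inputs.cpg)
        k4 = gio.read_bed(inputs.h3k4me3)
        k27 = gio.read_bed(inputs.h3k27ac)
        ann_rows = []
        for p in promoters:
            ann_rows.append(
                {
                    "promoter": p.id,
                    "TATA": classify_tata(p, tata, config),
                    "CpG": classify_cpg(p, cpg, config),
                    "shape": shapes.get(p.id, "NA"),
                }
            )
        _write("promoter_annotation.tsv", pd.DataFrame(ann_rows))
        regions = classify_regulatory_regions(k4, k27)
        gio.write_bed(
            [BedFeature(r.interval, r.label) for r in regions],
            out_dir / "regulatory_regions.bed",
        )
        manifest.outputs.append("regulatory_regions.bed")
        ctx_rows = []
        for p in promoters:
            ctx = promoter_context(p, regions, config.enhancer_max_distance)
            for label, hit in ctx.items():
                if hit is not None:
                    region, dist = hit
                    ctx_rows.append(
                        {"promoter": p.id, "label": label, "distance": dist,
                         "region_start": region.interval.start,
                         "region_end": region.interval.end}
                    )
        _write("promoter_context.tsv", pd.DataFrame(ctx_rows))
        manifest.row_counts[stage] = len(ann_rows)

        # --- correlate ---------------------------------------------------
        stage = "correlate"
        if detected.shape[0] >= 2:
            mat = correlation_matrix(detected, "spearman")
            out = mat.round(2)
            out.to_csv(out_dir / "correlation_spearman.tsv", sep="\t", index_label="promoter")
            manifest.outputs.append("correlation_spearman.tsv")
            pairs_long = matrix_to_long(detected, "spearman")
            _write(
                "correlation_pairs.tsv",
                pd.DataFrame([dataclasses.asdict(r) for r in pairs_long]),
            )
            manifest.row_counts[stage] = len(pairs_long)

        # --- link enhancers ----------------------------------------------
        stage = "link-enhancers"
        if inputs.enhancers is not None:
            if inputs.enhancer_expression is None:
                raise RuntimeError(f"stage {stage} failed: enhancer expression table missing")
            enh_bed = gio.read_bed(inputs.enhancers)
            enh_expr = gio.read_expression_table(inputs.enhancer_expression)
            pairs = candidate_pairs(promoters, enh_bed, config.enhancer_max_distance)
            links = test_links(pairs, detected, enh_expr)
            bonferroni_select(links, config.link_alpha)
            _write(
                "enhancer_links.tsv",
                pd.DataFrame([dataclasses.asdict(l) for l in links]),
            )
            manifest.row_counts[stage] = len(links)

        # --- tfbs ---------------------------------------------------------
        stage = "tfbs"
        if inputs.tfbs_sites is not None:
            sites = gio.read_tfbs_sites(inputs.tfbs_sites)
            retained = retain_sites(sites, config.posterior_min)
            backgrounds = (
                gio.read_background_counts(inputs.tfbs_background)
                if inputs.tfbs_background is not None
                else {}
            )
            tf_rows = []
            tf_names = sorted(backgrounds) if backgrounds else sorted({s.tf for s in retained})
            for p in promoters:
                counts = site_count(p, retained, config.tfbs_window, tfs=tf_names)
                for tf in tf_names:
                    c = counts[tf]
                    row = {"promoter": p.id, "tf": tf, "site_count": c.site_count,
                           "n_sites": c.n_sites_retained}
                    if tf in backgrounds:
                        sig = tail_probability(c, backgrounds[tf], observed_included=False)
                        row["tail_prob"] = sig.tail_prob
                        row["rendered"] = f"{c.site_count:.1f} (p = {sig.tail_prob:.2g})"
                    tf_rows.append(row)
            _write("tfbs_counts.tsv", pd.DataFrame(tf_rows))
            gene_promoters: dict[str, list[PromoterRecord]] = {}
            for p in promoters:
                gene_promoters.setdefault(p.gene, []).append(p)
            report = shared_tf_report(gene_promoters, sites, config,
                                      backgrounds if backgrounds else None)
            _write(
                "tfbs_shared.tsv",
                pd.DataFrame(
                    [{"gene": g, "tfs": ",".join(sorted(tfs))}
                     for g, tfs in report["per_gene"].items()]
                    + [{"gene": "__common__", "tfs": ",".join(sorted(report["common"]))}]
                ),
            )
            manifest.row_counts[stage] = len(tf_rows)

        caught.extend(f"{w.category.__name__}: {w.message}" for w in wrec)

    manifest.warnings = caught
    manifest.save(manifest_path)
    manifest.outputs.append("manifest.json")
    return manifest
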