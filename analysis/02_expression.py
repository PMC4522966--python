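#!/usr/bin/env python
"""Normalize tag counts to TPM, apply the 5-TPM detection filter, assign
promoter names and novelty, and summarize per-gene expressed-sample
fractions at the 1-TPM cutoff."""

import sys
from pathlib import Path

import pandas as pd

from cageprom import AnalysisConfig
from cageprom.expression import (
    PromoterRecord,
    assign_promoter_names,
    classify_novelty,
    expressed_sample_fraction,
    filter_detected,
    tpm_normalize,
)
from cageprom import io as gio

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = Path(__file__).resolve().parents[1] / "scratch" / "world"


def main() -> None:
    cfg = AnalysisConfig(background_n=10_000)
    raw = gio.read_expression_table(WORLD / "raw_counts.tsv")
    totals = gio.read_library_totals(WORLD / "library_totals.tsv")
    tpm = tpm_normalize(raw, totals)
    detected = filter_detected(tpm, cfg.tpm_detect_threshold)
    print(f"{detected.shape[0]} of {tpm.shape[0]} TSS clusters exceed "
          f"{cfg.tpm_detect_threshold} TPM in at least one of {tpm.shape[1]} samples",
          file=sys.stderr)

    bed = {f.name: f for f in gio.read_bed(WORLD / "promoters.bed")}
    gene_map = gio.read_promoter_map(WORLD / "promoter_map.tsv")
    refseq = gio.read_bed(WORLD / "refseq.bed")
    refs_by_gene: dict[str, list[int]] = {}
    for f in refseq:
        refs_by_gene.setdefault(f.name.rsplit("_tss", 1)[0], []).append(f.interval.start)

    promoters = []
    for gene, rids in gene_map.items():
        for rid in rids:
            p = PromoterRecord(rid, gene, bed[rid].interval)
            p.novelty = classify_novelty(p, refs_by_gene[gene], cfg.novelty_distance)
            promoters.append(p)
    rename = {}
    for gene in gene_map:
        rename.update(assign_promoter_names(
            gene, [p for p in promoters if p.gene == gene], detected))
    for p in promoters:
        p.id = rename[p.id]
    detected = detected.rename_rows(rename)
    detected.to_tsv(ROOT / "expression_tpm_detected.tsv")

    rows = []
    named_map = {g: [rename[r] for r in rids] for g, rids in gene_map.items()}
    for gene in named_map:
        count, frac = expressed_sample_fraction(
            detected, gene, named_map, cfg.tpm_expressed_threshold)
        rows.append({"gene": gene, "samples_expressing": count,
                     "fraction": round(frac, 3)})
        print(f"{gene}: expressed >1 TPM in {count} samples ({frac:.0%})",
              file=sys.stderr)
    pd.DataFrame(rows).to_csv(ROOT / "expressed_fraction.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"promoter": p.id, "gene": p.gene, "novelty": p.novelty,
          "center": p.center} for p in promoters]
    ).to_csv(ROOT / "promoters_named.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
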