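#!/usr/bin/env python
"""Annotate promoters with TATA-box and CpG-island status and classify
H3K4me3/H3K27ac peaks into active promoters, active enhancers and dual
regions; report the nearest region of each class per promoter."""

import sys
from pathlib import Path

import pandas as pd

from cageprom import AnalysisConfig
from cageprom import io as gio
from cageprom.annotation import (
    classify_cpg,
    classify_regulatory_regions,
    classify_tata,
    promoter_context,
)
from cageprom.expression import PromoterRecord

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = Path(__file__).resolve().parents[1] / "scratch" / "world"


def main() -> None:
    cfg = AnalysisConfig(background_n=10_000)
    named = pd.read_csv(ROOT / "promoters_named.tsv", sep="\t")
    bed = list(gio.read_bed(WORLD / "promoters.bed"))
    tata = gio.read_bed(WORLD / "tata.bed")
    cpg = gio.read_bed(WORLD / "cpg.bed")
    k4 = gio.read_bed(WORLD / "h3k4me3.bed")
    k27 = gio.read_bed(WORLD / "h3k27ac.bed")

    promoters = [
        PromoterRecord(row.promoter, row.gene, feat.interval)
        for (_, row), feat in zip(named.iterrows(), bed)
    ]
    shapes = pd.read_csv(ROOT / "promoter_shapes.tsv", sep="\t").set_index("promoter_id")
    rows = [
        {"promoter": p.id,
         "TATA": classify_tata(p, tata, cfg),
         "CpG": classify_cpg(p, cpg, cfg),
         "shape": shapes.loc[p.id, "shape"]}
        for p in promoters
    ]
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "promoter_annotation.tsv", sep="\t", index=False)
    print(table.to_string(index=False), file=sys.stderr)

    regions = classify_regulatory_regions(k4, k27)
    gio.write_bed(
        [gio.BedFeature(r.interval, r.label) for r in regions],
        ROOT / "regulatory_regions.bed",
    )
    ctx_rows = []
    for p in promoters:
        for label, hit in promoter_context(p, regions, cfg.enhancer_max_distance).items():
            if hit:
                region, dist = hit
                ctx_rows.append({"promoter": p.id, "label": label,
                                 "signed_distance": dist})
    pd.DataFrame(ctx_rows).to_csv(ROOT / "promoter_context.tsv", sep="\t", index=False)
    n_enh = sum(r.label == "active_enhancer" for r in regions)
    print(f"{len(regions)} regulatory regions ({n_enh} enhancer-only)", file=sys.stderr)


if __name__ == "__main__":
    main()
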