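#!/usr/bin/env python
"""Link candidate enhancers to promoters: Pearson correlation over all
samples for every enhancer within 500 kb, Bonferroni-corrected across the
whole family of tested pairs."""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from cageprom import AnalysisConfig, read_expression_table
from cageprom import io as gio
from cageprom.enhancers import bonferroni_select, candidate_pairs, test_links
from cageprom.expression import PromoterRecord

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = Path(__file__).resolve().parents[1] / "scratch" / "world"


def main() -> None:
    cfg = AnalysisConfig(background_n=10_000)
    named = pd.read_csv(ROOT / "promoters_named.tsv", sep="\t")
    bed = list(gio.read_bed(WORLD / "promoters.bed"))
    promoters = [
        PromoterRecord(row.promoter, row.gene, feat.interval)
        for (_, row), feat in zip(named.iterrows(), bed)
    ]
    enhancers = gio.read_bed(WORLD / "enhancers.bed")
    prom_expr = read_expression_table(ROOT / "expression_tpm_detected.tsv")
    enh_expr = gio.read_expression_table(WORLD / "enhancer_expression.tsv")

    pairs = candidate_pairs(promoters, enhancers, cfg.enhancer_max_distance)
    print(f"{len(pairs)} candidate pairs within {cfg.enhancer_max_distance/1e3:.0f} kb "
          f"({len(enhancers)} enhancers, {len(promoters)} promoters)", file=sys.stderr)
    links = test_links(pairs, prom_expr, enh_expr)
    significant = bonferroni_select(links, cfg.link_alpha)
    df = pd.DataFrame([dataclasses.asdict(l) for l in links])
    df.to_csv(ROOT / "enhancer_links.tsv", sep="\t", index=False)
    print(f"{len(significant)} significant links (corrected P < {cfg.link_alpha}):",
          file=sys.stderr)
    for l in sorted(significant, key=lambda l: l.p_adj)[:10]:
        print(f"  {l.enhancer_id} -> {l.promoter_id}: r={l.r:.2f}, "
              f"{l.distance/1e3:.0f} kb, p_adj={l.p_adj:.2g}", file=sys.stderr)


if __name__ == "__main__":
    main()
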