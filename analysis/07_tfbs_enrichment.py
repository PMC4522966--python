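#!/usr/bin/env python
"""Summed-posterior TFBS counts per promoter and TF, with empirical rank
tail probabilities against the background promoter population, and the
TFs shared by all three genes."""

import sys
from pathlib import Path

import pandas as pd

from cageprom import AnalysisConfig
from cageprom import io as gio
from cageprom.expression import PromoterRecord
from cageprom.tfbs import retain_sites, shared_tf_report, site_count, tail_probability

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
    sites = gio.read_tfbs_sites(WORLD / "tfbs_sites.tsv")
    backgrounds = gio.read_background_counts(WORLD / "tfbs_background.tsv")
    retained = retain_sites(sites, cfg.posterior_min)

    rows = []
    for p in promoters:
        counts = site_count(p, retained, cfg.tfbs_window, tfs=sorted(backgrounds))
        for tf, c in counts.items():
            sig = tail_probability(c, backgrounds[tf], observed_included=False)
            rows.append({"promoter": p.id, "tf": tf,
                         "site_count": round(c.site_count, 2),
                         "tail_prob": round(sig.tail_prob, 4),
                         "rendered": f"{c.site_count:.1f} (p = {sig.tail_prob:.2g})"})
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "tfbs_enrichment.tsv", sep="\t", index=False)
    enriched = table[(table.site_count > 0) & (table.tail_prob < cfg.link_alpha)]
    print(f"{len(enriched)} promoter/TF pairs enriched at p < {cfg.link_alpha}:",
          file=sys.stderr)
    print(enriched.to_string(index=False), file=sys.stderr)

    gene_promoters: dict[str, list[PromoterRecord]] = {}
    for p in promoters:
        gene_promoters.setdefault(p.gene, []).append(p)
    report = shared_tf_report(gene_promoters, sites, cfg, backgrounds)
    for gene, tfs in report["per_gene"].items():
        print(f"{gene}: high-posterior TFs {sorted(tfs)}", file=sys.stderr)
    print(f"common to all genes: {sorted(report['common'])}", file=sys.stderr)
    pd.DataFrame(
        [{"gene": g, "tfs": ",".join(sorted(t))} for g, t in report["per_gene"].items()]
        + [{"gene": "__common__", "tfs": ",".join(sorted(report["common"]))}]
    ).to_csv(ROOT / "tfbs_shared.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
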