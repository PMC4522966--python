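#!/usr/bin/env python
"""Classify each promoter as sharp or broad from its pooled per-nucleotide
tag profile (best 5-nt window > 50% of the densest 50-bp cluster)."""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from cageprom import AnalysisConfig
from cageprom import io as gio
from cageprom.shape import classify_shape, profile_from_ctss

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = Path(__file__).resolve().parents[1] / "scratch" / "world"


def main() -> None:
    cfg = AnalysisConfig(background_n=10_000)
    ctss = gio.read_ctss(WORLD / "ctss.bed")
    named = pd.read_csv(ROOT / "promoters_named.tsv", sep="\t")
    bed = {f.name: f for f in gio.read_bed(WORLD / "promoters.bed")}
    # promoters_named carries assigned ids in world order
    rows = []
    for (_, row), rid in zip(named.iterrows(), bed):
        profile = profile_from_ctss(row.promoter, bed[rid].interval, ctss)
        call = classify_shape(profile, cfg)
        rows.append(dataclasses.asdict(call))
        print(f"{row.promoter}: {call.shape} "
              f"(dominant 5-nt fraction {call.dominant_fraction:.2f})", file=sys.stderr)
    pd.DataFrame(rows).to_csv(ROOT / "promoter_shapes.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
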