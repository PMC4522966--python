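#!/usr/bin/env python
"""Intra- and inter-gene promoter expression correlations: the full
Spearman matrix over all detected promoters, in matrix and long form."""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from cageprom import correlation_matrix, read_expression_table
from cageprom.correlation import matrix_to_long

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_expression_table(ROOT / "expression_tpm_detected.tsv")
    mat = correlation_matrix(table, "spearman")
    mat.round(2).to_csv(ROOT / "correlation_spearman.tsv", sep="\t",
                        index_label="promoter")
    pd.DataFrame(
        [dataclasses.asdict(r) for r in matrix_to_long(table, "spearman")]
    ).to_csv(ROOT / "correlation_pairs.tsv", sep="\t", index=False)
    print("promoter Spearman matrix (2 dp):", file=sys.stderr)
    print(mat.round(2).to_string(), file=sys.stderr)
    within = [mat.loc[a, b] for a in mat.index for b in mat.index
              if a < b and a.split("@")[1] == b.split("@")[1]]
    across = [mat.loc[a, b] for a in mat.index for b in mat.index
              if a < b and a.split("@")[1] != b.split("@")[1]]
    print(f"mean within-gene rho {sum(within)/len(within):.2f}; "
          f"mean cross-gene rho {sum(across)/len(across):.2f}", file=sys.stderr)


if __name__ == "__main__":
    main()
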