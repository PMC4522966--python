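import numpy as np
import pandas as pd
import pytest

from cageprom import AnalysisConfig, ExpressionTable, GenomicInterval, PromoterRecord


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig(background_n=10_000)


@pytest.fixture
def small_table() -> ExpressionTable:
    values = pd.DataFrame(
        [[0.5, 2.0, 0.0], [6.0, 1.0, 0.2], [5.0, 5.0, 5.0]],
        index=["pX", "pY", "pZ"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionTable(values)


@pytest.fixture
def plus_promoter() -> PromoterRecord:
    return PromoterRecord(
        "p1@GENE", "GENE", GenomicInterval("chr1", 10_000, 10_040, "+"), center=10_020
    )


def brute_force_spearman(x, y) -> float:
    """Independent rank oracle: explicit sort-based average ranks, then the
    covariance formula written out."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    return brute_force_pearson_r(rx, ry)


def brute_force_pearson_r(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def t_tail_two_sided(t_abs: float, df: int) -> float:
    """Two-sided t tail by numeric integration of the density."""
    import math

    from scipy.integrate import quad

    def density(u):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, t_abs, math.inf)
    return 2.0 * tail
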