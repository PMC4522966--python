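"""TPM normalization, detection filtering, novelty, naming, gene-set sums."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cageprom import (
    ExpressionTable,
    GenomicInterval,
    PromoterRecord,
    aggregate_gene_set,
    assign_promoter_names,
    classify_novelty,
    expressed_sample_fraction,
    filter_detected,
    fold_ratio,
    tpm_normalize,
)


def table(rows: dict, samples=None) -> ExpressionTable:
    df = pd.DataFrame(rows).T
    if samples is not None:
        df.columns = samples
    return ExpressionTable(df)


class TestTpmNormalize:
    @pytest.mark.parametrize(
        "raw,total,expected", [(5, 1e6, 5.0), (10, 2e7, 0.5), (0, 1e6, 0.0)]
    )
    def test_scale(self, raw, total, expected):
        t = table({"r": [raw]}, ["s"])
        out = tpm_normalize(t, pd.Series({"s": total}))
        assert out.values.iloc[0, 0] == pytest.approx(expected)

    def test_missing_or_zero_total(self):
        t = table({"r": [1.0, 2.0]}, ["s1", "s2"])
        with pytest.raises(ValueError, match="missing"):
            tpm_normalize(t, pd.Series({"s1": 1e6}))
        with pytest.raises(ValueError, match="non-positive"):
            tpm_normalize(t, pd.Series({"s1": 1e6, "s2": 0.0}))

    @given(
        st.integers(2, 6),
        st.integers(2, 5),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_column_sum_identity_on_whole_library(self, n_rows, n_samples, seed):
        # when the table covers the whole library, TPM columns sum to 1e6
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 1000, size=(n_rows, n_samples)).astype(float)
        t = ExpressionTable(
            pd.DataFrame(counts, index=[f"r{i}" for i in range(n_rows)],
                         columns=[f"s{j}" for j in range(n_samples)])
        )
        totals = pd.Series(counts.sum(axis=0), index=t.sample_ids)
        out = tpm_normalize(t, totals)
        assert np.allclose(out.values.sum(axis=0), 1e6)


class TestFilterDetected:
    def test_boundary_is_strict(self):
        t = table({"at": [5.0, 1.0], "above": [5.01, 0.0]}, ["s1", "s2"])
        out = filter_detected(t, 5.0)
        assert out.row_ids == ["above"]

    def test_threshold_zero_keeps_positive_rows(self):
        t = table({"a": [0.1, 0.0], "b": [3.0, 1.0]}, ["s1", "s2"])
        assert filter_detected(t, 0.0).row_ids == ["a", "b"]

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(1)
        t = ExpressionTable(
            pd.DataFrame(rng.exponential(5, size=(20, 10)),
                         index=[f"r{i}" for i in range(20)],
                         columns=[f"s{j}" for j in range(10)])
        )
        once = filter_detected(t, 5.0)
        assert filter_detected(once, 5.0).row_ids == once.row_ids
        stricter = filter_detected(t, 10.0)
        assert set(stricter.row_ids) <= set(once.row_ids)


class TestExpressedSampleFraction:
    def test_single_promoter(self):
        t = table({"p": [0.5, 2.0, 0.0]}, ["s1", "s2", "s3"])
        count, frac = expressed_sample_fraction(t, "G", {"G": ["p"]}, 1.0)
        assert (count, frac) == (1, pytest.approx(1 / 3))

    def test_union_counts_each_sample_once(self):
        t = table({"p1": [2.0, 0.0, 0.0], "p2": [3.0, 2.0, 0.0]}, ["s1", "s2", "s3"])
        count, _ = expressed_sample_fraction(t, "G", {"G": ["p1", "p2"]}, 1.0)
        assert count == 2

    def test_threshold_above_max_and_unknown_gene(self):
        t = table({"p": [0.5, 2.0, 0.0]}, ["s1", "s2", "s3"])
        assert expressed_sample_fraction(t, "G", {"G": ["p"]}, 100.0)[0] == 0
        with pytest.raises(KeyError):
            expressed_sample_fraction(t, "H", {"G": ["p"]}, 1.0)


class TestClassifyNovelty:
    def promoter(self, center):
        return PromoterRecord(
            "p", "G", GenomicInterval("chr1", center - 10, center + 10, "+"), center
        )

    @pytest.mark.parametrize(
        "center,refs,expected",
        [
            (11200, [10000], "novel"),    # 1200 bp downstream of the TSS
            (10500, [10000], "known"),    # exactly 500 bp: strict >
            (10000, [10000], "known"),
            (10501, [10000], "novel"),
            (10900, [10000, 10800], "known"),  # nearest of several refs
        ],
    )
    def test_rule(self, center, refs, expected):
        assert classify_novelty(self.promoter(center), refs, 500) == expected

    def test_empty_reference_set(self):
        with pytest.raises(ValueError):
            classify_novelty(self.promoter(10000), [], 500)


class TestAssignPromoterNames:
    def make(self, i, start, novelty="known"):
        return PromoterRecord(
            f"raw{i}", "G", GenomicInterval("chr1", start, start + 20, "+"),
            novelty=novelty,
        )

    def test_ordering_by_max_tpm(self):
        proms = [self.make(0, 100), self.make(1, 200)]
        t = table({"raw0": [10.0, 1.0], "raw1": [100.0, 0.0]}, ["s1", "s2"])
        names = assign_promoter_names("G", proms, t)
        assert names == {"raw1": "p1@G", "raw0": "p2@G"}

    def test_novel_get_letters(self):
        proms = [self.make(0, 100, "novel"), self.make(1, 200)]
        t = table({"raw0": [10.0], "raw1": [5.0]}, ["s1"])
        assert assign_promoter_names("G", proms, t) == {
            "raw0": "pA@G",
            "raw1": "p1@G",
        }

    def test_tie_break_leftmost_and_permutation_stability(self):
        proms = [self.make(0, 500), self.make(1, 100)]
        t = table({"raw0": [7.0], "raw1": [7.0]}, ["s1"])
        names = assign_promoter_names("G", proms, t)
        assert names["raw1"] == "p1@G" and names["raw0"] == "p2@G"
        assert assign_promoter_names("G", proms[::-1], t) == names

    def test_bijection(self):
        rng = np.random.default_rng(3)
        proms = [
            self.make(i, int(s), "novel" if i % 3 == 0 else "known")
            for i, s in enumerate(rng.integers(0, 10**6, size=12))
        ]
        t = ExpressionTable(
            pd.DataFrame(rng.exponential(10, size=(12, 4)),
                         index=[p.id for p in proms],
                         columns=list("abcd"))
        )
        names = assign_promoter_names("G", proms, t)
        assert len(set(names.values())) == len(proms)


class TestAggregateGeneSet:
    def test_sum_and_ratio(self):
        t = table({"h1a": [1.0, 2.0], "h1b": [3.0, 4.0]}, ["s1", "s2"])
        agg = aggregate_gene_set(t, ["h1a", "h1b"])
        assert agg.tolist() == [4.0, 6.0]
        ratios = fold_ratio(agg, pd.Series([2.0, 3.0], index=["s1", "s2"]))
        assert ratios["ratio"].tolist() == [2.0, 2.0]

    def test_zero_reference_flagged(self):
        agg = pd.Series([4.0], index=["s1"])
        out = fold_ratio(agg, pd.Series([0.0], index=["s1"]))
        assert np.isinf(out["ratio"].iloc[0]) and out["reference_zero"].iloc[0]

    def test_missing_row_id(self, small_table):
        with pytest.raises(KeyError):
            aggregate_gene_set(small_table, ["pX", "nope"])
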