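"""Generator contracts: determinism, planted structure, truth records."""

import numpy as np
import pandas as pd
import pytest

from cageprom import SimulationSpec, default_world_spec
from cageprom.config import AnalysisConfig
from cageprom.shape import TagProfile, classify_shape, profile_from_ctss
from cageprom.simulate import (
    EnhancerSim,
    PromoterSim,
    TfbsSim,
    calibrated_partner,
    simulate_annotations,
    simulate_enhancers,
    simulate_expression,
    simulate_profiles,
    simulate_tfbs,
    write_world,
)
from cageprom.correlation import spearman
from cageprom.io import read_ctss


def two_promoter_spec(seed, rho, n_samples=450):
    return SimulationSpec(
        seed=seed,
        n_samples=n_samples,
        promoters=(
            PromoterSim("A", "sharp", 100.0),
            PromoterSim("B", "broad", 100.0),
        ),
        rank_correlation=((1.0, rho), (rho, 1.0)),
    )


class TestSimulateExpression:
    def test_same_seed_identical_tables(self):
        a, ta, _ = simulate_expression(two_promoter_spec(5, 0.5))
        b, tb, _ = simulate_expression(two_promoter_spec(5, 0.5))
        assert a.values.equals(b.values) and ta.equals(tb)

    def test_different_seed_differs(self):
        a, _, _ = simulate_expression(two_promoter_spec(5, 0.5))
        b, _, _ = simulate_expression(two_promoter_spec(6, 0.5))
        assert not a.values.equals(b.values)

    def test_identity_target_near_zero_spearman(self):
        raw, _, truth = simulate_expression(two_promoter_spec(11, 0.0))
        rho = spearman(truth["tpm"].iloc[0], truth["tpm"].iloc[1])
        assert abs(rho) < 0.1

    def test_planted_085_recovered(self):
        raw, _, truth = simulate_expression(two_promoter_spec(12, 0.85))
        rho = spearman(truth["tpm"].iloc[0], truth["tpm"].iloc[1])
        assert rho == pytest.approx(0.85, abs=0.05)

    def test_non_psd_target_rejected(self):
        spec = SimulationSpec(
            seed=1,
            n_samples=10,
            promoters=(
                PromoterSim("A", "sharp", 10.0),
                PromoterSim("B", "sharp", 10.0),
                PromoterSim("C", "sharp", 10.0),
            ),
            rank_correlation=(
                (1.0, 0.99, -0.99),
                (0.99, 1.0, 0.99),
                (-0.99, 0.99, 1.0),
            ),
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_expression(spec)

    def test_restricted_fraction_zeroes_samples(self):
        spec = SimulationSpec(
            seed=3,
            n_samples=400,
            promoters=(PromoterSim("A", "sharp", 100.0, restricted_fraction=0.7),),
        )
        raw, _, truth = simulate_expression(spec)
        zero_frac = (truth["tpm"].iloc[0] == 0).mean()
        assert zero_frac == pytest.approx(0.7, abs=0.02)


class TestSimulateProfiles:
    def test_truth_labels_recovered_by_classifier(self, config):
        spec = default_world_spec(seed=21)
        ctss_records, truth = simulate_profiles(spec)
        grouped: dict = {}
        for r in ctss_records:
            grouped.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
        for rec in spec.promoter_records():
            profile = profile_from_ctss(rec.id, rec.interval, grouped)
            assert classify_shape(profile, config).shape == truth[rec.id]

    def test_zero_tags_rejected(self):
        spec = SimulationSpec(
            seed=1, n_samples=3,
            promoters=(PromoterSim("A", "sharp", 10.0),),
            tags_per_profile=0,
        )
        with pytest.raises(ValueError, match="tags_per_profile"):
            simulate_profiles(spec)


class TestSimulateEnhancers:
    def test_calibrated_partner_hits_target_r(self):
        rng = np.random.default_rng(9)
        x = rng.exponential(10, size=450)
        for target in (0.8, 0.43, -0.5):
            y = calibrated_partner(np.random.default_rng(10), x, target)
            r = np.corrcoef(x, y)[0, 1]
            assert r == pytest.approx(target, abs=0.05)
            assert (y >= 0).all()

    def test_null_enhancer_and_distances(self):
        spec = two_promoter_spec(30, 0.3)
        spec = SimulationSpec(
            **{**spec.__dict__, "enhancers": (
                EnhancerSim(-7_000, 0.8),
                EnhancerSim(600_000, 0.9),
                EnhancerSim(10_000, None),
            )}
        )
        raw, _, truth = simulate_expression(spec)
        from cageprom.io import ExpressionTable
        tpm = ExpressionTable(truth["tpm"], raw.sample_meta)
        feats, table, links = simulate_enhancers(spec, tpm)
        assert links[0]["distance"] == pytest.approx(7_000, abs=1)
        assert links[1]["distance"] == pytest.approx(600_000, abs=1)
        assert links[2]["target_r"] is None
        r_null = np.corrcoef(tpm.row("prom_0"), table.row("enh_2"))[0, 1]
        assert abs(r_null) < 0.15


class TestSimulateTfbs:
    def test_planted_and_negative_controls(self, config):
        spec = SimulationSpec(
            seed=8, n_samples=3,
            promoters=(PromoterSim("A", "sharp", 10.0),),
            tfbs=TfbsSim(planted=((0, "NFY", 1.9),)),
        )
        sites, backgrounds, truth = simulate_tfbs(spec)
        from cageprom.tfbs import retain_sites, site_count
        retained = retain_sites(sites, config.posterior_min)
        rec = spec.promoter_records()[0]
        counts = site_count(rec, retained, config.tfbs_window, tfs=["NFY"])
        # the sub-0.2 and the out-of-window control sites must not leak in
        assert counts["NFY"].site_count == pytest.approx(1.9, abs=1e-6)
        assert all(len(v) == 10_000 for v in backgrounds.values())

    def test_background_too_small_rejected(self):
        with pytest.raises(ValueError, match="background_n"):
            TfbsSim(background_n=50)


class TestWriteWorld:
    def test_same_seed_byte_identical_files(self, tmp_path):
        p1 = write_world(default_world_spec(seed=4, n_samples=40), tmp_path / "w1")
        p2 = write_world(default_world_spec(seed=4, n_samples=40), tmp_path / "w2")
        assert set(p1) == set(p2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_annotation_offsets_respected(self):
        spec = SimulationSpec(
            seed=2, n_samples=3,
            promoters=(PromoterSim("A", "sharp", 10.0, tata_offset=-30, cpg_offset=None),),
        )
        ann = simulate_annotations(spec)
        (tata,) = ann["tata"]
        center = spec.promoter_center(0)
        assert tata.interval.start == center - 30 - 4
        assert ann["cpg"] == []
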