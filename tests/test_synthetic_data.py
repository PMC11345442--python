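import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eccdna_charter import synthetic_data as sd
from eccdna_charter.formats import read_genome_fasta


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


class TestGenome:
    def test_uniform_target_realized_gc(self):
        cfg = sd.SimConfig(seed=1, n_chrom=1, chrom_length=100_000,
                           gc_landscape=np.array([0.5]))
        g = sd.generate_genome(cfg)
        assert 0.47 <= gc_fraction(g.sequences["chr1"]) <= 0.53

    def test_all_gc_boundary(self):
        cfg = sd.SimConfig(seed=1, n_chrom=1, chrom_length=5_000,
                           gc_landscape=np.array([1.0]))
        g = sd.generate_genome(cfg)
        assert set(g.sequences["chr1"]) <= {"G", "C"}

    def test_determinism(self):
        cfg = sd.SimConfig(seed=9, n_chrom=2, chrom_length=50_000)
        assert sd.generate_genome(cfg).sequences == sd.generate_genome(cfg).sequences

    def test_window_gc_tracks_target(self):
        cfg = sd.SimConfig(seed=2, n_chrom=1, chrom_length=200_000,
                           gc_landscape=np.array([0.4]))
        g = sd.generate_genome(cfg)
        seq = g.sequences["chr1"]
        for s in range(0, 200_000, 20_000):  # 10-kb+ windows near target
            assert abs(gc_fraction(seq[s : s + 20_000]) - 0.4) < 0.03


class TestAnnotation:
    def test_repeat_fraction_on_target(self, small_genome, small_annotation):
        rep = small_annotation.features[small_annotation.features["gene_id"] == ""]
        frac = (rep["end"] - rep["start"]).sum() / small_genome.total_length
        assert abs(frac - 0.525) < 0.02

    def test_zero_repeat_fraction(self):
        cfg = sd.SimConfig(seed=1, n_chrom=1, chrom_length=100_000, repeat_fraction=0.0)
        g = sd.generate_genome(cfg)
        ann = sd.generate_annotation(g, cfg)
        assert (ann.features["gene_id"] != "").all()

    def test_gene_gradient_monotone_in_expectation(self):
        total = np.zeros(10)
        for seed in range(20):
            cfg = sd.SimConfig(seed=seed, n_chrom=1, chrom_length=1_000_000,
                               gene_density_range=(5.0, 50.0), repeat_fraction=0.0)
            g = sd.generate_genome(cfg)
            ann = sd.generate_annotation(g, cfg)
            genes = ann.subset(["gene"])
            total += np.bincount(genes["start"] // 100_000, minlength=10)
        rho, _ = stats.spearmanr(np.arange(10), total)
        assert rho > 0.8

    def test_infeasible_density_raises(self):
        cfg = sd.SimConfig(seed=1, n_chrom=1, chrom_length=100_000,
                           gene_density_range=(500.0, 500.0))
        g = sd.generate_genome(cfg)
        with pytest.raises(ValueError, match="infeasible"):
            sd.generate_annotation(g, cfg)


class TestCatalogs:
    def test_unbiased_config_has_no_gc_excess(self):
        cfg = sd.SimConfig(seed=3, n_chrom=2, chrom_length=500_000, gc_bias=0.0,
                           density_coupling=(0.0, 0.0), group_profile_tilt=0.0,
                           n_samples=1, n_high=1, abundance_split=(10_000, 10_000))
        g = sd.generate_genome(cfg)
        ann = sd.generate_annotation(g, cfg)
        cats, _ = sd.generate_eccdna_catalogs(g, ann, cfg)
        from eccdna_charter.sequence_context import GenomeGC

        idx = GenomeGC(g)
        rec = cats[0].records
        locus = [idx.interval_gc(r.chrom, r.start, r.end) for r in rec.itertuples()]
        assert abs(np.mean(locus) - idx.genome_gc()) < 0.01

    def test_h_catalogs_dominate_l(self, small_catalogs):
        cats, truth = small_catalogs
        sizes = {c.sample_id: len(c) for c in cats}
        h = [sizes[s] for s, g in truth.group_labels.items() if g == "H"]
        l = [sizes[s] for s, g in truth.group_labels.items() if g == "L"]
        assert min(h) > max(l)

    def test_modal_length_bin_below_100bp(self, small_catalogs):
        lengths = np.concatenate([c.lengths for c in small_catalogs[0]])
        counts = np.bincount(np.minimum(lengths // 100, 50))
        assert counts.argmax() == 0

    def test_determinism(self, small_genome, small_annotation):
        cfg = sd.SimConfig(seed=7, n_chrom=2, chrom_length=200_000,
                           n_samples=2, n_high=1, abundance_split=(500, 100))
        a, _ = sd.generate_eccdna_catalogs(small_genome, small_annotation, cfg)
        b, _ = sd.generate_eccdna_catalogs(small_genome, small_annotation, cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.records, y.records)

    def test_truth_table_weight_recomputable(self, small_genome, small_annotation):
        cfg = sd.SimConfig(seed=7, n_chrom=2, chrom_length=200_000,
                           n_samples=2, n_high=1, abundance_split=(300, 100))
        _, truth = sd.generate_eccdna_catalogs(small_genome, small_annotation, cfg)
        recomputed = sd.placement_weights(small_genome, small_annotation, cfg)
        merged = truth.placement_intensity.merge(
            recomputed, on=["chrom", "window_start"], suffixes=("_t", "_r")
        )
        assert np.allclose(merged["weight_L"], merged["weight"], atol=1e-9)
        tilted = merged["weight"] * merged["chrom"].map(truth.chrom_tilt)
        assert np.allclose(merged["weight_H"], tilted, atol=1e-9)


class TestCopyNumber:
    def test_zero_aberrant_fraction_gives_wgii_zero(self):
        cfg = sd.SimConfig(seed=1, n_chrom=3, chrom_length=100_000,
                           wgii_high=0.0, wgii_low=0.0, wgii_noise=0.0,
                           n_samples=4, n_high=2)
        from eccdna_charter.genome_instability import compute_wgii

        for cn in sd.generate_cn_segments(cfg):
            assert compute_wgii(cn).wgii == 0.0

    def test_group_targets_separate(self):
        cfg = sd.SimConfig(seed=2, n_chrom=3, chrom_length=100_000,
                           wgii_high=0.6, wgii_low=0.1, n_samples=18, n_high=9)
        from eccdna_charter.genome_instability import compute_wgii

        w = [compute_wgii(c).wgii for c in sd.generate_cn_segments(cfg)]
        assert np.mean(w[:9]) - np.mean(w[9:]) > 0.3

    def test_segments_tile_chromosomes(self):
        cfg = sd.SimConfig(seed=3, n_chrom=2, chrom_length=50_000,
                           n_samples=2, n_high=1)
        for cn in sd.generate_cn_segments(cfg):
            seg = cn.segments
            by_chrom = seg.groupby("chrom")
            assert ((by_chrom["end"].max() - by_chrom["start"].min()) == 50_000).all()
            assert (seg.groupby("chrom").apply(
                lambda d: (d["end"] - d["start"]).sum(), include_groups=False
            ) == 50_000).all()


class TestExpressionSurvival:
    def test_expression_deterministic(self):
        cfg = sd.SimConfig(seed=5, n_genes_expr=100, samples_per_group=10,
                           n_de_up=10, n_de_down=10)
        a, _ = sd.generate_expression(cfg)
        b, _ = sd.generate_expression(cfg)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_planted_fold_change_realized(self):
        cfg = sd.SimConfig(seed=5, n_genes_expr=500, samples_per_group=200,
                           n_de_up=50, n_de_down=50, de_fold_change=2.0)
        mat, truth = sd.generate_expression(cfg)
        h = mat.values.loc[:, mat.groups == "H"].mean(axis=1)
        l = mat.values.loc[:, mat.groups == "L"].mean(axis=1)
        up = truth[truth["direction"] == "up"]["gene"]
        ratio = (h[up] / l[up]).mean()
        assert 1.8 < ratio < 2.2

    def test_full_censoring(self):
        cfg = sd.SimConfig(seed=1, n_patients=50, censoring_rate=1.0)
        cohort, _ = sd.generate_survival_cohort(cfg)
        assert (cohort.event == 0).all()

    def test_hazard_ratio_orders_medians(self):
        worse = 0
        for seed in range(20):
            cfg = sd.SimConfig(seed=seed, n_patients=300, survival_hr=2.0,
                               censoring_rate=0.2)
            cohort, strata = sd.generate_survival_cohort(cfg)
            t = cohort.table["time"]
            hi = strata.to_numpy() == 1
            worse += t[hi].median() < t[~hi].median()
        assert worse >= 19

    def test_censoring_rate_near_target(self):
        cfg = sd.SimConfig(seed=2, n_patients=2_000, survival_hr=1.0,
                           censoring_rate=0.3)
        cohort, _ = sd.generate_survival_cohort(cfg)
        assert abs((cohort.event == 0).mean() - 0.3) < 0.05


def test_bundle_files_deterministic(tmp_path):
    cfg = sd.SimConfig(seed=4, n_chrom=2, chrom_length=100_000, n_samples=4,
                       n_high=2, abundance_split=(300, 60), n_genes_expr=200,
                       samples_per_group=20, n_de_up=20, n_de_down=20,
                       n_patients=60)
    p1 = sd.simulate_bundle(cfg, tmp_path / "a")
    p2 = sd.simulate_bundle(cfg, tmp_path / "b")
    for key in ("genome", "genes", "repeats", "cn", "expression", "survival"):
        assert p1[key].read_bytes() == p2[key].read_bytes()
    g = read_genome_fasta(p1["genome"])
    assert g.lengths == {"chr1": 100_000, "chr2": 100_000}
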