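import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score

from eccdna_charter import synthetic_data as sd
from eccdna_charter.formats import ExpressionMatrix, SurvivalCohort
from eccdna_charter.outcome_assoc import (
    build_panel,
    differential_expression,
    km_logrank,
    optimal_cutoff,
    roc_auc,
    ssgsea_score,
)


def toy_matrix():
    """10-gene, 6+6-sample fixture with hand-evaluated fold changes."""
    h = np.array(
        [
            [10.0] * 6,  # g0: FC 1.0 -> none
            [13.0] * 6,  # g1: FC 1.3 -> up
            [10.0] * 6,  # g2: vs 13 -> FC 0.769 -> down
            [11.0] * 6,  # g3: FC 1.1 -> none (inside band)
            [24.0] * 6,  # g4: FC 2.0 -> up
            [5.0] * 6,  # g5: FC 0.5 -> down
            [0.0] * 6,  # g6: 0 vs 0 -> FC 1 -> none
            [12.1] * 6,  # g7: FC 1.21 -> up (just over)
            [10.0] * 6,  # g8: vs 12.1 -> FC 0.826 -> down (just under 1/1.2)
            [10.9] * 6,  # g9: FC 1.09 -> none
        ]
    )
    l = np.array(
        [[10.0] * 6, [10.0] * 6, [13.0] * 6, [10.0] * 6, [12.0] * 6,
         [10.0] * 6, [0.0] * 6, [10.0] * 6, [12.1] * 6, [10.0] * 6]
    )
    jitter = np.linspace(0.0, 0.01, 6)  # break rank ties within groups
    values = np.hstack([h + jitter, l + jitter])
    genes = [f"g{i}" for i in range(10)]
    cols = [f"h{i}" for i in range(6)] + [f"l{i}" for i in range(6)]
    groups = pd.Series(["H"] * 6 + ["L"] * 6, index=cols)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), groups)


class TestDifferentialExpression:
    def test_identical_groups_not_called(self):
        mat = toy_matrix()
        de = differential_expression(mat, test="none")
        assert de.table.loc["g0", "fold_change"] == pytest.approx(1.0, abs=1e-6)
        assert de.table.loc["g0", "call"] == "none"

    def test_toy_truth_list_fc_only(self):
        de = differential_expression(toy_matrix(), fc_threshold=1.2, test="none")
        assert set(de.up) == {"g1", "g4", "g7"}
        assert set(de.down) == {"g2", "g5", "g8"}

    def test_swap_symmetry(self):
        mat = toy_matrix()
        de = differential_expression(mat, test="none")
        swapped = mat.groups.map({"H": "L", "L": "H"})
        de2 = differential_expression(mat, swapped, test="none")
        assert set(de2.up) == set(de.down)
        assert set(de2.down) == set(de.up)

    def test_planted_fc_detected_with_wilcoxon(self):
        cfg = sd.SimConfig(seed=1, n_genes_expr=300, samples_per_group=200,
                           n_de_up=20, n_de_down=20, de_fold_change=2.0,
                           expr_sigma=0.2)
        mat, truth = sd.generate_expression(cfg)
        de = differential_expression(mat)
        up_true = set(truth[truth["direction"] == "up"]["gene"])
        assert up_true <= set(de.up)
        assert de.table.loc[sorted(up_true), "p_adj"].max() < 1e-6

    def test_min_group_size(self):
        mat = toy_matrix()
        small = pd.Series(["H"] * 2 + ["L"] * 10, index=mat.samples)
        with pytest.raises(ValueError, match=">= 3"):
            differential_expression(mat, small)


class TestPanel:
    def test_shortfall_logged_not_fatal(self):
        de = differential_expression(toy_matrix(), test="none")
        panel = build_panel(de, n=100)
        assert panel == ["g4", "g1", "g7"]  # descending fold change

    def test_tie_broken_lexicographically(self):
        values = pd.DataFrame(
            {
                "h1": [2.0, 2.0, 1.0], "h2": [2.1, 2.1, 1.0], "h3": [1.9, 1.9, 1.0],
                "l1": [1.0, 1.0, 1.0], "l2": [1.1, 1.1, 1.0], "l3": [0.9, 0.9, 1.0],
            },
            index=["gb", "ga", "gc"],
        )
        groups = pd.Series(["H"] * 3 + ["L"] * 3, index=values.columns)
        de = differential_expression(ExpressionMatrix(values, groups), test="none")
        assert build_panel(de, n=2) == ["ga", "gb"]

    def test_column_permutation_invariance(self):
        mat = toy_matrix()
        perm = list(mat.samples[::-1])
        mat2 = ExpressionMatrix(mat.values[perm], mat.groups[perm])
        assert build_panel(differential_expression(mat2, test="none")) == build_panel(
            differential_expression(mat, test="none")
        )


def brute_force_ssgsea(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Independent running-sum oracle, scalar loops only."""
    from scipy.stats import rankdata

    n = len(expr)
    ranks = rankdata(expr)
    order = sorted(range(n), key=lambda i: (-expr[i], i))
    sum_w = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = n - int(in_set.sum())
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** alpha / sum_w
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            expr = rng.random((20, 1)) * 10
            genes = [f"g{i}" for i in range(20)]
            panel_idx = rng.choice(20, size=5, replace=False)
            panel = [genes[i] for i in panel_idx]
            mat = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=["s"]))
            ours = ssgsea_score(mat, panel).iloc[0]
            in_set = np.zeros(20, dtype=bool)
            in_set[panel_idx] = True
            oracle = brute_force_ssgsea(expr[:, 0], in_set, alpha=0.25)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        expr = rng.random((30, 4)) * 5
        genes = [f"g{i}" for i in range(30)]
        panel = genes[:6]
        mat = ExpressionMatrix(pd.DataFrame(expr, index=genes,
                                            columns=list("abcd")))
        mat2 = ExpressionMatrix(pd.DataFrame(np.exp(expr), index=genes,
                                             columns=list("abcd")))
        pd.testing.assert_series_equal(ssgsea_score(mat, panel),
                                       ssgsea_score(mat2, panel))

    def test_panel_of_all_genes_constant_across_samples(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(15)]
        mat = ExpressionMatrix(
            pd.DataFrame(rng.random((15, 3)), index=genes, columns=list("xyz"))
        )
        scores = ssgsea_score(mat, genes)
        assert scores.nunique() == 1

    def test_top_ranks_beat_bottom_ranks(self):
        genes = [f"g{i}" for i in range(12)]
        top = np.concatenate([np.arange(12, 8, -1), np.arange(8, 0, -1)]).astype(float)
        bottom = top[::-1].copy()
        mat = ExpressionMatrix(
            pd.DataFrame({"top": top, "bottom": bottom}, index=genes)
        )
        scores = ssgsea_score(mat, genes[:4])
        assert scores["top"] > scores["bottom"]

    def test_absent_panel_rejected(self):
        mat = ExpressionMatrix(pd.DataFrame(np.ones((3, 2)), index=list("abc")))
        with pytest.raises(ValueError, match="no panel gene"):
            ssgsea_score(mat, ["zzz"])


def cohort(times, events, scores=None):
    df = pd.DataFrame(
        {"patient": [f"p{i}" for i in range(len(times))], "time": times, "event": events}
    )
    if scores is not None:
        df["score"] = scores
    return SurvivalCohort(df)


class TestKmLogrank:
    def test_toy_hand_arithmetic(self):
        # times 1..4 all observed; A = {1,2}, B = {3,4} -> chi2 = 49/17
        c = cohort([1, 2, 3, 4], [1, 1, 1, 1])
        res = km_logrank(c, [1, 1, 0, 0])
        assert res.chi2 == pytest.approx(49 / 17, abs=1e-12)

    def test_identical_groups_null(self):
        c = cohort([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        res = km_logrank(c, [1, 1, 1, 0, 0, 0])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        c = cohort(rng.exponential(50, 40), (rng.random(40) < 0.7).astype(int))
        z = rng.random(40) < 0.5
        assert km_logrank(c, z).chi2 == pytest.approx(km_logrank(c, ~z).chi2)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(4)
        t = rng.integers(1, 15, size=60).astype(float)  # heavy ties
        e = (rng.random(60) < 0.8).astype(int)
        z = rng.random(60) < 0.5
        res = km_logrank(cohort(t, e), z)
        lt = logrank_test(t[z], t[~z], e[z], e[~z])
        assert res.chi2 == pytest.approx(lt.test_statistic, rel=1e-10)

    def test_km_curve_product_limit(self):
        c = cohort([1, 2, 3, 4], [1, 1, 1, 1])
        res = km_logrank(c, [1, 1, 0, 0])
        curve = res.km_curves["group1"]  # times 1, 2 both events
        # S(2) = (1 - 1/2) * (1 - 1/1) = 0
        assert curve["survival"].iloc[-1] == pytest.approx(0.0)
        assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestOptimalCutoff:
    def test_all_scores_equal_rejected(self):
        rng = np.random.default_rng(5)
        c = cohort(rng.exponential(50, 30), np.ones(30, int), scores=np.ones(30))
        with pytest.raises(ValueError, match="no valid cutoff"):
            optimal_cutoff(None, c, n_permutations=10)

    def test_group_size_floor_respected(self):
        rng = np.random.default_rng(6)
        n = 50
        c = cohort(rng.exponential(50, n), np.ones(n, int), scores=rng.random(n))
        res = optimal_cutoff(None, c, min_group_frac=0.2, n_permutations=20, seed=0)
        assert min(res.group_sizes.values()) >= 10

    def test_planted_split_found_and_significant(self):
        cfg = sd.SimConfig(seed=8, n_patients=300, survival_hr=2.5, censoring_rate=0.2)
        coh, strata = sd.generate_survival_cohort(cfg)
        res = optimal_cutoff(None, coh, n_permutations=200, seed=1)
        assert res.p_adjusted < 0.01
        # selected split should largely agree with the true stratum
        z = coh.score > res.cutoff
        agree = max((z == (strata.to_numpy() == 1)).mean(),
                    (z == (strata.to_numpy() == 0)).mean())
        assert agree > 0.8


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_matches_all_pairs_count(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(8, 30))
            x = rng.integers(0, 10, size=n).astype(float)  # ties likely
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            res = roc_auc(x, y)
            pos, neg = x[y], x[~y]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert res.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)
            assert res.auc == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.random(40) < 0.4
        assert roc_auc(x, y).auc + roc_auc(-x, y).auc == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_marker_near_half(self):
        inside = 0
        rng = np.random.default_rng(9)
        for _ in range(100):
            x = rng.random(200)
            y = rng.random(200) < 0.5
            if y.all() or not y.any():
                continue
            inside += 0.4 <= roc_auc(x, y).auc <= 0.6
        assert inside >= 95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            roc_auc([1.0, 2.0], [1, 1])
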