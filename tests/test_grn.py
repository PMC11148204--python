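import networkx as nx
import numpy as np
import pandas as pd
import pytest

from modratio.grn import (
    ExpressionDataset,
    GoldStandard,
    GrnTestOptions,
    RankedInteractionList,
    classify_indirect,
    correlation_ranking,
    evaluate_pr_roc,
    holdout_size_selection,
    overall_score,
    planted_regulatory_network,
    rerank,
    subnetwork_module_pvalue,
)


def dataset_from_arrays(n=200, seed=0, tf_cols=("tf1", "tf2")):
    rng = np.random.default_rng(seed)
    cols = {
        "tf1": rng.standard_normal(n),
        "tf2": rng.standard_normal(n),
        "g1": rng.standard_normal(n),
        "g2": rng.standard_normal(n),
    }
    return ExpressionDataset(pd.DataFrame(cols), {c: c in tf_cols for c in cols})


class TestCorrelationRanking:
    def test_artificial_pvalues_are_rank_over_n(self):
        ds = dataset_from_arrays()
        ranked = correlation_ranking(ds)
        assert [p for _, _, _, p in ranked.edges] == [0.25, 0.5, 0.75, 1.0]

    def test_proportional_target_ranks_first(self):
        rng = np.random.default_rng(1)
        n = 100
        tf1 = rng.standard_normal(n)
        cols = {
            "tf1": tf1,
            "tf2": rng.standard_normal(n),
            "g1": 2.0 * tf1,
            "g2": rng.standard_normal(n),
        }
        ds = ExpressionDataset(pd.DataFrame(cols), {c: c.startswith("tf") for c in cols})
        ranked = correlation_ranking(ds)
        assert ranked.edges[0][:2] == ("tf1", "g1")

    def test_sign_of_correlation_is_ignored(self):
        rng = np.random.default_rng(2)
        n = 500
        tf1 = rng.standard_normal(n)
        cols = {
            "tf1": tf1,
            "tf2": rng.standard_normal(n),
            "g1": -tf1 + 0.3 * rng.standard_normal(n),  # strong negative
            "g2": tf1 + 0.8 * rng.standard_normal(n),  # weaker positive
        }
        ds = ExpressionDataset(pd.DataFrame(cols), {c: c.startswith("tf") for c in cols})
        ranked = correlation_ranking(ds)
        assert ranked.edges[0][:2] == ("tf1", "g1")

    def test_zero_variance_gene_ranked_last(self):
        rng = np.random.default_rng(3)
        n = 50
        cols = {
            "tf1": rng.standard_normal(n),
            "tf2": rng.standard_normal(n),
            "g1": rng.standard_normal(n),
            "g2": np.ones(n),
        }
        ds = ExpressionDataset(pd.DataFrame(cols), {c: c.startswith("tf") for c in cols})
        ranked = correlation_ranking(ds)
        assert {e[:2] for e in ranked.edges[-2:]} == {("tf1", "g2"), ("tf2", "g2")}


class TestSubnetworkModulePvalue:
    def test_mediated_chain_retains_module(self):
        """One TF drives both TGs, the other TF sits downstream of it:
        a single interface mediates everything, so p should be large."""
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 800
            tf1 = 1.0 + (rng.random(n) < 0.5)
            tf2 = 1.0 + (rng.random(n) < np.where(tf1 == 2, 0.85, 0.15))
            cols = {
                "tf1": tf2 + 0.1 * rng.standard_normal(n),
                "tf2": tf1 + 0.1 * rng.standard_normal(n),
                "g1": tf2 + 0.5 * rng.standard_normal(n),
                "g2": tf2 + 0.5 * rng.standard_normal(n),
            }
            ds = ExpressionDataset(
                pd.DataFrame(cols), {c: c.startswith("tf") for c in cols}
            )
            ps.append(subnetwork_module_pvalue(ds, ("tf1", "tf2"), ("g1", "g2")))
        assert np.median(ps) > 0.1

    def test_independent_regulators_refute_module(self):
        """Two independent TFs driving both TGs with different mixtures:
        the two moment ratios settle on different values (0.5 vs 2), so
        no single interface exists; rejections exceed the nominal level
        and grow with sample size."""
        rates = {}
        for n in (400, 1600):
            rej = 0
            for seed in range(40):
                rng = np.random.default_rng(1000 + seed)
                tf1 = 1.0 + (rng.random(n) < 0.5)
                tf2 = 1.0 + (rng.random(n) < 0.5)
                cols = {
                    "tf1": tf1 + 0.1 * rng.standard_normal(n),
                    "tf2": tf2 + 0.1 * rng.standard_normal(n),
                    "g1": tf1 + 2.0 * tf2 + 0.4 * rng.standard_normal(n),
                    "g2": 2.0 * tf1 + tf2 + 0.4 * rng.standard_normal(n),
                }
                ds = ExpressionDataset(
                    pd.DataFrame(cols), {c: c.startswith("tf") for c in cols}
                )
                p = subnetwork_module_pvalue(ds, ("tf1", "tf2"), ("g1", "g2"))
                rej += p < 0.05
            rates[n] = rej / 40
        assert rates[1600] > 0.2
        assert rates[1600] >= rates[400]

    def test_permuted_samples_give_roughly_uniform_p(self):
        ps = []
        for seed in range(200):
            ds = dataset_from_arrays(n=400, seed=seed)
            ps.append(
                subnetwork_module_pvalue(
                    ds, ("tf1", "tf2"), ("g1", "g2"), GrnTestOptions(theta=0.5)
                )
            )
        ps = np.array(ps)
        # independence can trigger the cutoff (p = 1); the non-cutoff part
        # must not concentrate at small values
        assert (ps < 0.05).mean() < 0.12
        assert np.median(ps) > 0.2


@pytest.fixture(scope="module")
def planted():
    ds, gold = planted_regulatory_network(0)
    return ds, gold, correlation_ranking(ds)


class TestRerank:
    def test_corrected_pvalues_dominate_originals(self, planted):
        ds, gold, ranked = planted
        corrected = rerank(ds, ranked, set_size=int(0.9 * len(ranked.edges)))
        orig = ranked.pvalues()
        for tf, tg, _, p in corrected.edges:
            assert p >= orig[(tf, tg)] - 1e-15

    def test_improves_aupr_on_planted_network(self, planted):
        ds, gold, ranked = planted
        a0, _ = evaluate_pr_roc(ranked, gold, seed=0)
        corrected = rerank(ds, ranked, set_size=int(0.9 * len(ranked.edges)))
        a1, _ = evaluate_pr_roc(corrected, gold, seed=0)
        assert a1 > a0

    def test_insufficiently_connected_subnetworks_untouched(self):
        """With a tiny most-likely set (fewer than 3 subnetwork edges)
        no test is applied and the ranking is unchanged."""
        ds, gold = planted_regulatory_network(1)
        ranked = correlation_ranking(ds)
        corrected = rerank(ds, ranked, set_size=2)
        assert corrected.pairs() == ranked.pairs()

    def test_set_size_cannot_exceed_list(self):
        ds, _ = planted_regulatory_network(2)
        ranked = correlation_ranking(ds)
        with pytest.raises(ValueError):
            rerank(ds, ranked, set_size=len(ranked.edges) + 1)


class TestHoldout:
    def test_single_candidate_returned_unchanged(self):
        ds, gold = planted_regulatory_network(3)
        ranked = correlation_ranking(ds)
        assert holdout_size_selection(ds, ranked, [8], gold) == 8

    def test_requires_gold(self):
        ds, _ = planted_regulatory_network(4)
        ranked = correlation_ranking(ds)
        with pytest.raises(ValueError, match="gold"):
            holdout_size_selection(ds, ranked, [4, 8], GoldStandard(labels={}))

    def test_holdout_is_every_eighth_sample(self):
        ds, _ = planted_regulatory_network(5)
        idx = np.arange(0, ds.matrix.shape[0], 8)
        sub = ds.subset_samples(idx)
        assert sub.matrix.shape[0] == int(np.ceil(ds.matrix.shape[0] / 8))
        np.testing.assert_array_equal(
            sub.matrix.iloc[1].to_numpy(), ds.matrix.iloc[8].to_numpy()
        )


class TestEvaluation:
    def test_perfect_ranking(self):
        ranked = RankedInteractionList(
            edges=[("t", "a", 1.0, 0.25), ("t", "b", 0.9, 0.5), ("t", "c", 0.1, 0.75)]
        )
        gold = GoldStandard(labels={("t", "a"): 1, ("t", "b"): 1, ("t", "c"): 0})
        aupr, auroc = evaluate_pr_roc(ranked, gold)
        assert aupr == pytest.approx(1.0)
        assert auroc == pytest.approx(1.0)

    def test_reversed_ranking(self):
        ranked = RankedInteractionList(
            edges=[("t", "c", 1.0, 0.5), ("t", "a", 0.1, 1.0)]
        )
        gold = GoldStandard(labels={("t", "a"): 1, ("t", "c"): 0})
        _, auroc = evaluate_pr_roc(ranked, gold)
        assert auroc == pytest.approx(0.0)

    def test_random_ranking_aupr_near_prevalence(self):
        rng = np.random.default_rng(0)
        edges, gold = [], {}
        n, n_pos = 400, 100
        order = rng.permutation(n)
        for i, o in enumerate(order):
            e = ("t", f"g{o}")
            edges.append((*e, 1.0 - i / n, (i + 1) / n))
            gold[e] = 1 if o < n_pos else 0
        aupr, _ = evaluate_pr_roc(RankedInteractionList(edges=edges), GoldStandard(gold))
        assert aupr == pytest.approx(n_pos / n, abs=0.08)

    def test_missing_gold_edges_appended(self):
        ranked = RankedInteractionList(edges=[("t", "a", 1.0, 1.0)])
        gold = GoldStandard(labels={("t", "a"): 0, ("t", "b"): 1})
        aupr, auroc = evaluate_pr_roc(ranked, gold, seed=1)
        assert auroc == pytest.approx(0.0)  # positive forced to the end

    def test_no_positives_errors(self):
        ranked = RankedInteractionList(edges=[("t", "a", 1.0, 1.0)])
        with pytest.raises(ValueError, match="no positives"):
            evaluate_pr_roc(ranked, GoldStandard(labels={("t", "a"): 0}))


class TestOverallScore:
    def test_all_ones_scores_zero(self):
        assert overall_score((1.0, 1.0), (1.0, 1.0)) == (0.0, 0.0, 0.0)

    def test_hand_computed_values(self):
        s_roc, s_pr, s = overall_score((1e-2, 1e-4), (1.0, 1.0))
        assert s_roc == pytest.approx(3.0)
        assert s_pr == pytest.approx(0.0)
        assert s == pytest.approx(1.5)

    def test_monotone_in_evidence(self):
        _, _, s1 = overall_score((0.1, 0.2), (0.3, 0.4))
        _, _, s2 = overall_score((0.05, 0.1), (0.15, 0.2))
        assert s2 > s1

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            overall_score((0.0, 0.5), (0.5, 0.5))


class TestClassifyIndirect:
    def test_chain_with_single_mediator_is_removable(self):
        g = nx.DiGraph([("A", "B"), ("B", "T")])
        labels = classify_indirect(g, tfs={"A", "B"})
        assert labels[("A", "T")] == "removable"

    def test_interdependent_mediators_are_nonremovable(self):
        g = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "T"), ("C", "T")])
        labels = classify_indirect(g, tfs={"A", "B", "C"})
        assert labels[("A", "T")] == "nonremovable"

    def test_empty_graph_gives_no_labels(self):
        assert classify_indirect(nx.DiGraph()) == {}
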