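"""Training-set experiments: size curves, integration, HASTS/LASTS,
the random-integration null, and rule-based selection."""

import math

import numpy as np
import pytest

from esstrans.datatypes import DivergenceMatrix, SpeciesMeta
from esstrans.evaluation import cross_species_matrix
from esstrans.experiments import (
    enumerate_integrated_sets,
    group_comparison,
    hasts_lasts_split,
    incomplete_training_curve,
    integrated_performance,
    partition_k_subsets,
    random_integration_pvalue,
    rule_based_select,
    welch_t_test,
)


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(19, 2, 171), (19, 3, 969), (19, 4, 3876), (10, 4, 210), (3, 3, 1)],
    )
    def test_counts(self, n, k, expected):
        pool = [f"s{i:02d}" for i in range(n)]
        assert len(enumerate_integrated_sets(pool, k)) == expected

    def test_counts_match_binomial_coefficient(self):
        for n in range(2, 21):
            pool = [f"s{i:02d}" for i in range(n)]
            for k in range(1, min(n, 5) + 1):
                assert len(enumerate_integrated_sets(pool, k)) == math.comb(n, k)

    def test_lexicographic_order(self):
        combos = enumerate_integrated_sets(["c", "a", "b"], 2)
        assert combos == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            enumerate_integrated_sets(["a", "b"], 3)


class TestHastsLasts:
    def test_nineteen_splits_nine_ten(self):
        aucs = {f"s{i:02d}": 0.5 + i * 0.01 for i in range(19)}
        hasts, lasts, thr = hasts_lasts_split(aucs)
        assert len(hasts) == 9 and len(lasts) == 10
        assert min(aucs[s] for s in hasts) > max(aucs[s] for s in lasts)
        assert max(aucs[s] for s in lasts) < thr < min(aucs[s] for s in hasts)

    def test_four_sets_top_two(self):
        hasts, lasts, _ = hasts_lasts_split({"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.6})
        assert hasts == ["a", "b"] and lasts == ["c", "d"]

    def test_all_equal_deterministic_by_id(self):
        hasts, lasts, _ = hasts_lasts_split({s: 0.8 for s in "abcd"})
        assert hasts == ["a", "b"] and lasts == ["c", "d"]

    def test_group_partition_sizes(self):
        hasts = [f"h{i}" for i in range(9)]
        lasts = [f"l{i}" for i in range(10)]
        combos, groups = partition_k_subsets(hasts, lasts, 4)
        counts = {g: groups.count(g) for g in ("high", "low", "mixed")}
        assert counts == {"high": 126, "low": 210, "mixed": 3540}
        assert len(combos) == 3876


class TestIncompleteCurve:
    def test_same_seed_reproducible(self, small_corpus):
        datasets, _, _ = small_corpus
        ds = next(iter(datasets.values()))
        kw = dict(fractions=[0.1, 0.4], reps=5, seed=7)
        c1 = incomplete_training_curve(ds, **kw)
        c2 = incomplete_training_curve(ds, **kw)
        assert c1.mean_auc == c2.mean_auc and c1.sd_ppv == c2.sd_ppv

    def test_full_fraction_is_plain_split(self, small_corpus):
        datasets, _, _ = small_corpus
        ds = next(iter(datasets.values()))
        c = incomplete_training_curve(ds, fractions=[0.5, 0.8], reps=10, seed=1)
        assert c.reps == 10 and len(c.mean_auc) == 2
        # at 80% the training set is the whole remainder: finite sensible AUC
        assert 0.5 < c.mean_auc[1] <= 1.0

    def test_invalid_fractions_rejected(self, small_corpus):
        datasets, _, _ = small_corpus
        ds = next(iter(datasets.values()))
        with pytest.raises(ValueError, match="strictly increasing"):
            incomplete_training_curve(ds, fractions=[0.2, 0.1], reps=2)
        with pytest.raises(ValueError, match="test_fraction"):
            incomplete_training_curve(ds, fractions=[0.9], reps=2)


class TestIntegration:
    def test_single_species_combo_matches_matrix_entry(self, small_corpus):
        datasets, _, _ = small_corpus
        species = list(datasets)
        test_sp, train_sp = species[0], species[1]
        m = cross_species_matrix(datasets)
        res = integrated_performance(datasets, [(train_sp,)], test_sp)
        assert res.aucs[0] == pytest.approx(m.entry(train_sp, test_sp), abs=1e-12)

    def test_result_length_matches_combos(self, small_corpus):
        datasets, _, _ = small_corpus
        species = list(datasets)
        combos = enumerate_integrated_sets(species[1:], 2)
        res = integrated_performance(datasets, combos, species[0])
        assert len(res.aucs) == len(combos) == math.comb(len(species) - 1, 2)

    def test_duplicated_dataset_pools_to_same_auc(self, small_corpus):
        datasets, _, _ = small_corpus
        species = list(datasets)
        test_sp, train_sp = species[0], species[1]
        base = datasets[train_sp]
        feats = base.features.copy()
        clone = type(base)(
            species_id="CLONE", features=feats, labels=base.labels.copy(),
            schema=base.schema,
        )
        aug = dict(datasets)
        aug["CLONE"] = clone
        single = integrated_performance(aug, [(train_sp,)], test_sp).aucs[0]
        paired = integrated_performance(aug, [(train_sp, "CLONE")], test_sp).aucs[0]
        assert paired == pytest.approx(single, abs=0.01)

    def test_combo_containing_test_species_rejected(self, small_corpus):
        datasets, _, _ = small_corpus
        species = list(datasets)
        with pytest.raises(ValueError, match="contains the test species"):
            integrated_performance(datasets, [(species[0],)], species[0])

    def test_group_comparison_tags_all_combos(self, small_corpus):
        datasets, _, _ = small_corpus
        species = sorted(datasets)
        test_sp = species[0]
        pool = species[1:]
        res = group_comparison(datasets, pool[:2], pool[2:], test_sp, k=2)
        assert len(res.combos) == math.comb(4, 2)
        counts = {g: res.groups.count(g) for g in ("high", "low", "mixed")}
        assert counts == {"high": 1, "low": 1, "mixed": 4}


class _StubScorer:
    """Fixed combo -> AUC lookup for exercising the null-distribution logic."""

    def __init__(self, table):
        self.table = {tuple(sorted(k)): v for k, v in table.items()}

    def auc_of(self, combo):
        return self.table[tuple(sorted(combo))]


class TestNullDistribution:
    pool = ["a", "b", "c", "d"]

    def scorer(self, rule_auc):
        table = {c: 0.7 + 0.01 * i for i, c in enumerate(enumerate_integrated_sets(self.pool, 2))}
        table[("x", "y")] = rule_auc
        return table

    def test_threshold_below_all_gives_p_one(self):
        stub = _StubScorer(self.scorer(0.1))
        res = random_integration_pvalue(
            {}, "t", ["x", "y"], k=2, mode="exact", pool=self.pool, scorer=stub
        )
        assert res.p_value == 1.0

    def test_threshold_above_all_gives_p_zero(self):
        stub = _StubScorer(self.scorer(0.99))
        res = random_integration_pvalue(
            {}, "t", ["x", "y"], k=2, mode="exact", pool=self.pool, scorer=stub
        )
        assert res.p_value == 0.0

    def test_sampled_within_binomial_error_of_exact(self):
        stub = _StubScorer(self.scorer(0.72))
        kw = dict(k=2, pool=self.pool, scorer=stub)
        exact = random_integration_pvalue({}, "t", ["x", "y"], mode="exact", **kw)
        sampled = random_integration_pvalue(
            {}, "t", ["x", "y"], mode="sampled", n_sims=10_000, seed=5, **kw
        )
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 10_000)
        assert abs(sampled.p_value - exact.p_value) <= 3 * se + 1e-12

    def test_rule_set_with_test_species_rejected(self):
        with pytest.raises(ValueError, match="exclude the test species"):
            random_integration_pvalue({}, "t", ["t", "y"], pool=self.pool)

    def test_invalid_n_sims(self):
        with pytest.raises(ValueError, match="n_sims"):
            random_integration_pvalue({}, "t", ["x", "y"], n_sims=0, pool=self.pool)


class TestRuleBasedSelect:
    def corpus_meta(self):
        mk = lambda sp, **kw: SpeciesMeta(species_id=sp, **kw)
        meta = {
            "TGT": mk("TGT", quality_tier="deletion", growth_condition="rich",
                      gram="neg", oxygen="aerobe", shape="rod"),
            "TWIN": mk("TWIN", quality_tier="deletion", growth_condition="rich",
                       gram="neg", oxygen="aerobe", shape="rod"),
            "QLOW": mk("QLOW", quality_tier="inferred", growth_condition="rich",
                       gram="neg", oxygen="aerobe", shape="rod"),
            "QMID": mk("QMID", quality_tier="transposon", growth_condition="rich",
                       gram="neg", oxygen="aerobe", shape="rod"),
            "FAR": mk("FAR", quality_tier="deletion", growth_condition="rich",
                      gram="neg", oxygen="aerobe", shape="rod"),
            "ODD": mk("ODD", quality_tier="deletion", growth_condition="minimal",
                      gram="pos", oxygen="anaerobe", shape="coccus"),
        }
        ids = list(meta)
        d = np.full((6, 6), 2000.0)
        np.fill_diagonal(d, 0.0)
        frame = dict(zip(ids, range(6)))
        d[frame["TGT"], frame["TWIN"]] = d[frame["TWIN"], frame["TGT"]] = 0.0
        d[frame["TGT"], frame["FAR"]] = d[frame["FAR"], frame["TGT"]] = 4000.0
        # keep the matrix ultrametric-agnostic; only symmetry/diagonal required
        div = DivergenceMatrix(ids, (d + d.T) / 2)
        return meta, div

    def test_identical_candidate_ranks_first(self):
        meta, div = self.corpus_meta()
        top, ranking = rule_based_select(meta, div, "TGT", n=1)
        assert top == ["TWIN"]
        assert ranking.iloc[0]["score"] == pytest.approx(1.0)

    def test_quality_tier_monotonicity(self):
        meta, div = self.corpus_meta()
        _, ranking = rule_based_select(meta, div, "TGT", n=3)
        pos = {s: i for i, s in enumerate(ranking["species"])}
        assert pos["QMID"] < pos["QLOW"]

    def test_hand_computed_weighted_scores(self):
        meta, div = self.corpus_meta()
        _, ranking = rule_based_select(meta, div, "TGT", n=4)
        scores = dict(zip(ranking["species"], ranking["score"]))
        # subscores: quality, condition match, 1 - d/4000, lifestyle fraction
        expect = {
            "TWIN": 0.25 * (1 + 1 + 1 + 1),
            "QLOW": 0.25 * (0 + 1 + 0.5 + 1),
            "QMID": 0.25 * (0.5 + 1 + 0.5 + 1),
            "FAR": 0.25 * (1 + 1 + 0 + 1),
            "ODD": 0.25 * (1 + 0 + 0.5 + 0),
        }
        for sp, val in expect.items():
            assert scores[sp] == pytest.approx(val, abs=1e-12)
        order = sorted(expect, key=lambda s: (-expect[s], s))
        assert list(ranking["species"]) == order

    def test_missing_divergence_excluded(self):
        meta, div = self.corpus_meta()
        meta["GHOST"] = SpeciesMeta(species_id="GHOST")
        top, ranking = rule_based_select(meta, div, "TGT", n=4)
        assert "GHOST" not in set(ranking["species"])


def test_welch_t_test_matches_known_direction():
    rng = np.random.default_rng(0)
    a = rng.normal(1.0, 1.0, 200)
    b = rng.normal(0.0, 2.0, 200)
    t, p = welch_t_test(a, b)
    assert t > 0 and p < 1e-6
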