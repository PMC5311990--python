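import numpy as np
import pandas as pd
import pytest

from focusheur.data_io import DiseaseGeneTable
from focusheur.evaluation import (
    EmptyReferenceWarning,
    ReferenceSet,
    auc,
    auc_of_ranking,
    compare_methods,
    make_reference,
    restrict_top,
    roc,
    similarity_matrix,
    wilcoxon_greater,
)
from focusheur.ranking import GeneRanking


def table_from_pairs(pairs):
    return DiseaseGeneTable(pd.DataFrame(pairs, columns=["gene", "disease"]))


def random_ranking(rng, n, max_group=None):
    genes = [f"g{i:03d}" for i in range(n)]
    rng.shuffle(genes)
    tie_group, gid = [], 0
    for _ in genes:
        if gid == 0 or rng.random() < 0.6:
            gid += 1
        tie_group.append(gid)
    return GeneRanking(genes=genes, tie_group=tie_group)


def oracle_auc(ranking, positives):
    """Mann–Whitney pair counting: P(pos above neg) + 1/2 P(tie)."""
    tg = dict(zip(ranking.genes, ranking.tie_group))
    pos = [g for g in ranking.genes if g in positives]
    neg = [g for g in ranking.genes if g not in positives]
    total = 0.0
    for p in pos:
        for q in neg:
            if tg[p] < tg[q]:
                total += 1.0
            elif tg[p] == tg[q]:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestMakeReference:
    def test_pleiotropy_boundary_ten_masked_nine_kept(self):
        pairs = [("hub", f"d{i}") for i in range(10)]
        pairs += [("mild", f"d{i}") for i in range(9)]
        pairs += [("hub", "target"), ("mild", "target"), ("specific", "target")]
        table = table_from_pairs(pairs)
        universe = ["hub", "mild", "specific", "bystander"]
        complete = make_reference(table, "target", universe, "complete")
        reduced = make_reference(table, "target", universe, "reduced")
        assert complete.positives == {"hub", "mild", "specific"}
        # "hub" now counts 11 diseases, "mild" 10 -> both masked at cutoff 10
        assert reduced.positives == {"specific"}
        # 8 other diseases plus the target itself: pleiotropy 9 -> retained
        nine = make_reference(
            table_from_pairs([("g", f"d{i}") for i in range(8)] + [("g", "t")]),
            "t", ["g", "other"], "reduced",
        )
        assert nine.positives == {"g"}

    def test_reduced_subset_of_complete(self):
        rng = np.random.default_rng(31)
        pairs = [
            (f"g{rng.integers(25)}", f"d{rng.integers(15)}") for _ in range(400)
        ]
        table = table_from_pairs(pairs)
        universe = [f"g{i}" for i in range(25)]
        import warnings
        for disease in table.diseases:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyReferenceWarning)
                red = make_reference(table, disease, universe, "reduced", 5)
                comp = make_reference(table, disease, universe, "complete", 5)
            assert red.positives <= comp.positives
            # brute-force filter oracle
            counts = {}
            for g, d in set(map(tuple, pairs)):
                counts[g] = counts.get(g, 0) + 1
            want = {g for g in comp.positives if counts[g] < 5}
            assert red.positives == want

    def test_empty_positive_set_warns(self):
        table = table_from_pairs([("a", "d1")])
        with pytest.warns(EmptyReferenceWarning):
            ref = make_reference(table, "d1", ["x", "y"], "complete")
        assert not ref.positives


class TestRocAuc:
    def test_perfect_ranking_hits_0_1(self):
        ranking = GeneRanking(genes=["p1", "p2", "n1", "n2"], tie_group=[1, 2, 3, 4])
        ref = ReferenceSet("d", frozenset({"p1", "p2"}))
        curve = roc(ranking, ref)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))
        assert auc(curve) == 1.0

    def test_single_tie_group_is_diagonal(self):
        ranking = GeneRanking(genes=list("abcd"), tie_group=[1, 1, 1, 1])
        ref = ReferenceSet("d", frozenset({"a", "c"}))
        curve = roc(ranking, ref)
        assert np.allclose(curve.fpr, [0, 1]) and np.allclose(curve.tpr, [0, 1])
        assert auc(curve) == 0.5

    def test_random_curves_match_threshold_enumeration(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            ranking = random_ranking(rng, 20)
            positives = set(rng.choice(ranking.genes, size=6, replace=False))
            ref = ReferenceSet("d", frozenset(positives))
            curve = roc(ranking, ref)
            # oracle: confusion counts at every tie-group cut
            tg = dict(zip(ranking.genes, ranking.tie_group))
            n_pos, n_neg = 6, 14
            points = {(0.0, 0.0)}
            for cut in range(1, max(tg.values()) + 1):
                sel = {g for g in ranking.genes if tg[g] <= cut}
                tp = len(sel & positives)
                fp = len(sel - positives)
                points.add((fp / n_neg, tp / n_pos))
            assert set(zip(curve.fpr, curve.tpr)) == points

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(25):
            ranking = random_ranking(rng, 30)
            positives = set(rng.choice(ranking.genes, size=8, replace=False))
            ref = ReferenceSet("d", frozenset(positives))
            assert auc_of_ranking(ranking, ref) == pytest.approx(
                oracle_auc(ranking, positives), abs=1e-12
            )

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(34)
        ranking = random_ranking(rng, 40)
        positives = set(rng.choice(ranking.genes, size=12, replace=False))
        ref = ReferenceSet("d", frozenset(positives))
        y = [1 if g in positives else 0 for g in ranking.genes]
        score = [-t for t in ranking.tie_group]  # higher = better
        assert auc_of_ranking(ranking, ref) == pytest.approx(
            roc_auc_score(y, score), abs=1e-12
        )

    def test_reversed_ranking_flips_auc(self):
        rng = np.random.default_rng(35)
        genes = [f"g{i}" for i in range(15)]
        rng.shuffle(genes)
        fwd = GeneRanking(genes=genes, tie_group=list(range(1, 16)))
        rev = GeneRanking(genes=genes[::-1], tie_group=list(range(1, 16)))
        positives = frozenset(rng.choice(genes, size=5, replace=False))
        ref = ReferenceSet("d", positives)
        assert auc_of_ranking(fwd, ref) + auc_of_ranking(rev, ref) == \
            pytest.approx(1.0, abs=1e-12)

    def test_tie_split_invariance(self):
        # splitting a tie group into identically-scored singletons is the
        # same curve area as the diagonal through the block
        genes = list("abcdef")
        tied = GeneRanking(genes=genes, tie_group=[1, 2, 2, 2, 3, 4])
        ref = ReferenceSet("d", frozenset({"b", "e"}))
        assert auc_of_ranking(tied, ref) == pytest.approx(
            oracle_auc(tied, {"b", "e"}), abs=1e-12
        )

    def test_degenerate_reference_rejected(self):
        ranking = GeneRanking(genes=["a", "b"], tie_group=[1, 2])
        with pytest.raises(ValueError):
            roc(ranking, ReferenceSet("d", frozenset()))
        with pytest.raises(ValueError):
            roc(ranking, ReferenceSet("d", frozenset({"a", "b"})))


class TestRestrictTop:
    def test_fraction_one_is_identity(self):
        rng = np.random.default_rng(36)
        ranking = random_ranking(rng, 12)
        out = restrict_top(ranking, 1.0)
        assert out.genes == ranking.genes and out.tie_group == ranking.tie_group

    def test_one_percent_of_200_keeps_two(self):
        ranking = GeneRanking(
            genes=[f"g{i:03d}" for i in range(200)],
            tie_group=list(range(1, 201)),
        )
        out = restrict_top(ranking, 0.01)
        assert out.tie_group[:2] == [1, 2]
        assert len(set(out.tie_group[2:])) == 1  # 198-way terminal tie
        assert len(out) == 200

    def test_auc_after_restriction_matches_direct_roc(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            ranking = random_ranking(rng, 50)
            positives = set(rng.choice(ranking.genes, size=10, replace=False))
            ref = ReferenceSet("d", frozenset(positives))
            out = restrict_top(ranking, 0.1)
            assert auc_of_ranking(out, ref) == pytest.approx(
                oracle_auc(out, positives), abs=1e-12
            )

    def test_invalid_fraction(self):
        ranking = GeneRanking(genes=["a"], tie_group=[1])
        with pytest.raises(ValueError):
            restrict_top(ranking, 0.0)


class TestSimilarityMatrix:
    def test_diagonal_and_reverse(self):
        genes = [f"g{i}" for i in range(15)]
        fwd = GeneRanking(genes=genes, tie_group=list(range(1, 16)), method="fwd")
        rev = GeneRanking(genes=genes[::-1], tie_group=list(range(1, 16)),
                          method="rev")
        sim = similarity_matrix({"ds": {"fwd": fwd, "rev": rev}})
        assert sim.values.loc["fwd", "fwd"] == 1.0
        assert sim.values.loc["fwd", "rev"] == pytest.approx(-1.0)
        assert np.allclose(sim.values, sim.values.T)

    def test_matches_pearson_on_midranks(self):
        rng = np.random.default_rng(38)
        r1 = random_ranking(rng, 15)
        r2 = random_ranking(rng, 15)
        sim = similarity_matrix({"ds": {"m1": r1, "m2": r2}})
        m1 = r1.midranks().sort_index().to_numpy()
        m2 = r2.midranks().sort_index().to_numpy()
        want = np.corrcoef(m1, m2)[0, 1]
        assert sim.values.loc["m1", "m2"] == pytest.approx(want, abs=1e-12)

    def test_constant_ranking_excluded(self):
        genes = list("abcde")
        const = GeneRanking(genes=genes, tie_group=[1] * 5, method="const")
        other = GeneRanking(genes=genes, tie_group=[1, 2, 3, 4, 5], method="o")
        sim = similarity_matrix({"ds": {"const": const, "o": other}})
        assert np.isnan(sim.values.loc["const", "o"])
        assert sim.values.loc["const", "const"] == 1.0

    def test_mean_over_datasets(self):
        genes = list("abcd")
        a = GeneRanking(genes=genes, tie_group=[1, 2, 3, 4], method="a")
        b_same = GeneRanking(genes=genes, tie_group=[1, 2, 3, 4], method="b")
        b_rev = GeneRanking(genes=genes[::-1], tie_group=[1, 2, 3, 4], method="b")
        sim = similarity_matrix(
            {"ds1": {"a": a, "b": b_same}, "ds2": {"a": a, "b": b_rev}}
        )
        assert sim.values.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)


class TestWilcoxon:
    def test_ten_straight_wins_exact_p(self):
        x = np.linspace(0.8, 0.9, 10)
        y = x - 0.05
        res = wilcoxon_greater(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2.0**-10, rel=1e-12)

    def test_identical_vectors_flagged_degenerate(self):
        res = wilcoxon_greater([0.5] * 8, [0.5] * 8)
        assert res.degenerate and res.p_value == 1.0

    def test_antisymmetry_of_exact_test(self):
        rng = np.random.default_rng(39)
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            p1 = wilcoxon_greater(x, y).p_value
            p2 = wilcoxon_greater(y, x).p_value
            assert p1 + p2 >= 1.0 - 1e-12

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(40)
        for _ in range(10):
            x = rng.normal(size=14)
            y = rng.normal(size=14)
            ours = wilcoxon_greater(x, y).p_value
            ref = scipy_wilcoxon(x, y, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_normal_branch_close_to_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(41)
        x = rng.normal(0.1, 1, size=40)
        y = rng.normal(0.0, 1, size=40)
        ours = wilcoxon_greater(x, y)
        assert ours.method == "normal"
        ref = scipy_wilcoxon(
            x, y, alternative="greater", method="approx", correction=True
        ).pvalue
        assert ours.p_value == pytest.approx(ref, rel=1e-6)

    def test_compare_methods_pairs_on_disease(self):
        rows = []
        for d in range(10):
            rows.append({"method": "m1", "disease": f"d{d}", "auc": 0.8 + d * 0.001})
            rows.append({"method": "m2", "disease": f"d{d}", "auc": 0.7 + d * 0.001})
        res = compare_methods(pd.DataFrame(rows), "m1", "m2")
        assert res.p_value == pytest.approx(2.0**-10, rel=1e-12)
        assert compare_methods(pd.DataFrame(rows), "m2", "m1").p_value > 0.99
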