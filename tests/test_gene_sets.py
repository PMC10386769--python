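"""Gene-set statistics against brute-force oracles and calibration checks."""
import numpy as np
import pandas as pd
import pytest

import txplore as tx
from txplore.containers import DataError, GeneSet, GeneSetCollection
from oracles import enrichment_score_bruteforce, hypergeom_upper_tail


def _ranked(stats, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(stats))]
    pairs = sorted(zip(genes, stats), key=lambda gv: (-gv[1], gv[0]))
    return tx.RankedList([g for g, _ in pairs], np.array([v for _, v in pairs]))


class TestMakeRankedList:
    def test_sorting_and_tie_rule(self, bundle, cpm_matrix):
        de = tx.run_differential_expression(cpm_matrix, bundle.groups, "A", "B")
        ranked = tx.make_ranked_list(de)
        assert (np.diff(ranked.stats) <= 0).all()
        # equal stats must be ordered by ascending gene id
        for i in range(len(ranked) - 1):
            if ranked.stats[i] == ranked.stats[i + 1]:
                assert ranked.genes[i] < ranked.genes[i + 1]

    def test_nonfinite_dropped_and_counted(self):
        table = pd.DataFrame(
            {"gene": ["a", "b", "c"], "log2_fold_change": [1.0, np.inf, -2.0]}
        )
        de = tx.DEResult(table, "A", "B", "welch", 1.0, 3, 3, 0, "CPM")
        ranked = tx.make_ranked_list(de)
        assert ranked.n_dropped_nonfinite == 1
        assert ranked.genes == ["a", "c"]


class TestEnrichmentScore:
    def test_top_gene_singleton_hits_one(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5], ["w", "x", "y", "z"])
        profile = tx.enrichment_score(ranked, {"w"}, weight=1.0)
        assert profile.es == pytest.approx(1.0)
        assert profile.leading_edge == ["w"]

    def test_negation_and_reversal_flips_es(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            stats = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i:03d}" for i in range(n)]
            members = set(rng.choice(genes, int(rng.integers(2, min(8, n - 1))), replace=False))
            profile = tx.enrichment_score(_ranked(stats, genes), members)
            es_flipped = tx.enrichment_score(_ranked(-stats, genes), members).es
            assert abs(es_flipped) == pytest.approx(abs(profile.es), abs=1e-12)
            walk = profile.running_sum
            if abs(walk.max() + walk.min()) > 1e-9:  # tie-free: sign flips too
                assert es_flipped == pytest.approx(-profile.es, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 50))
            stats = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i:03d}" for i in range(n)]
            size = int(rng.integers(1, min(10, n - 1) + 1))
            members = set(rng.choice(genes, size, replace=False))
            weight = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            profile = tx.enrichment_score(_ranked(stats, genes), members, weight)
            oracle = enrichment_score_bruteforce(
                _ranked(stats, genes).genes, _ranked(stats, genes).stats, members, weight
            )
            assert profile.es == pytest.approx(oracle, abs=1e-12)

    def test_weight_zero_equals_classical_ks(self, rng):
        # equal hit increments regardless of the statistics' magnitudes
        stats = np.sort(rng.normal(size=30))[::-1]
        genes = [f"g{i:03d}" for i in range(30)]
        members = set(genes[::7])
        es_w0 = tx.enrichment_score(_ranked(stats, genes), members, 0.0).es
        flat = tx.enrichment_score(
            _ranked(np.linspace(30, 1, 30), genes), members, 0.0
        ).es
        assert es_w0 == pytest.approx(flat, abs=1e-12)

    def test_degenerate_sets_error(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        with pytest.raises(DataError):
            tx.enrichment_score(ranked, {"absent"})
        with pytest.raises(DataError):
            tx.enrichment_score(ranked, set(ranked.genes))


def _collection(sets: dict[str, set]) -> GeneSetCollection:
    return GeneSetCollection(
        {name: GeneSet(name, "", tuple(sorted(members))) for name, members in sets.items()}
    )


class TestPrerankedGsea:
    def test_planted_top_set_is_significant(self, rng):
        n = 1000
        stats = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i:04d}" for i in range(n)]
        ranked = _ranked(stats, genes)
        planted = set(ranked.genes[:20])
        coll = _collection({"PLANTED": planted})
        result = tx.preranked_gsea(ranked, coll, n_permutations=1000, seed=3)
        assert float(result.table["p_value"].iloc[0]) <= 0.01

    def test_determinism_and_ordering_invariance(self, rng):
        n = 200
        stats = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i:04d}" for i in range(n)]
        ranked = _ranked(stats, genes)
        sets = {
            f"S{k}": set(rng.choice(genes, 15, replace=False)) for k in range(5)
        }
        coll = _collection(sets)
        r1 = tx.preranked_gsea(ranked, coll, 200, seed=11)
        r2 = tx.preranked_gsea(ranked, coll, 200, seed=11)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        # reversed collection order and shuffled member order: same p per set
        shuffled = {
            name: GeneSet(name, "", tuple(rng.permutation(sorted(members))))
            for name, members in reversed(list(sets.items()))
        }
        r3 = tx.preranked_gsea(ranked, GeneSetCollection(shuffled), 200, seed=11)
        merged = r1.table.merge(r3.table, on="name", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_value_a"], merged["p_value_b"])
        assert np.allclose(merged["es_a"], merged["es_b"])

    def test_size_bounds_counted_and_all_filtered_errors(self, rng):
        stats = np.sort(rng.normal(size=50))[::-1]
        genes = [f"g{i:04d}" for i in range(50)]
        ranked = _ranked(stats, genes)
        coll = _collection({"TINY": set(genes[:2]), "OK": set(genes[5:15])})
        result = tx.preranked_gsea(ranked, coll, 100, min_size=5, seed=0)
        assert result.n_skipped_size == 1
        assert result.table["name"].tolist() == ["OK"]
        with pytest.raises(DataError, match="size bounds"):
            tx.preranked_gsea(ranked, coll, 100, min_size=30, seed=0)

    def test_min_permutations_enforced(self, rng):
        ranked = _ranked(np.arange(20.0)[::-1])
        coll = _collection({"S": set(ranked.genes[:6])})
        with pytest.raises(DataError, match="100"):
            tx.preranked_gsea(ranked, coll, 50)


class TestOverrepresentation:
    def test_closed_form_extreme_overlap(self):
        universe = {f"u{i}" for i in range(10)}
        query = {f"u{i}" for i in range(5)}
        res = tx.overrepresentation_test(query, universe, query)
        assert res.p_value == pytest.approx(1 / 252, abs=1e-12)
        assert res.expected == pytest.approx(2.5)

    def test_zero_overlap_and_forced_overlap(self):
        universe = {f"u{i}" for i in range(8)}
        res = tx.overrepresentation_test(
            {"u0", "u1"}, universe, {"u6", "u7"}
        )
        assert res.overlap == 0
        res_forced = tx.overrepresentation_test(universe, universe, {"u0", "u1"})
        assert res_forced.overlap == 2 and res_forced.p_value == 1.0

    def test_matches_combinatorial_oracle_on_small_universes(self, rng):
        for _ in range(100):
            m = int(rng.integers(4, 31))
            universe = [f"u{i}" for i in range(m)]
            query = set(rng.choice(universe, int(rng.integers(1, m + 1)), replace=False))
            members = set(rng.choice(universe, int(rng.integers(1, m + 1)), replace=False))
            res = tx.overrepresentation_test(query, universe, members)
            oracle = hypergeom_upper_tail(res.overlap, m, len(members), len(query))
            assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(DataError, match="outside"):
            tx.overrepresentation_test({"x"}, {"a", "b"}, {"a"})


class TestCompareSetExpression:
    def test_planted_shift_detected(self, rng):
        n, genes = 200, [f"g{i:03d}" for i in range(200)]
        values = rng.lognormal(3, 0.3, size=(n, 8))
        member_idx = np.arange(30)
        values[member_idx, :4] *= 16.0  # +4 log2 units in group A
        frame = pd.DataFrame(values, index=genes, columns=[f"s{j}" for j in range(8)])
        matrix = tx.ExpressionMatrix(frame, "CPM")
        groups = tx.SampleGroups(
            {"A": [f"s{j}" for j in range(4)], "B": [f"s{j}" for j in range(4, 8)]}
        )
        gs = GeneSet("SHIFTED", "", tuple(genes[i] for i in member_idx))
        res = tx.compare_set_expression(matrix, gs, groups, "A", "B")
        assert res.p_value < 0.01
        assert res.direction == "A"
        assert len(res.values) == 30

    def test_identical_groups_give_p_one(self, rng):
        half = rng.lognormal(3, 0.3, size=(20, 3))
        values = np.hstack([half, half])  # group B duplicates group A
        genes = [f"g{i:03d}" for i in range(20)]
        frame = pd.DataFrame(values, index=genes, columns=[f"s{j}" for j in range(6)])
        matrix = tx.ExpressionMatrix(frame, "CPM")
        groups = tx.SampleGroups(
            {"A": ["s0", "s1", "s2"], "B": ["s3", "s4", "s5"]}
        )
        gs = GeneSet("ANY", "", tuple(genes[:10]))
        res = tx.compare_set_expression(matrix, gs, groups, "A", "B")
        assert res.p_value == 1.0
        assert res.direction == "equal"

    def test_small_overlap_refused(self, bundle, cpm_matrix):
        gs = GeneSet("TWO", "", ("G00001", "G00002"))
        with pytest.raises(DataError, match=">= 3"):
            tx.compare_set_expression(cpm_matrix, gs, bundle.groups, "A", "B")
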