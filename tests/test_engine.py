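"""Orchestration: context selection, matrix assembly, contextualization,
empirical p-values, representatives and the key-index evaluation."""

import numpy as np
import pandas as pd
import pytest

from microsearch import engine
from microsearch.engine import (
    assemble_matrix,
    build_pvalue_table,
    composition_comparison,
    empirical_pvalue,
    false_negative_percentage,
    hierarchical_cluster,
    pcoa,
    phyla_index_fn_table,
    run_type1,
    run_type2,
    select_context,
    select_representatives,
)
from microsearch.errors import EmptyContextError, MissingDistanceError
from microsearch.metric_index import SearchRecord
from microsearch.profiles import (
    AbundanceProfile,
    DistanceStore,
    TaxonomyTable,
)


def record(qid, evaluated, radius=0.3):
    rec = SearchRecord(qid, radius)
    for s, d in evaluated.items():
        rec.record(s, d)
    return rec.finalize()


class TestSelectContext:
    def test_intersection_then_topk_covers_all(self):
        r1 = record("n1", {"s1": 0.1, "s2": 0.2, "s3": 0.5})
        r2 = record("n2", {"s2": 0.15, "s3": 0.4})
        assert select_context([r1, r2], k=20) == ["s2", "s3"]

    def test_topk_restricted_to_intersection(self):
        # s1 is n1's closest overall but was not compared to n2, so the
        # k=1 ranking considers only {s2, s3}
        r1 = record("n1", {"s1": 0.1, "s2": 0.2, "s3": 0.5})
        r2 = record("n2", {"s2": 0.15, "s3": 0.4})
        assert select_context([r1, r2], k=1) == ["s2"]

    def test_single_query_keeps_whole_evaluated_set(self):
        r = record("n1", {"s1": 0.3, "s2": 0.9, "s3": 0.7})
        assert select_context([r], k=10) == ["s1", "s2", "s3"]

    def test_empty_intersection_is_loud(self):
        r1 = record("n1", {"s1": 0.1})
        r2 = record("n2", {"s2": 0.1})
        with pytest.raises(EmptyContextError):
            select_context([r1, r2])


class TestAssembleMatrix:
    def two_by_one(self):
        store = DistanceStore(
            ["s1", "s2"], np.array([[0.0, 0.4], [0.4, 0.0]])
        )
        rec = record("q", {"s1": 0.1, "s2": 0.2})
        q = AbundanceProfile("q", {"o": 1.0})
        return store, rec, q

    def test_blocks_fill_symmetric_zero_diag(self):
        store, rec, q = self.two_by_one()
        mat = assemble_matrix(["s1", "s2"], [q], store, [rec], lambda a, b: 0.0)
        assert mat.shape == (3, 3)
        assert (np.diag(mat) == 0).all()
        assert mat.loc["s1", "s2"] == 0.4
        assert mat.loc["s1", "q"] == 0.1 and mat.loc["q", "s2"] == 0.2
        assert (mat.values == mat.values.T).all()

    def test_missing_precalc_cell_named(self):
        store, rec, q = self.two_by_one()
        with pytest.raises(MissingDistanceError, match="s3"):
            assemble_matrix(
                ["s1", "s3"], [q], store, [record("q", {"s1": 0.1, "s3": 0.2})],
                lambda a, b: 0.0,
            )

    def test_cells_match_direct_recomputation(self, small_world):
        db, tree, metric = (
            small_world["db"], small_world["tree"], small_world["metric"],
        )
        queries = [
            AbundanceProfile("qa", dict(db.profiles[0].counts)),
            AbundanceProfile("qb", dict(db.profiles[1].counts)),
        ]
        res = run_type1(db, queries, tree, "gnat", radius=0.4, seed=0)
        mat = res.context.full_matrix
        profile_of = {s: db[s] for s in res.context.context_ids}
        profile_of.update({q.sample_id: q for q in queries})
        for a in mat.index:
            for b in mat.columns:
                expected = 0.0 if a == b else metric(profile_of[a], profile_of[b])
                assert mat.loc[a, b] == pytest.approx(expected, abs=1e-9)


class TestPcoa:
    def test_collinear_three_points(self):
        D = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"),
            columns=list("abc"), dtype=float,
        )
        coords, eigvals = pcoa(D)
        assert coords.shape[1] == 1
        d12 = abs(coords.iloc[0, 0] - coords.iloc[1, 0])
        d13 = abs(coords.iloc[0, 0] - coords.iloc[2, 0])
        assert d12 == pytest.approx(1.0, abs=1e-9)
        assert d13 == pytest.approx(2.0, abs=1e-9)

    def test_equilateral_embeds_in_two_dims(self):
        D = pd.DataFrame(
            1.0 - np.eye(3), index=list("abc"), columns=list("abc")
        )
        coords, _ = pcoa(D)
        assert coords.shape[1] == 2
        for i in range(3):
            for j in range(i + 1, 3):
                dij = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
                assert dij == pytest.approx(1.0, abs=1e-9)

    def test_identical_points_coincide(self):
        D = pd.DataFrame(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0]], index=list("abc"),
            columns=list("abc"), dtype=float,
        )
        coords, _ = pcoa(D)
        assert np.linalg.norm(coords.iloc[0] - coords.iloc[1]) < 1e-9

    def test_euclidean_matrix_reproduced_at_full_rank(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        coords, _ = pcoa(pd.DataFrame(D))
        D2 = np.linalg.norm(
            coords.values[:, None] - coords.values[None, :], axis=2
        )
        np.testing.assert_allclose(D, D2, atol=1e-6)

    def test_skbio_agrees(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        ours, eig = pcoa(pd.DataFrame(D))
        theirs = skbio_pcoa(DistanceMatrix(D), method="eigh")
        np.testing.assert_allclose(
            sorted(eig, reverse=True),
            sorted(theirs.eigvals[theirs.eigvals > 1e-9], reverse=True),
            atol=1e-8,
        )


class TestUpgma:
    def test_first_merge_at_half_distance(self):
        D = pd.DataFrame(
            [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
            index=list("abc"), columns=list("abc"),
        )
        nwk = hierarchical_cluster(D)
        assert "(a:0.05,b:0.05)" in nwk or "(b:0.05,a:0.05)" in nwk

    def test_identical_points_merge_at_zero(self):
        D = pd.DataFrame(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0]], index=list("abc"),
            columns=list("abc"), dtype=float,
        )
        nwk = hierarchical_cluster(D)
        assert "a:0" in nwk and "b:0" in nwk

    def test_four_points_match_manual_upgma(self):
        # d(a,b)=2, d(c,d)=4, all cross distances 10:
        # merges (a,b)@1, (c,d)@2, then ((ab),(cd)) at 10/2=5
        D = pd.DataFrame(
            [
                [0, 2, 10, 10],
                [2, 0, 10, 10],
                [10, 10, 0, 4],
                [10, 10, 4, 0],
            ],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        from microsearch.phylo import parse_newick

        tree = parse_newick(hierarchical_cluster(D))
        # leaf depths: a,b at 5; c,d at 5 (ultrametric root height 5)
        for leaf in "abcd":
            path = tree.ancestor_path(leaf)
            depth = sum(tree.nodes[n].length for n in path[:-1])
            assert depth == pytest.approx(5.0, abs=1e-9)
        ab = tree.nodes[tree.nodes[tree.leaf_index["a"]].parent]
        assert {tree.nodes[c].label for c in ab.children} == {"a", "b"}
        assert tree.nodes[tree.leaf_index["a"]].length == pytest.approx(1.0)
        assert tree.nodes[tree.leaf_index["c"]].length == pytest.approx(2.0)


class TestEmpiricalPvalues:
    DISTS = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])

    def test_exact_fraction(self):
        table = build_pvalue_table(self.DISTS)
        assert empirical_pvalue(table, 0.35) == pytest.approx(0.5)

    def test_zero_distance(self):
        table = build_pvalue_table(self.DISTS)
        assert empirical_pvalue(table, 0.0) == 0.0

    def test_beyond_maximum(self):
        table = build_pvalue_table(self.DISTS)
        assert empirical_pvalue(table, 0.7) == 1.0

    def test_total_pairs(self):
        table = build_pvalue_table(self.DISTS)
        assert table.total_pairs == 6
        assert table.cumulative[-1] == 6

    def test_table_matches_exact_counting_within_one_bin(self):
        rng = np.random.default_rng(8)
        dists = rng.uniform(0, 1, size=500)
        table = build_pvalue_table(dists, bins=1000)
        width = table.bin_edges[1] - table.bin_edges[0]
        for d in rng.uniform(0, 1.1, size=50):
            exact = (dists < d).mean()
            approx = empirical_pvalue(table, d)
            shifted = (dists < max(d - width, 0.0)).mean()
            assert shifted <= approx <= exact + 1e-12

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        table = build_pvalue_table(rng.uniform(0, 1, size=200))
        grid = np.linspace(0, 1.2, 100)
        ps = [empirical_pvalue(table, d) for d in grid]
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))


class TestRepresentatives:
    def test_small_pool_returned_whole(self, small_world):
        db = small_world["db"]
        reps = select_representatives(db, "eco1", max_n=1000)
        assert reps == sorted(
            s for s in db.sample_ids if db.ecosystem(s) == "eco1"
        )

    def test_all_filter_spans_every_ecosystem(self, small_world):
        db = small_world["db"]
        reps = select_representatives(db, "All", max_n=9, seed=0)
        assert len(reps) <= 9
        assert {db.ecosystem(s) for s in reps} == {"eco1", "eco2", "eco3"}

    def test_seed_determinism(self, small_world):
        db = small_world["db"]
        a = select_representatives(db, "All", max_n=7, seed=3)
        b = select_representatives(db, "All", max_n=7, seed=3)
        assert a == b


class TestAnalysisRuns:
    def test_identical_query_ranks_first_with_zero_pvalue(self, small_world):
        db, tree = small_world["db"], small_world["tree"]
        pt = build_pvalue_table(db.precalc.condensed())
        q = AbundanceProfile("q", dict(db.profiles[4].counts))
        res = run_type1(db, [q], tree, "gnat", pvalues=pt, seed=0)
        top = res.ranking.per_query["q"][0]
        assert top.sample_id == db.profiles[4].sample_id
        assert top.distance == 0.0
        assert top.p_value == 0.0

    def test_identical_queries_get_identical_rankings(self, small_world):
        db, tree = small_world["db"], small_world["tree"]
        counts = dict(db.profiles[2].counts)
        res = run_type1(
            db,
            [AbundanceProfile("qa", counts), AbundanceProfile("qb", counts)],
            tree, "aesa", seed=0,
        )
        ra = [(m.sample_id, m.distance) for m in res.ranking.per_query["qa"]]
        rb = [(m.sample_id, m.distance) for m in res.ranking.per_query["qb"]]
        assert ra == rb

    def test_ecosystem_recovery(self, small_world):
        # well-separated ecosystems: top-k majority shares the query label
        db, tree = small_world["db"], small_world["tree"]
        q = AbundanceProfile("q", dict(db.profiles[0].counts))  # eco1
        res = run_type1(db, [q], tree, "gnat", radius=0.4, k=5, seed=0)
        labels = [m.ecosystem for m in res.ranking.per_query["q"]]
        assert labels.count("eco1") > len(labels) / 2

    def test_ranking_matches_linear_oracle(self, small_world):
        from microsearch.metric_index import linear_range_search

        db, tree, metric = (
            small_world["db"], small_world["tree"], small_world["metric"],
        )
        q = AbundanceProfile("q", dict(db.profiles[9].counts))
        res = run_type1(db, [q], tree, "gnat", radius=0.3, k=db.size, seed=0)
        lin = linear_range_search(db, q, 0.3, metric)
        got = [(m.sample_id, m.distance) for m in res.ranking.per_query["q"]]
        want = [(s, lin.evaluated[s]) for s in lin.hits]
        assert [g[0] for g in got] == [w[0] for w in want]
        for (_, dg), (_, dw) in zip(got, want):
            assert dg == pytest.approx(dw, abs=1e-12)

    def test_query_limit_enforced(self, small_world):
        db, tree = small_world["db"], small_world["tree"]
        queries = [
            AbundanceProfile(f"q{i}", dict(db.profiles[i % 5].counts))
            for i in range(11)
        ]
        with pytest.raises(ValueError, match="10"):
            run_type1(db, queries, tree, "gnat")
        res = run_type1(db, queries, tree, "gnat", max_queries=11, seed=0)
        assert len(res.ranking.per_query) > 0

    def test_type2_query_equal_to_representative(self, small_world):
        db = small_world["db"]
        q = AbundanceProfile("q", dict(db.profiles[6].counts))
        res = run_type2(db, [q], "All", seed=0)
        top = res.ranking.per_query["q"][0]
        assert top.sample_id == db.profiles[6].sample_id
        assert top.distance == 0.0

    def test_type2_distances_bounded(self, small_world):
        db = small_world["db"]
        q = AbundanceProfile("q", dict(db.profiles[8].counts))
        res = run_type2(db, [q], "All", seed=0)
        mat = res.context.full_matrix.values
        assert (mat >= 0).all() and (mat <= 1).all()

    def test_type2_top_match_shares_ecosystem(self, small_world):
        db = small_world["db"]
        q = AbundanceProfile("q", dict(db.profiles[1].counts))  # eco2
        res = run_type2(db, [q], "All", seed=0)
        assert res.ranking.per_query["q"][0].ecosystem == "eco2"


class TestComposition:
    TAX = TaxonomyTable(
        {
            "o1": ("k", "PX", "c1", "ord", "f", "g", "s1"),
            "o2": ("k", "PY", "c2", "ord", "f", "g", "s2"),
        }
    )

    def test_query_order_drives_both_columns(self):
        q = AbundanceProfile("q", {"o1": 0.6, "o2": 0.4})
        m = AbundanceProfile("m", {"o1": 0.5, "o2": 0.5})
        out = composition_comparison(q, m, self.TAX, ("phylum",))
        assert out["phylum"] == [("PX", 0.6, 0.5), ("PY", 0.4, 0.5)]

    def test_absent_taxon_reports_zero(self):
        q = AbundanceProfile("q", {"o1": 1.0})
        m = AbundanceProfile("m", {"o2": 1.0})
        out = composition_comparison(q, m, self.TAX, ("phylum",))
        assert out["phylum"] == [("PX", 1.0, 0.0), ("PY", 0.0, 1.0)]

    def test_identical_profiles_identical_columns(self):
        q = AbundanceProfile("q", {"o1": 2, "o2": 6})
        m = AbundanceProfile("m", {"o1": 2, "o2": 6})
        out = composition_comparison(q, m, self.TAX, ("phylum", "class"))
        for rank in ("phylum", "class"):
            for _, qf, mf in out[rank]:
                assert qf == pytest.approx(mf)
            assert sum(r[1] for r in out[rank]) == pytest.approx(1.0)


class TestKeyIndexFalseNegatives:
    def test_percentage_rule_on_published_counts(self):
        assert false_negative_percentage(28_247, 351) == 1.24
        assert false_negative_percentage(96_977, 1_402) == 1.45
        assert false_negative_percentage(846_107, 14_993) == 1.77
        assert false_negative_percentage(4_847_874, 91_902) == 1.90

    def test_undefined_when_no_pairs_below_threshold(self):
        assert false_negative_percentage(0, 0) is None

    def test_shared_key_fixture_has_zero_differing(self):
        store = DistanceStore(
            ["a", "b", "c"],
            np.array([[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]]),
        )
        keys = {s: ("P1", "P2") for s in store.ids}
        rows = phyla_index_fn_table(store, keys, [0.05, 0.3])
        assert rows[0] == (0.05, 0, 0, None)
        assert rows[1] == (0.3, 3, 0, 0.0)

    def test_counts_and_percentage_consistent(self, small_world):
        from microsearch.profiles import phyla_key

        db, tax = small_world["db"], small_world["tax"]
        keys = {p.sample_id: phyla_key(p, tax) for p in db.profiles}
        rows = phyla_index_fn_table(db.precalc, keys, [0.2, 0.4])
        for t, total, diff, pct in rows:
            assert 0 <= diff <= total
            if total:
                assert pct == pytest.approx(100 * diff / total, abs=0.005)


class TestDefaults:
    def test_documented_parameter_defaults(self):
        assert engine.DEFAULT_RADIUS == 0.3
        assert engine.SUPPORTED_RADII == (0.1, 0.2, 0.3, 0.4)
        assert engine.DEFAULT_TOP_K == 20
        assert engine.DEFAULT_BINS == 10_000
        assert engine.DEFAULT_MAX_REPRESENTATIVES == 1000
        assert engine.MAX_QUERIES_GNAT == 10
        assert engine.MAX_QUERIES_AESA == 100
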