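"""Hypergeometric enrichment, gene-complex association FDR, query ranking."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from demap import (
    GeneSetCatalog,
    InteractionNetwork,
    ThresholdConfig,
    complex_association,
    complex_summary,
    degree_fitness_correlation,
    rank_queries,
    sensitive_pair_enrichment,
    top_queries,
)
from demap._stats import hypergeom_tail
from demap.differential import DifferentialTable


def enumerate_tail(k, N, K, n):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = total = 0
    marked = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,N,K,n,expected",
        [
            (2, 10, 4, 3, 1 / 3),     # (C(4,2)C(6,1)+C(4,3)) / C(10,3)
            (2, 5, 2, 2, 0.1),        # 1 / C(5,2)
        ],
    )
    def test_small_universe_closed_forms(self, k, N, K, n, expected):
        assert hypergeom_tail(k, N, K, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_small_universes(self):
        for N in (5, 8, 10, 12):
            for K in (0, 2, N // 2):
                for n in (1, 3, min(5, N)):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeom_tail(k, N, K, n) == pytest.approx(
                            enumerate_tail(k, N, K, n), abs=1e-12
                        )


def _diff_net(cond, pairs):
    edges = pd.DataFrame(
        [(q, a, 2.5, 2.5, 1) for q, a in pairs],
        columns=["query", "array", "score", "z", "sign"],
    )
    return InteractionNetwork(cond, "differential", edges, 2.0)


class TestSensitivePairEnrichment:
    def test_example_universe(self):
        # universe of 10 pairs, 4 sensitive (both endpoints), network of 3 with 2
        sens = {"S1", "S2", "S3"}
        universe = (
            [("S1", "S2"), ("S1", "S3"), ("S2", "S3"), ("S3", "S1")]  # 4 sensitive
            + [("S1", "X1"), ("X1", "X2"), ("X2", "X3"), ("X3", "X4"),
               ("X4", "X5"), ("X5", "X6")]
        )
        net = _diff_net("SO", [("S1", "S2"), ("S1", "S3"), ("X1", "X2")])
        res = sensitive_pair_enrichment(net, sens, universe)
        assert res.observed == 2 and res.draws == 3
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert res.fold == pytest.approx(2 / (3 * 4 / 10))

    def test_network_equal_to_universe_gives_p_one(self):
        sens = {"S1", "S2"}
        universe = [("S1", "S2"), ("S1", "X"), ("X", "Y")]
        net = _diff_net("SO", universe)
        res = sensitive_pair_enrichment(net, sens, universe)
        assert res.observed == res.successes_in_universe == 1
        assert res.p_value == pytest.approx(1.0)

    def test_no_sensitive_pairs_in_universe(self):
        res = sensitive_pair_enrichment(
            _diff_net("SO", [("A", "B")]), {"Z"}, [("A", "B"), ("C", "D")]
        )
        assert np.isnan(res.fold) and res.p_value == 1.0

    def test_relaxed_single_endpoint_mode(self):
        sens = {"S1"}
        universe = [("S1", "X"), ("X", "Y")]
        net = _diff_net("SO", [("S1", "X")])
        strict = sensitive_pair_enrichment(net, sens, universe)
        relaxed = sensitive_pair_enrichment(net, sens, universe, both_endpoints=False)
        assert strict.successes_in_universe == 0
        assert relaxed.successes_in_universe == 1


def _z_tables(z_by_cond, queries, arrays):
    return {
        cond: DifferentialTable(cond, "S1", pd.DataFrame(z, index=queries, columns=arrays))
        for cond, z in z_by_cond.items()
    }


class TestComplexAssociation:
    def test_all_partners_in_complex_example(self):
        """Universe of 20 array genes, complex of 5, query with 4 partners all
        inside: p = C(5,4)C(15,0)/C(20,4) = 5/4845."""
        arrays = [f"A{i:02d}" for i in range(20)]
        z = np.zeros((1, 20))
        z[0, :4] = 3.0  # 4 differential partners, all members
        cat = GeneSetCatalog()
        cat.add("CPLX", arrays[:5], kind="complex")
        tables = _z_tables({"SO": z}, ["Q1"], arrays)
        res = complex_association(tables, cat, ThresholdConfig(), n_perm=200, seed=0)
        row = res.iloc[0]
        assert row["observed"] == 4
        assert row["p_value"] == pytest.approx(5 / math.comb(20, 4), abs=1e-12)

    def test_zero_partner_query_not_significant(self):
        arrays = [f"A{i:02d}" for i in range(20)]
        cat = GeneSetCatalog()
        cat.add("CPLX", arrays[:5], kind="complex")
        tables = _z_tables({"SO": np.zeros((1, 20))}, ["Q1"], arrays)
        res = complex_association(tables, cat, ThresholdConfig(), n_perm=200, seed=0)
        assert res.iloc[0]["p_value"] == 1.0
        assert not res.iloc[0]["significant"]

    def test_small_complexes_skipped(self):
        arrays = [f"A{i:02d}" for i in range(10)]
        cat = GeneSetCatalog()
        cat.add("TINY", arrays[:3], kind="complex")
        tables = _z_tables({"SO": np.zeros((1, 10))}, ["Q1"], arrays)
        with pytest.warns(UserWarning, match="skipped"):
            res = complex_association(tables, cat, ThresholdConfig(), n_perm=200, seed=0)
        assert res.empty

    def test_fdr_reproducible_and_monotone(self, rng):
        arrays = [f"A{i:03d}" for i in range(60)]
        queries = ["Q1", "Q2", "Q3"]
        z = rng.normal(size=(3, 60)) * 1.5
        cat = GeneSetCatalog()
        for i in range(4):
            cat.add(f"C{i}", arrays[i * 10:(i + 1) * 10], kind="complex")
        tables = _z_tables({"SO": z}, queries, arrays)
        r1 = complex_association(tables, cat, ThresholdConfig(), n_perm=300, seed=42)
        r2 = complex_association(tables, cat, ThresholdConfig(), n_perm=300, seed=42)
        pd.testing.assert_frame_equal(r1, r2)
        # monotone non-decreasing FDR in p within each (query, condition) family
        for _, fam in r1.groupby(["condition", "query"]):
            fam = fam.sort_values("p_value")
            assert (np.diff(fam["fdr"]) >= -1e-12).all()

    def test_summary_counts_significant_triples(self):
        df = pd.DataFrame(
            {
                "condition": ["SO", "OX", "SO"],
                "query": ["Q1", "Q1", "Q2"],
                "complex": ["C1", "C1", "C2"],
                "significant": [True, True, False],
            }
        )
        s = complex_summary(df)
        assert s.to_dict() == {"C1": 2}


class TestRankQueries:
    def test_fractions_and_tie_break(self):
        net = _diff_net(
            "SO",
            [("Q1", "a"), ("Q1", "b"), ("Q1", "c"), ("Q2", "d"), ("Q2", "e"), ("Q3", "f")],
        )
        ranking = rank_queries({"SO": net})
        assert list(ranking["query"]) == ["Q1", "Q2", "Q3"]
        assert list(ranking["fraction"]) == pytest.approx([0.5, 1 / 3, 1 / 6])
        # tie: equal degrees ordered alphabetically
        net2 = _diff_net("SO", [("QB", "a"), ("QB", "b"), ("QA", "c"), ("QA", "d")])
        r2 = rank_queries({"SO": net2})
        assert list(r2["query"]) == ["QA", "QB"]

    def test_single_query_holds_all_edges(self):
        net = _diff_net("SO", [("Q1", "a"), ("Q1", "b")])
        r = rank_queries({"SO": net})
        assert r.iloc[0]["fraction"] == 1.0

    def test_fractions_sum_to_one(self, rng):
        pairs = {(f"Q{rng.integers(5)}", f"A{i}") for i in range(40)}
        r = rank_queries({"SO": _diff_net("SO", sorted(pairs))})
        assert r["fraction"].sum() == pytest.approx(1.0)

    def test_top_k_extraction(self):
        net = _diff_net("SO", [(f"Q{i:02d}", "a") for i in range(30)])
        r = top_queries(rank_queries({"SO": net}), k=20)
        assert len(r) == 20


class TestDegreeFitnessCorrelation:
    def test_perfect_correlations(self):
        r, n, p = degree_fitness_correlation(
            {"A": 1, "B": 2, "C": 3, "D": 4}, {"A": 2, "B": 4, "C": 6, "D": 8}
        )
        assert r == pytest.approx(1.0)
        r, _, _ = degree_fitness_correlation(
            {"A": 1, "B": 2, "C": 3, "D": 4}, {"A": 4, "B": 3, "C": 2, "D": 1}
        )
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        genes = [f"G{i}" for i in range(10)]
        deg = {g: float(v) for g, v in zip(genes, rng.integers(0, 20, 10))}
        smf = {g: float(v) for g, v in zip(genes, rng.normal(size=10))}
        r, n, p = degree_fitness_correlation(deg, smf)
        x = np.array([deg[g] for g in sorted(genes)])
        y = np.array([smf[g] for g in sorted(genes)])
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(manual, abs=1e-12)
        assert n == 10

    def test_exclusion_and_minimum_size(self):
        deg = {"A": 1, "B": 2, "C": 3, "D": 10}
        smf = {"A": 1, "B": 2, "C": 3, "D": 10}
        r_all, n_all, _ = degree_fitness_correlation(deg, smf)
        r_ex, n_ex, _ = degree_fitness_correlation(deg, smf, exclude=["D"])
        assert n_all == 4 and n_ex == 3
        with pytest.raises(ValueError):
            degree_fitness_correlation(deg, smf, exclude=["B", "C", "D"])
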