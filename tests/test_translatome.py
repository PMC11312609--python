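"""Delta ranking, concordance, response correlation and hypergeometric ORA."""

import math

import numpy as np
import pandas as pd
import pytest

from trapseq import translatome
from trapseq.translatome import (
    concordance_shift,
    hypergeom_ora,
    response_correlation,
    ribo_total_delta,
    top_n_by_delta,
)


def de_table(genes, lfc, se=None, p=None, padj=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "log2FC": lfc,
            "se": se if se is not None else [0.2] * n,
            "p": p if p is not None else [0.5] * n,
            "padj": padj if padj is not None else [0.5] * n,
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestDelta:
    def test_hand_example(self):
        # lfc_ribo 1.0 (se 0.2) vs lfc_total 0.2 (se 0.2)
        d = ribo_total_delta(de_table(["g1"], [1.0]), de_table(["g1"], [0.2]),
                             min_mean_tpm=0)
        assert d.loc["g1", "delta"] == pytest.approx(0.8)
        assert d.loc["g1", "se_delta"] == pytest.approx(0.28284, abs=1e-4)
        assert d.loc["g1", "z"] == pytest.approx(2.8284, abs=1e-3)
        assert d.loc["g1", "p"] == pytest.approx(0.00468, abs=2e-5)

    def test_equal_contrasts_give_zero(self):
        a = de_table(["g1", "g2"], [0.7, -0.3])
        d = ribo_total_delta(a, a.copy(), min_mean_tpm=0)
        assert np.allclose(d["delta"], 0.0)
        assert np.allclose(d["p"], 1.0)

    def test_antisymmetric_under_contrast_swap(self):
        a = de_table(["g1", "g2", "g3"], [1.0, -0.5, 0.2])
        b = de_table(["g1", "g2", "g3"], [0.2, 0.4, -0.1])
        d_ab = ribo_total_delta(a, b, min_mean_tpm=0)
        d_ba = ribo_total_delta(b, a, min_mean_tpm=0)
        assert np.allclose(d_ab["delta"], -d_ba.loc[d_ab.index, "delta"])

    def test_only_shared_genes_kept_and_empty_rejected(self):
        a = de_table(["g1", "g2"], [1.0, 0.5])
        b = de_table(["g2", "g3"], [0.2, 0.1])
        d = ribo_total_delta(a, b, min_mean_tpm=0)
        assert list(d.index) == ["g2"]
        with pytest.raises(ValueError, match="no shared genes"):
            ribo_total_delta(a, de_table(["gX"], [0.1]), min_mean_tpm=0)

    def test_tpm_floor_applied(self):
        a = de_table(["g1", "g2"], [1.0, 1.0])
        tpm = pd.Series([500.0, 5.0], index=["g1", "g2"])
        d = ribo_total_delta(a, a.copy(), mean_tpm=tpm, min_mean_tpm=100)
        assert list(d.index) == ["g1"]


class TestTopN:
    def test_full_universe_ordered(self):
        d = ribo_total_delta(de_table(["a", "b", "c"], [3.0, 1.0, 2.0]),
                             de_table(["a", "b", "c"], [0.0, 0.0, 0.0]),
                             min_mean_tpm=0)
        assert top_n_by_delta(d, 3, "up") == ["a", "c", "b"]
        assert top_n_by_delta(d, 1, "down") == ["b"]

    def test_tie_break_lexicographic(self):
        d = ribo_total_delta(de_table(["zz", "aa"], [1.0, 1.0]),
                             de_table(["zz", "aa"], [0.0, 0.0]), min_mean_tpm=0)
        assert top_n_by_delta(d, 1, "up") == ["aa"]

    def test_n_beyond_universe_rejected(self):
        d = ribo_total_delta(de_table(["a"], [1.0]), de_table(["a"], [0.0]),
                             min_mean_tpm=0)
        with pytest.raises(ValueError, match="exceeds"):
            top_n_by_delta(d, 2, "up")


class TestConcordance:
    def test_fraction_arithmetic(self):
        # 10 LDF-up responsive genes, 8 with ECKO LFC > 0.5
        genes = [f"g{i}" for i in range(10)]
        cond = de_table(genes, [1.0] * 10, p=[0.01] * 10)
        pert = de_table(genes, [1.0] * 8 + [0.0, -1.0])
        # add a down-responsive gene so both directions exist
        cond.loc["gd"] = {"log2FC": -1.0, "se": 0.2, "p": 0.01, "padj": 0.01}
        pert.loc["gd"] = {"log2FC": -1.0, "se": 0.2, "p": 0.01, "padj": 0.01}
        s = concordance_shift(cond, pert)
        assert s.n_up_ldf == 10
        assert s.frac_up_further_up == pytest.approx(0.80)
        assert s.frac_down_further_down == pytest.approx(1.0)

    def test_fisher_table_hand_value(self):
        # quadrant table [[3,1],[1,3]] -> two-sided p = 34/70
        up = [f"u{i}" for i in range(4)]
        down = [f"d{i}" for i in range(4)]
        cond = de_table(up + down, [1.0] * 4 + [-1.0] * 4, p=[0.001] * 8)
        pert = de_table(up + down, [1, 1, 1, -1, 1, -1, -1, -1])
        s = concordance_shift(cond, pert)
        assert s.fisher_p == pytest.approx(34 / 70)

    def test_quadrants_partition_threshold_input(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        cond = de_table(genes, rng.normal(0, 1, 20), p=list(rng.uniform(0, 0.2, 20)))
        pert = de_table(genes, rng.normal(0, 1, 20))
        s = concordance_shift(cond, pert, ldf_p_thresh=0.1)
        got = sorted(g for q in s.quadrants.values() for g in q)
        resp = cond[(cond["p"] < 0.1) & (cond["log2FC"] != 0)]
        assert got == sorted(resp.index)

    def test_no_responsive_genes_rejected(self):
        cond = de_table(["g1"], [1.0], p=[0.9])
        with pytest.raises(ValueError, match="responsive"):
            concordance_shift(cond, cond.copy())


class TestResponseCorrelation:
    def test_identity_and_negation(self):
        a = de_table(["a", "b", "c"], [1.0, 2.0, 3.0])
        assert response_correlation(a, a.copy()) == pytest.approx(1.0)
        b = de_table(["a", "b", "c"], [-1.0, -2.0, -3.0])
        assert response_correlation(a, b) == pytest.approx(-1.0)

    def test_hand_vectors(self):
        # r of (1,2,3) vs (2,4,7) = 5 / sqrt(2 * 114/9) = 0.99340
        a = de_table(["a", "b", "c"], [1.0, 2.0, 3.0])
        b = de_table(["a", "b", "c"], [2.0, 4.0, 7.0])
        assert response_correlation(a, b) == pytest.approx(0.99340, abs=1e-5)
        assert response_correlation(a, b, "r_squared") == pytest.approx(0.99340**2, abs=1e-5)

    def test_constant_vector_rejected(self):
        a = de_table(["a", "b", "c"], [1.0, 1.0, 1.0])
        b = de_table(["a", "b", "c"], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            response_correlation(a, b)


def ora_oracle(N, K, n, k):
    """Exact upper-tail hypergeometric by fraction arithmetic."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(n, K) + 1)) / total


class TestOra:
    def test_hand_tail(self):
        # N=20, K=5, n=5, k=3 -> 1126/15504
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        sets = {"s": [f"g{i}" for i in range(2, 7)]}  # overlap 3
        res = hypergeom_ora(query, universe, sets)
        assert res.loc["s", "overlap"] == 3
        assert res.loc["s", "p"] == pytest.approx(1126 / 15504)

    def test_zero_overlap_p_at_most_one(self):
        universe = {f"g{i}" for i in range(30)}
        res = hypergeom_ora({"g0"}, universe, {"s": ["g20", "g21"]})
        assert 0.0 <= res.loc["s", "p"] <= 1.0

    def test_query_equals_set_equals_universe(self):
        universe = {"a", "b", "c"}
        res = hypergeom_ora(universe, universe, {"s": list(universe)})
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeom_ora({"x"}, {"a"}, {"s": ["a"]})

    def test_matches_enumeration_small_grid(self):
        universe = [f"g{i}" for i in range(12)]
        sets = {}
        expected = {}
        n = 5
        query = set(universe[:n])
        for K in range(1, 10):
            for k in range(max(0, n + K - 12), min(n, K) + 1):
                if n - k + K > 12:
                    continue
                name = f"K{K}k{k}"
                sets[name] = universe[n - k : n - k + K]  # exact overlap k
                expected[name] = ora_oracle(12, K, n, k)
        res = hypergeom_ora(query, set(universe), sets)
        for name, e in expected.items():
            assert res.loc[name, "p"] == pytest.approx(e, rel=1e-9)
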