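"""NB Wald differential expression: size factors, GLM, BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trapseq.diffexpr import ContrastSpec, bh_adjust, fit_nb_wald, size_factors
from trapseq.simulate import EffectBlock, SimulationConfig, simulate_counts

from conftest import make_metadata


def brute_force_size_factors(mat: np.ndarray) -> np.ndarray:
    """Independent re-derivation of median-of-ratios from its definition."""
    logs = np.log(mat.astype(float))
    geo = np.exp(logs.mean(axis=1))
    ok = np.isfinite(logs).all(axis=1)
    s = np.array([np.median(mat[ok, j] / geo[ok]) for j in range(mat.shape[1])])
    return s / np.exp(np.mean(np.log(s)))


class TestSizeFactors:
    def test_hand_example(self):
        # genes x samples [[2,8],[2,8]]: geomeans 4,4; ratios 0.5 / 2.0
        df = pd.DataFrame([[2, 8], [2, 8]], columns=["a", "b"])
        s = size_factors(df)
        assert np.allclose(s.to_numpy(), [0.5, 2.0])

    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame([[5, 5, 5], [9, 9, 9], [2, 2, 2]], columns=list("abc"))
        assert np.allclose(size_factors(df).to_numpy(), 1.0)

    def test_scaled_column_scales_its_factor(self):
        base = pd.DataFrame([[10, 20, 30], [6, 12, 18], [100, 200, 300]],
                            columns=list("abc"))
        tripled = base.copy()
        tripled["b"] = base["b"] * 3
        s0, s1 = size_factors(base), size_factors(tripled)
        assert np.isclose(s1["b"] / s0["b"] / (s1["a"] / s0["a"]), 3.0)

    def test_no_universally_expressed_gene_rejected(self):
        df = pd.DataFrame([[0, 5], [5, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="filter"):
            size_factors(df)


class TestBhAdjust:
    def test_hand_step_up(self):
        out = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_na_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.04])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariant_and_monotone(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = bh_adjust(p[perm])
        assert np.allclose(adj[perm], adj_perm)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()


def two_group_gcm(counts_a, counts_b):
    """Genes x (3+3) toy matrix as a GeneCountMatrix."""
    from trapseq.io import GeneCountMatrix

    meta = make_metadata(
        [(f"a{i}", "ribosomal", "LDF", "WT") for i in range(len(counts_a[0]))]
        + [(f"b{i}", "ribosomal", "contralateral", "WT") for i in range(len(counts_b[0]))]
    )
    arr = np.hstack([np.array(counts_a), np.array(counts_b)])
    counts = pd.DataFrame(arr, index=pd.Index([f"g{i}" for i in range(arr.shape[0])],
                                              name="gene_id"), columns=meta.index)
    return GeneCountMatrix(counts=counts, samples=meta)


CONTRAST = ContrastSpec("condition", "LDF", "contralateral", {"fraction": "ribosomal"})


class TestNbWald:
    def test_identical_groups_give_zero_lfc_p_one(self):
        gcm = two_group_gcm([[100, 100, 100]] * 3, [[100, 100, 100]] * 3)
        res = fit_nb_wald(gcm, CONTRAST)
        assert np.allclose(res["log2FC"], 0.0, atol=1e-10)
        assert np.allclose(res["p"], 1.0)

    def test_closed_form_beta_on_toy(self):
        """With a saturated two-group design and within-group-constant
        offsets, beta equals log2 of the ratio of normalized group means
        exactly (the NB score equations then have that closed form)."""
        gcm = two_group_gcm([[120, 120, 120], [40, 40, 40], [75, 75, 75]],
                            [[60, 60, 60], [44, 44, 44], [100, 100, 100]])
        s = size_factors(gcm.counts).to_numpy()
        norm = gcm.counts.to_numpy() / s
        expected = np.log2(norm[:, :3].mean(axis=1) / norm[:, 3:].mean(axis=1))
        res = fit_nb_wald(gcm, CONTRAST)
        assert np.allclose(res["log2FC"].to_numpy(), expected, atol=1e-6)

    def test_all_zero_group_gets_continuity_correction(self):
        gcm = two_group_gcm([[50, 60, 55], [0, 0, 0]], [[50, 60, 55], [30, 35, 32]])
        res = fit_nb_wald(gcm, CONTRAST)
        assert bool(res.loc["g1", "continuity"])
        assert np.isfinite(res.loc["g1", "log2FC"])
        assert res.loc["g1", "log2FC"] < -3  # strongly depleted, not -inf

    def test_monotone_wald_z_in_planted_lfc(self):
        """Mean |z| over planted genes never decreases as the planted
        LFC grows (same seed)."""
        mean_absz = []
        planted = tuple(f"g{i:04d}" for i in range(100))
        for lfc in (0.5, 1.0, 2.0):
            cfg = SimulationConfig(
                seed=3, n_genes=500, replicates=5, fractions=("ribosomal",),
                genotypes=("WT",), contamination={}, contaminant_genes=(),
                effects=(EffectBlock(genes=planted, lfc_condition_ribo=lfc),),
                baseline_overrides={g: 200.0 for g in planted},
            )
            gcm, _ = simulate_counts(cfg)
            res = fit_nb_wald(gcm, CONTRAST)
            mean_absz.append(res.loc[list(planted), "z"].abs().mean())
        assert mean_absz[0] < mean_absz[1] < mean_absz[2]

    def test_matches_statsmodels_glm(self):
        """Cross-check beta and se against an independent NB GLM fit
        (statsmodels, same fixed dispersion and offsets)."""
        import statsmodels.api as sm

        cfg = SimulationConfig(seed=9, n_genes=30, replicates=5, fractions=("ribosomal",),
                               genotypes=("WT",), contamination={}, contaminant_genes=())
        gcm, _ = simulate_counts(cfg)
        res = fit_nb_wald(gcm, CONTRAST)
        sel = CONTRAST.select(gcm.samples)
        sub = gcm.counts[sel.index]
        s = size_factors(sub).to_numpy()
        x = (sel["condition"] == "LDF").to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        ln2 = np.log(2)
        for g in gcm.counts.index[:10]:
            alpha = res.loc[g, "dispersion"]
            glm = sm.GLM(sub.loc[g].to_numpy(), X,
                         family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=np.log(s)).fit()
            assert res.loc[g, "log2FC"] == pytest.approx(glm.params[1] / ln2, abs=1e-4)
            assert res.loc[g, "se"] == pytest.approx(glm.bse[1] / ln2, rel=1e-3)

    def test_tpm_floor_excluded_before_bh(self):
        cfg = SimulationConfig(seed=10, n_genes=200, replicates=4, fractions=("ribosomal",),
                               genotypes=("WT",), contamination={}, contaminant_genes=())
        gcm, _ = simulate_counts(cfg)
        res_all = fit_nb_wald(gcm, CONTRAST)
        res_floor = fit_nb_wald(gcm, CONTRAST, min_mean_tpm=2000.0)
        assert len(res_floor) < len(res_all)

    def test_too_few_replicates_rejected(self):
        gcm = two_group_gcm([[10], [10]], [[10, 12], [8, 9]])
        with pytest.raises(ValueError, match=">= 2"):
            fit_nb_wald(gcm, CONTRAST)
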