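"""Negative-binomial Wald differential expression for two-group contrasts.

The model is the standard RNA-seq count GLM: counts ~ NB(mu, alpha) with
variance mu + alpha*mu^2, log link, median-of-ratios size factors as
offsets, and a two-group design (intercept + group indicator).  Per-gene
dispersion is estimated by method of moments on normalized counts pooled
within groups, then shrunk 50/50 toward a fitted mean-dispersion trend
alpha(mu) = a0 + a1/mu.  The group coefficient is the natural-log fold
change; it is reported in log2 with its Wald standard error, z, p, and
Benjamini-Hochberg adjusted p.

This is a documented, testable stand-in for DESeq2-style analyses; it
deliberately omits empirical-Bayes dispersion shrinkage, LFC shrinkage
and outlier handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneCountMatrix

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
MIN_DISPERSION = 1e-8
MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8


@dataclass
class ContrastSpec:
    """A two-level contrast on one metadata factor within an optional stratum.

    ``level_a`` is the numerator: positive log2FC means higher in
    ``level_a`` than in ``level_b``.  ``stratum`` fixes other factors,
    e.g. ``{"fraction": "ribosomal", "condition": "LDF"}``.
    """

    factor: str
    level_a: str
    level_b: str
    stratum: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level_a == self.level_b:
            raise ValueError("contrast levels must differ")

    def select(self, samples: pd.DataFrame) -> pd.DataFrame:
        sel = samples
        for col, val in self.stratum.items():
            sel = sel[sel[col] == val]
        sel = sel[sel[self.factor].isin([self.level_a, self.level_b])]
        for level in (self.level_a, self.level_b):
            n = (sel[self.factor] == level).sum()
            if n < 2:
                raise ValueError(
                    f"contrast level {self.factor}={level} has {n} samples "
                    f"in stratum {self.stratum}; need >= 2"
                )
        return sel


def size_factors(counts: GeneCountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median over genes with positive geometric mean of
    count_gj / geomean_g; requires at least one gene expressed in every
    sample.
    """
    mat = counts.counts if isinstance(counts, GeneCountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(arr).mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter genes or samples first"
        )
    ratios = arr[usable] / np.exp(loggeo[usable])[:, None]
    s = np.median(ratios, axis=0)
    if (s <= 0).any():
        raise ValueError("non-positive size factor; sample with too many zero counts")
    s /= np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=mat.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion per gene, pooled within groups.

    Uses the within-group sample variance (ddof=1) of normalized counts;
    alpha = (var - mean) / mean^2.  Returns raw (possibly negative)
    estimates; flooring and trend shrinkage happen in the caller.
    """
    mean_all = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    df = 0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        df += sub.shape[1] - 1
    pooled_var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean_all) / mean_all**2
    return np.where(mean_all > 0, alpha, 0.0)


def _dispersion_trend(mean: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu on genes with positive raw estimates."""
    ok = (alpha_raw > 0) & (mean > 0)
    if ok.sum() < 10:  # too few informative genes: flat trend at the mean
        level = float(np.mean(alpha_raw[ok])) if ok.any() else 0.01
        return np.full_like(mean, max(level, MIN_DISPERSION))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / mean
    return np.maximum(trend, MIN_DISPERSION)


def _irls_two_group(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the two-group NB GLM for all genes at once.

    y: genes x samples counts; x: 0/1 group indicator per sample;
    offset: log size factor per sample; alpha: per-gene dispersion.
    Returns (beta1 natural-log LFC, se of beta1, converged flag).
    """
    G, N = y.shape
    s = np.exp(offset)[None, :]
    # init from group means of normalized counts (0.5 guards all-zero groups)
    norm = y / s
    m1 = norm[:, x == 1].mean(axis=1)
    m0 = norm[:, x == 0].mean(axis=1)
    b0 = np.log(np.maximum(m0, 0.5))
    b1 = np.log(np.maximum(m1, 0.5)) - b0
    converged = np.zeros(G, dtype=bool)
    a = alpha[:, None]
    for _ in range(MAX_IRLS_ITER):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        S = w.sum(axis=1)
        Sx = (w * x[None, :]).sum(axis=1)
        Sz = (w * z).sum(axis=1)
        Sxz = (w * x[None, :] * z).sum(axis=1)
        det = S * Sx - Sx**2  # Sxx == Sx for binary x
        nb0 = (Sx * Sz - Sx * Sxz) / det
        nb1 = (S * Sxz - Sx * Sz) / det
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        newly = (step < IRLS_TOL) & ~converged
        converged |= newly
        if converged.all():
            break
    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + a * mu)
    S = w.sum(axis=1)
    Sx = (w * x[None, :]).sum(axis=1)
    var_b1 = S / (Sx * (S - Sx))
    return b1, np.sqrt(var_b1), converged


def fit_nb_wald(
    gcm: GeneCountMatrix,
    contrast: ContrastSpec,
    min_mean_tpm: float = 0.0,
) -> pd.DataFrame:
    """NB Wald test of ``contrast`` on ``gcm``.

    Returns a DataFrame indexed by gene_id with columns baseMean,
    log2FC, se, z, p, padj, continuity (0.5-count correction applied)
    and converged.  Genes below the mean-TpM floor (computed over the
    stratum samples) are excluded before testing and before the BH m.
    Non-converged genes get p = NA and are excluded from BH.
    """
    sel = contrast.select(gcm.samples)
    sub = gcm.subset_samples(list(sel.index))
    counts = sub.counts

    if min_mean_tpm > 0:
        from .qc import compute_tpm  # local import: qc depends on io only

        tpm = compute_tpm(sub)
        keep = tpm.mean(axis=1) >= min_mean_tpm
        logger.info("TpM floor %g: %d of %d genes retained", min_mean_tpm, keep.sum(), len(keep))
        counts = counts[keep]
        if counts.empty:
            raise ValueError("no genes pass the mean-TpM floor")

    s = size_factors(counts)
    x = (sel[contrast.factor] == contrast.level_a).to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float)
    offset = np.log(s.to_numpy())

    # continuity correction for groups that are all-zero: +0.5 everywhere
    zero_a = y[:, x == 1].sum(axis=1) == 0
    zero_b = y[:, x == 0].sum(axis=1) == 0
    continuity = zero_a | zero_b
    y = np.where(continuity[:, None], y + 0.5, y)

    norm = y / np.exp(offset)[None, :]
    base_mean = norm.mean(axis=1)
    groups = x.astype(int)
    alpha_raw = _mom_dispersion(norm, groups)
    alpha_floored = np.maximum(alpha_raw, MIN_DISPERSION)
    trend = _dispersion_trend(base_mean, alpha_raw)
    alpha = 0.5 * alpha_floored + 0.5 * trend

    b1, se_ln, converged = _irls_two_group(y, x, offset, alpha)
    log2fc = b1 / LN2
    se = se_ln / LN2
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(converged, p, np.nan)
    if not converged.all():
        logger.warning("%d gene(s) failed IRLS convergence; p set to NA", (~converged).sum())

    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "se": se,
            "z": z,
            "p": p,
            "padj": bh_adjust(p),
            "dispersion": alpha,
            "continuity": continuity,
            "converged": converged,
        },
        index=counts.index,
    )
    return res


def bh_adjust(pvals) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    NA inputs are excluded from m and returned as NA.  Output is capped
    at 1 and monotone in p-rank; ties share the smaller adjusted value.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    if isinstance(pvals, pd.Series):
        return pd.Series(out, index=pvals.index, name="padj")
    return out
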