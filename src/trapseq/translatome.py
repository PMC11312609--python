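"""Ribosome-vs-total translational-shift analyses.

A gene regulated at the level of ribosome association — rather than
transcript abundance — responds in the TRAP (ribosome-bound) fraction
but not in total mRNA.  The delta statistic quantifies this: delta =
lfc_ribo - lfc_total for the same condition contrast run in the two
fractions, with se_delta = sqrt(se_r^2 + se_t^2) treating the contrasts
as independent (different animals feed the two library types).  The
concordance analysis asks whether a perturbation (e.g. a RBP knockout)
pushes condition-responsive genes further in the direction of their
condition response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


def _align(a: pd.DataFrame, b: pd.DataFrame) -> pd.Index:
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared genes between the two contrasts")
    dropped = len(a.index.union(b.index)) - len(shared)
    if dropped:
        logger.info("delta: %d gene(s) present in only one contrast, excluded", dropped)
    return shared


def ribo_total_delta(
    de_ribo: pd.DataFrame,
    de_total: pd.DataFrame,
    mean_tpm: pd.Series | None = None,
    min_mean_tpm: float = 100.0,
) -> pd.DataFrame:
    """Translational-shift statistic per gene.

    ``de_ribo``/``de_total`` are DE tables (log2FC, se columns) for the
    same condition comparison in the ribosomal and total fraction.
    ``mean_tpm``, when given, is the per-gene mean TpM across all
    samples of both fractions; genes below ``min_mean_tpm`` are dropped
    before testing.  Returns delta, se_delta, z, normal p, BH padj, and
    a deterministic signed rank (1 = largest delta; ties by gene_id).
    """
    shared = _align(de_ribo, de_total)
    if mean_tpm is not None and min_mean_tpm > 0:
        ok = mean_tpm.reindex(shared) >= min_mean_tpm
        shared = shared[ok.fillna(False).to_numpy()]
        if shared.empty:
            raise ValueError("no genes pass the mean-TpM floor")
    r = de_ribo.loc[shared]
    t = de_total.loc[shared]
    delta = r["log2FC"] - t["log2FC"]
    se = np.sqrt(r["se"] ** 2 + t["se"] ** 2)
    z = delta / se
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=shared)
    out = pd.DataFrame(
        {
            "lfc_ribo": r["log2FC"],
            "lfc_total": t["log2FC"],
            "delta": delta,
            "se_delta": se,
            "z": z,
            "p": p,
            "padj": bh_adjust(p),
        }
    )
    out = out.sort_index(kind="mergesort").sort_values(
        by="delta", ascending=False, kind="mergesort"
    )  # stable sort after index sort: ties fall in gene_id order
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_n_by_delta(delta: pd.DataFrame, n: int = 300, direction: str = "up") -> list[str]:
    """The ``n`` genes with the most extreme signed delta in one direction.

    ``direction="up"`` takes the largest deltas (ribosome-enriched
    responders), ``"down"`` the smallest.  Ties break lexicographically
    by gene_id.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if n > len(delta):
        raise ValueError(f"n={n} exceeds universe of {len(delta)} genes")
    asc = direction == "down"
    ordered = delta.sort_index(kind="mergesort").sort_values(
        by="delta", ascending=asc, kind="mergesort"
    )
    return list(ordered.index[:n])


@dataclass
class ConcordanceSummary:
    """Direction agreement between a condition response and a
    perturbation response, on genes beyond an LFC threshold."""

    n_up_ldf: int
    n_down_ldf: int
    frac_up_further_up: float
    frac_down_further_down: float
    fisher_p: float
    quadrants: dict[str, list[str]] = field(default_factory=dict)


def concordance_shift(
    de_condition: pd.DataFrame,
    de_perturbation: pd.DataFrame,
    ldf_p_thresh: float = 0.05,
    ecko_lfc_thresh: float = 0.5,
    use_padj: bool = False,
    perturbation_p_thresh: float | None = None,
) -> ConcordanceSummary:
    """Fraction of condition-responsive genes shifted further by a
    perturbation.

    ``de_condition`` selects responsive genes (p or padj below
    ``ldf_p_thresh``), split by LFC sign.  Within each direction we
    report the fraction whose perturbation LFC exceeds
    ``+ecko_lfc_thresh`` (for condition-up genes) or falls below
    ``-ecko_lfc_thresh`` (for condition-down); genes between the
    thresholds count against the fraction but enter neither tail of the
    Fisher table.  ``perturbation_p_thresh`` optionally additionally
    requires perturbation significance.  The Fisher exact test
    associates condition direction with beyond-threshold perturbation
    direction.
    """
    shared = _align(de_condition, de_perturbation)
    cond = de_condition.loc[shared]
    pert = de_perturbation.loc[shared]
    pcol = "padj" if use_padj else "p"
    responsive = cond[pcol] < ldf_p_thresh
    if not responsive.any():
        raise ValueError("no condition-responsive genes at the chosen threshold")
    if perturbation_p_thresh is not None:
        responsive &= pert["p"] < perturbation_p_thresh
    up = responsive & (cond["log2FC"] > 0)
    down = responsive & (cond["log2FC"] < 0)

    pert_up = pert["log2FC"] > ecko_lfc_thresh
    pert_down = pert["log2FC"] < -ecko_lfc_thresh

    quadrants = {
        "ldf_up_ecko_up": sorted(shared[up & pert_up]),
        "ldf_up_ecko_down": sorted(shared[up & pert_down]),
        "ldf_up_between": sorted(shared[up & ~pert_up & ~pert_down]),
        "ldf_down_ecko_up": sorted(shared[down & pert_up]),
        "ldf_down_ecko_down": sorted(shared[down & pert_down]),
        "ldf_down_between": sorted(shared[down & ~pert_up & ~pert_down]),
    }
    n_up, n_down = int(up.sum()), int(down.sum())
    frac_up = len(quadrants["ldf_up_ecko_up"]) / n_up if n_up else np.nan
    frac_down = len(quadrants["ldf_down_ecko_down"]) / n_down if n_down else np.nan
    table = [
        [len(quadrants["ldf_up_ecko_up"]), len(quadrants["ldf_up_ecko_down"])],
        [len(quadrants["ldf_down_ecko_up"]), len(quadrants["ldf_down_ecko_down"])],
    ]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return ConcordanceSummary(
        n_up_ldf=n_up,
        n_down_ldf=n_down,
        frac_up_further_up=frac_up,
        frac_down_further_down=frac_down,
        fisher_p=float(fisher_p),
        quadrants=quadrants,
    )


def response_correlation(
    de_a: pd.DataFrame, de_b: pd.DataFrame, method: str = "pearson"
) -> float:
    """Pearson r (or r^2) of the two contrasts' LFC vectors on the
    shared gene universe."""
    if method not in ("pearson", "r_squared"):
        raise ValueError("method must be 'pearson' or 'r_squared'")
    shared = _align(de_a, de_b)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    x = de_a.loc[shared, "log2FC"].to_numpy()
    y = de_b.loc[shared, "log2FC"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant LFC vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r * r if method == "r_squared" else r


def hypergeom_ora(
    query: set[str], universe: set[str], gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
    n=|query|); BH across sets.  ``query`` must be a subset of
    ``universe``; sets are intersected with the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query genes outside the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & set(universe)
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K, "query_size": n,
                     "universe_size": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    out["bh_q"] = bh_adjust(out["p"])
    return out.sort_values(by=["p", "set"], kind="mergesort")
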