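"""TpM quantification and TRAP fraction-purity QC.

The purity check mirrors the standard TRAP validation: transcripts
marking contaminating cell types (mural cells, myeloid cells) should be
depleted in the ribosome-bound pulldown relative to a total-mRNA flush,
while endothelial hallmark transcripts should be retained or enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneCountMatrix

logger = logging.getLogger(__name__)

#: pseudocount in TpM units added before log-ratios (markers may be 0
#: in the purified fraction)
TPM_PSEUDOCOUNT = 0.5


@dataclass
class MarkerPanel:
    """A named marker gene set with its expected direction in the
    ribosomal fraction relative to the reference fraction."""

    name: str
    genes: list[str]
    expected_direction: str  # "enriched" | "depleted"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker panel '{self.name}' is empty")
        if self.expected_direction not in ("enriched", "depleted"):
            raise ValueError("expected_direction must be 'enriched' or 'depleted'")


def compute_tpm(gcm: GeneCountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized counts scaled so each
    sample column sums to 1e6.

    tpm_gj = (count_gj / length_g) / sum_g(count_gj / length_g) * 1e6.
    An all-zero sample yields an all-zero column with a logged warning.
    """
    if gcm.gene_lengths is None:
        raise ValueError("gene_lengths required for TpM")
    rate = gcm.counts.to_numpy(dtype=float) / gcm.gene_lengths.to_numpy()[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("all-zero sample column(s): %s", list(np.array(gcm.sample_ids)[zero]))
        colsum = np.where(zero, 1.0, colsum)
    tpm = rate / colsum[None, :] * 1e6
    return pd.DataFrame(tpm, index=gcm.counts.index, columns=gcm.counts.columns)


def _resolve(samples: pd.DataFrame, selector) -> list[str]:
    """A selector is a list of sample_ids or a {column: value} mapping."""
    if isinstance(selector, dict):
        sel = samples
        for col, val in selector.items():
            sel = sel[sel[col] == val]
        ids = list(sel.index)
    else:
        ids = list(selector)
        missing = [s for s in ids if s not in samples.index]
        if missing:
            raise ValueError(f"unknown sample(s): {missing}")
    if not ids:
        raise ValueError(f"sample selector {selector!r} matches no samples")
    return ids


def marker_qc(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    panels: list[MarkerPanel],
    group_a,
    group_b,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Per-panel mean TpM in two sample groups and their log2 ratio.

    The panel statistic is the mean over genes of the per-gene mean TpM
    (panels are small, 1-3 genes); the ratio uses a 0.5-TpM pseudocount.
    Panels whose observed direction contradicts ``expected_direction``
    are flagged.  Missing panel genes raise unless ``allow_missing``.
    """
    ids_a = _resolve(samples, group_a)
    ids_b = _resolve(samples, group_b)
    rows = []
    for panel in panels:
        missing = [g for g in panel.genes if g not in tpm.index]
        if missing and not allow_missing:
            raise ValueError(f"panel '{panel.name}': gene(s) absent from matrix: {missing}")
        genes = [g for g in panel.genes if g in tpm.index]
        if not genes:
            raise ValueError(f"panel '{panel.name}': no panel gene present")
        mean_a = float(tpm.loc[genes, ids_a].mean(axis=1).mean())
        mean_b = float(tpm.loc[genes, ids_b].mean(axis=1).mean())
        ratio = np.log2((mean_a + TPM_PSEUDOCOUNT) / (mean_b + TPM_PSEUDOCOUNT))
        if abs(ratio) < 1e-12:
            status = "no change"
        else:
            observed = "enriched" if ratio > 0 else "depleted"
            status = "ok" if observed == panel.expected_direction else "contradicts expectation"
        rows.append(
            {
                "panel": panel.name,
                "n_genes": len(genes),
                "missing_genes": ",".join(missing),
                "mean_tpm_a": mean_a,
                "mean_tpm_b": mean_b,
                "log2_ratio": float(ratio),
                "expected": panel.expected_direction,
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("panel")


def marker_qc_genes(
    tpm: pd.DataFrame, samples: pd.DataFrame, panels: list[MarkerPanel], group_a, group_b
) -> pd.DataFrame:
    """Per-gene companion to :func:`marker_qc` (mean TpM per group per gene)."""
    ids_a = _resolve(samples, group_a)
    ids_b = _resolve(samples, group_b)
    rows = []
    for panel in panels:
        for g in panel.genes:
            if g not in tpm.index:
                continue
            a = float(tpm.loc[g, ids_a].mean())
            b = float(tpm.loc[g, ids_b].mean())
            rows.append(
                {
                    "panel": panel.name,
                    "gene_id": g,
                    "mean_tpm_a": a,
                    "mean_tpm_b": b,
                    "log2_ratio": np.log2((a + TPM_PSEUDOCOUNT) / (b + TPM_PSEUDOCOUNT)),
                }
            )
    return pd.DataFrame(rows)


def fraction_binding_report(
    tpm: pd.DataFrame, samples: pd.DataFrame, gene: str
) -> dict[str, float]:
    """Per-gene mean TpM in the ribosomal vs unbound fraction and their
    ratio — pure reporting of bead retention, no test."""
    if gene not in tpm.index:
        raise ValueError(f"gene '{gene}' absent from matrix")
    out = {}
    for fraction in ("ribosomal", "unbound"):
        ids = samples.index[samples["fraction"] == fraction]
        if len(ids) == 0:
            raise ValueError(f"no samples with fraction={fraction}")
        out[f"mean_tpm_{fraction}"] = float(tpm.loc[gene, ids].mean())
    out["ratio_ribosomal_vs_unbound"] = (out["mean_tpm_ribosomal"] + TPM_PSEUDOCOUNT) / (
        out["mean_tpm_unbound"] + TPM_PSEUDOCOUNT
    )
    return out
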