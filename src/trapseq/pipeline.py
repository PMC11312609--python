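"""End-to-end orchestration of the synthetic TRAP-seq walkthrough.

``run_all`` executes the stages in dependency order — simulate, purity
QC, four DE contrasts, ribo-vs-total delta ranking, knockout
concordance, splicing (cluster filter, PSI, delta-PSI, z-scores), flank
motif enrichment, and gene-set ORA — writing TSV outputs and a JSON
manifest of per-file SHA-256 hashes.  All stages are pure functions of
the config and its seed: rerunning into a fresh directory is
byte-identical.

Thresholds default to the constants of the emulated study: responsive
genes at p < 0.05, knockout shift beyond +/-0.5 log2FC, mean-TpM floor
100 for the top-300 delta ranking, 50 split reads per intron cluster,
200 bp flanks and 6-mers for motif scanning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import motifscan, qc, splicing, translatome
from .diffexpr import ContrastSpec, fit_nb_wald
from .simulate import EffectBlock, SimulationConfig, emit_dataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "de", "delta", "concordance", "splice", "motifs", "ora")


@dataclass
class PipelineConfig:
    """Single source of all pipeline thresholds and paths."""

    outdir: str
    seed: int
    sim: SimulationConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    data_dir: str | None = None  # reuse an existing emitted dataset
    ldf_p: float = 0.05
    ecko_lfc: float = 0.5
    tpm_floor: float = 100.0
    top_n: int = 300
    min_cluster_reads: int = 50
    min_coverage: int = 10
    window: int = 200
    k: int = 6
    dpsi_p: float = 0.05
    bg_ratio: int = 3
    bg_bins: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for name in ("ldf_p", "ecko_lfc", "tpm_floor", "top_n", "min_cluster_reads",
                     "window", "k", "dpsi_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.sim is None:
            self.sim = default_world(self.seed)


def default_world(seed: int) -> SimulationConfig:
    """The default stated world for the synthetic walkthrough.

    2000 genes, 5 replicates per arm, NB dispersion 0.1; 50 pure
    translational-shift genes (ribosomal LFC 1, total 0) held at
    baseline mean 200; 100 flow-up and 100 flow-down genes (LFC +/-1 in
    both fractions), 80% of each further shifted in the same direction
    by the knockout (LFC +/-1 in the ribosomal fraction) and 20%
    opposed; three contaminant marker genes mixed in at 10% (total) vs
    1% (ribosomal); 60 cassette exons, 20 regulated at delta-psi 0.4,
    with an AU-rich 6-mer planted in 60% of regulated flanks.
    """
    n = 2000
    markers = ("Smtn", "Cd68", "Adgre1")
    ids = [f"g{i:04d}" for i in range(n - len(markers))]
    te = tuple(ids[0:50])
    up, down = ids[50:150], ids[150:250]
    effects = (
        EffectBlock(genes=te, lfc_condition_ribo=1.0),
        EffectBlock(genes=tuple(up[:80]), lfc_condition_total=1.0,
                    lfc_condition_ribo=1.0, lfc_genotype_ribo=1.0),
        EffectBlock(genes=tuple(up[80:]), lfc_condition_total=1.0,
                    lfc_condition_ribo=1.0, lfc_genotype_ribo=-1.0),
        EffectBlock(genes=tuple(down[:80]), lfc_condition_total=-1.0,
                    lfc_condition_ribo=-1.0, lfc_genotype_ribo=-1.0),
        EffectBlock(genes=tuple(down[80:]), lfc_condition_total=-1.0,
                    lfc_condition_ribo=-1.0, lfc_genotype_ribo=1.0),
    )
    return SimulationConfig(
        seed=seed,
        n_genes=n,
        effects=effects,
        baseline_overrides={g: 200.0 for g in te},
        contaminant_genes=markers,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_inputs(config: PipelineConfig, data: Path) -> None:
    """Fail before any computation if an enabled stage lacks its input."""
    if "simulate" in config.stages:
        return
    needed = {"qc": ["counts.tsv", "metadata.tsv"],
              "de": ["counts.tsv", "metadata.tsv"],
              "delta": ["counts.tsv", "metadata.tsv"],
              "concordance": ["counts.tsv", "metadata.tsv"],
              "splice": ["events.tsv", "junctions"],
              "motifs": ["events.tsv", "junctions", "genome.fa", "motifs.txt"],
              "ora": ["gene_sets.gmt"]}
    for stage in config.stages:
        for rel in needed.get(stage, []):
            if not (data / rel).exists():
                raise FileNotFoundError(f"stage '{stage}' requires missing input {data / rel}")


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = Path(config.data_dir) if config.data_dir else outdir / "data"
    _validate_inputs(config, data)

    stage_info: dict[str, dict] = {}

    if "simulate" in config.stages:
        emit_dataset(config.sim, data, force=True)
        stage_info["simulate"] = {"n_genes": config.sim.n_genes,
                                  "n_events": config.sim.n_events,
                                  "config_hash": _stage_hash(config.sim)}

    gcm = tio.read_counts_tsv(data / "counts.tsv", data / "metadata.tsv")
    tpm = qc.compute_tpm(gcm)

    if "qc" in config.stages:
        markers = [g for g in ("Smtn", "Cd68", "Adgre1") if g in tpm.index]
        panels = [qc.MarkerPanel("contaminant_markers", markers, "depleted")] if markers else []
        if panels:
            report = qc.marker_qc(
                tpm, gcm.samples, panels,
                group_a={"fraction": "ribosomal"}, group_b={"fraction": "total"},
            )
            tio.write_results_table(report, outdir / "qc_markers.tsv", what="marker_qc")
            stage_info["qc"] = {"n_panels": len(report)}
        else:
            logger.info("qc: no marker genes present, skipping panel report")
            stage_info["qc"] = {"n_panels": 0}

    de: dict[str, pd.DataFrame] = {}
    if "de" in config.stages:
        contrasts = {
            "ribo_ldf_vs_con_wt": ContrastSpec("condition", "LDF", "contralateral",
                                               {"fraction": "ribosomal", "genotype": "WT"}),
            "total_ldf_vs_con_wt": ContrastSpec("condition", "LDF", "contralateral",
                                                {"fraction": "total", "genotype": "WT"}),
            "ribo_ecko_vs_wt_ldf": ContrastSpec("genotype", "ECKO", "WT",
                                                {"fraction": "ribosomal", "condition": "LDF"}),
            "total_ecko_vs_wt_ldf": ContrastSpec("genotype", "ECKO", "WT",
                                                 {"fraction": "total", "condition": "LDF"}),
        }
        for name, spec in contrasts.items():
            try:
                res = fit_nb_wald(gcm, spec)
            except ValueError as exc:
                logger.info("contrast %s skipped: %s", name, exc)
                continue
            de[name] = res
            tio.write_results_table(res, outdir / f"de_{name}.tsv", what=f"de {name}")
            stage_info.setdefault("de", {})[name] = {
                "n_genes": len(res),
                "n_padj_lt_05": int((res["padj"] < 0.05).sum()),
            }

    if "delta" in config.stages and {"ribo_ldf_vs_con_wt", "total_ldf_vs_con_wt"} <= de.keys():
        wt = gcm.samples["genotype"] == "WT"
        mean_tpm = tpm.loc[:, wt[wt].index].mean(axis=1)
        delta = translatome.ribo_total_delta(
            de["ribo_ldf_vs_con_wt"], de["total_ldf_vs_con_wt"],
            mean_tpm=mean_tpm, min_mean_tpm=config.tpm_floor,
        )
        tio.write_results_table(delta, outdir / "delta_ribo_vs_total.tsv", what="delta")
        top_n = min(config.top_n, len(delta))
        if top_n < config.top_n:
            logger.warning("delta universe %d < top_n %d; clamped", len(delta), config.top_n)
        top_up = translatome.top_n_by_delta(delta, top_n, "up")
        top_down = translatome.top_n_by_delta(delta, top_n, "down")
        (outdir / "delta_top_up.txt").write_text("\n".join(top_up) + "\n")
        (outdir / "delta_top_down.txt").write_text("\n".join(top_down) + "\n")
        r2 = translatome.response_correlation(
            de["ribo_ldf_vs_con_wt"], de["total_ldf_vs_con_wt"], "r_squared")
        stage_info["delta"] = {"n_universe": len(delta), "top_n": top_n,
                               "r_squared_ribo_vs_total": round(float(r2), 4)}

    if "concordance" in config.stages and {"ribo_ldf_vs_con_wt", "ribo_ecko_vs_wt_ldf"} <= de.keys():
        summ = translatome.concordance_shift(
            de["ribo_ldf_vs_con_wt"], de["ribo_ecko_vs_wt_ldf"],
            ldf_p_thresh=config.ldf_p, ecko_lfc_thresh=config.ecko_lfc,
        )
        payload = dataclasses.asdict(summ)
        with open(outdir / "concordance.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        stage_info["concordance"] = {
            "n_up_ldf": summ.n_up_ldf, "n_down_ldf": summ.n_down_ldf,
            "frac_up_further_up": round(summ.frac_up_further_up, 4),
            "frac_down_further_down": round(summ.frac_down_further_down, 4),
            "fisher_p": summ.fisher_p,
        }

    events = junctions = dpsi = None
    if "splice" in config.stages or "motifs" in config.stages:
        events = splicing.read_events_tsv(data / "events.tsv")
        jdir = data / "junctions"
        paths = sorted(jdir.glob("*.SJ.out.tab"))
        junctions = tio.read_junctions(paths, dialect="sj_tab")

    if "splice" in config.stages:
        clustered = splicing.cluster_filter(junctions, config.min_cluster_reads)
        psi = splicing.psi_table(events, clustered, config.min_coverage)
        samples = list(junctions.columns)
        grp_ldf = [s for s in samples if "_ldf_" in s]
        grp_con = [s for s in samples if "_con_" in s]
        dpsi = splicing.dpsi_table(events, clustered, grp_ldf, grp_con, config.min_coverage)
        z, constant = splicing.psi_zscores(psi)
        tio.write_results_table(psi, outdir / "psi.tsv", what="psi")
        tio.write_results_table(dpsi, outdir / "dpsi.tsv", what="dpsi")
        tio.write_results_table(z, outdir / "psi_zscores.tsv", what="psi_zscores")
        stage_info["splice"] = {
            "n_events": len(events),
            "n_junctions_clustered": len(clustered),
            "n_p_lt_05": int((dpsi["p"] < config.dpsi_p).sum()),
            "n_padj_lt_05": int((dpsi["padj"] < 0.05).sum()),
        }

    if "motifs" in config.stages:
        genome = tio.read_fasta(data / "genome.fa")
        motif_sets = tio.read_motif_config(data / "motifs.txt", config.k)
        if dpsi is None:
            clustered = splicing.cluster_filter(junctions, config.min_cluster_reads)
            samples = list(junctions.columns)
            dpsi = splicing.dpsi_table(
                events, clustered,
                [s for s in samples if "_ldf_" in s],
                [s for s in samples if "_con_" in s],
                config.min_coverage,
            )
        regulated_ids = set(dpsi.index[(dpsi["p"] < config.dpsi_p).fillna(False)])
        by_id = {ev.event_id: ev for ev in events}
        regulated = [by_id[i] for i in sorted(regulated_ids) if i in by_id]
        candidates = [ev for ev in events if ev.event_id not in regulated_ids]
        level = _event_coverage(events, junctions)
        if not regulated or not candidates:
            logger.warning("motifs: %d regulated / %d candidate events; stage skipped",
                           len(regulated), len(candidates))
            stage_info["motifs"] = {"skipped": True}
        else:
            background = motifscan.match_background(
                regulated, candidates, level,
                bins=config.bg_bins, ratio=config.bg_ratio, seed=config.seed,
            )
            fg = motifscan.extract_flanks(regulated, genome, config.window)
            bg = motifscan.extract_flanks(background, genome, config.window)
            table = motifscan.kmer_enrichment(fg, bg, region="both", k=config.k)
            ranking = motifscan.rbp_aggregate(table, motif_sets)
            tio.write_results_table(table, outdir / "kmer_enrichment.tsv",
                                    what="kmer_enrichment")
            tio.write_results_table(ranking, outdir / "rbp_ranking.tsv", what="rbp_ranking")
            stage_info["motifs"] = {
                "n_fg": len(fg), "n_bg": len(bg),
                "top_kmer": str(table["fisher_p"].idxmin()),
                "top_rbp": str(ranking.index[0]),
            }

    if "ora" in config.stages and "ribo_ldf_vs_con_wt" in de:
        gene_sets = tio.read_gmt(data / "gene_sets.gmt")
        res = de["ribo_ldf_vs_con_wt"]
        universe = set(res.index)
        query = set(res.index[(res["padj"] < 0.05).fillna(False)])
        if query:
            ora = translatome.hypergeom_ora(query, universe, gene_sets)
            tio.write_results_table(ora, outdir / "ora.tsv", what="ora")
            stage_info["ora"] = {"n_query": len(query),
                                 "top_set": str(ora.index[0])}
        else:
            stage_info["ora"] = {"n_query": 0}

    manifest = {
        "seed": config.seed,
        "stages": stage_info,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _stage_hash(sim: SimulationConfig) -> str:
    from .simulate import config_hash

    return config_hash(sim)


def _event_coverage(events, junctions: pd.DataFrame) -> dict[str, float]:
    """Mean per-sample total junction coverage per event (the
    detection-level axis for background matching)."""
    out = {}
    for ev in events:
        total = 0.0
        for key in (ev.i1, ev.i2, ev.e):
            if key in junctions.index:
                total += float(junctions.loc[key].sum())
        out[ev.event_id] = total / junctions.shape[1]
    return out
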