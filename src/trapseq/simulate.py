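"""Synthetic TRAP-seq datasets with machine-readable planted truth.

Emulates a paired-artery, two-fraction (total / ribosome-bound), two-
genotype bulk RNA-seq design.  Gene counts are negative binomial with
mean

    mu_gj = s_j * ( (1 - c_f) * q_g * 2^(sum of effects for sample j)
                    + c_f * contaminant_g )

and variance mu + alpha*mu^2: q_g is the gene's baseline expression,
s_j a log-normal size factor, c_f a fraction-specific contamination
proportion mixing in a contaminant cell-type profile concentrated on
marker genes (mural / myeloid markers are depleted by TRAP pulldown,
which is what the purity QC measures).  Effects are log2 fold changes
attached to gene blocks per (factor, fraction): a gene can respond to
the flow condition in total mRNA, in ribosome-bound mRNA (a pure
translational shift when the two differ), and to the genotype.

Cassette-exon splicing is simulated as junction counts: total cluster
coverage T ~ NB, inclusion reads ~ BetaBinomial(T, psi_arm, rho), the
two inclusion junctions split by a fair binomial, and a 6-mer motif
planted into the flanks of regulated exons on an otherwise uniform
i.i.d. DNA genome (background 6-mer frequency ~ 4^-6).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .motifscan import revcomp
from .splicing import ExonEvent, write_events_tsv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectBlock:
    """A planted log2-fold-change block for a set of genes.

    Condition effects apply to LDF samples (contralateral is the
    reference); genotype effects apply to ECKO samples.  A gene whose
    ribosomal condition effect differs from its total effect is a
    translational (TE) shift by construction.  ``lfc_binding`` is a
    constant ribosomal-fraction enrichment (bead retention), applied in
    both conditions.
    """

    genes: tuple[str, ...]
    lfc_condition_total: float = 0.0
    lfc_condition_ribo: float = 0.0
    lfc_genotype_ribo: float = 0.0
    lfc_genotype_total: float = 0.0
    lfc_binding: float = 0.0


@dataclass(frozen=True)
class PsiBlock:
    """Planted inclusion levels for a cassette exon: baseline psi in the
    contralateral arm and the LDF shift (clipped to [0.02, 0.98])."""

    event_id: str
    psi_contra: float
    dpsi: float = 0.0


@dataclass
class SimulationConfig:
    """The stated world of the generator; the seed is mandatory.

    Defaults follow the emulated study design: 5 replicates per arm,
    NB dispersion 0.1, contamination 10% into total and 1% into the
    TRAP pulldown, cassette-exon coverage ~100 with beta-binomial
    overdispersion 0.05, a planted delta-psi of 0.4, and an AU-rich
    planted 6-mer inserted into 60% of regulated-exon flanks.
    """

    seed: int
    n_genes: int = 2000
    n_events: int = 60
    n_regulated_events: int = 20
    replicates: int = 5
    fractions: tuple[str, ...] = ("total", "ribosomal")
    genotypes: tuple[str, ...] = ("WT", "ECKO")
    nb_dispersion: float = 0.1
    poisson: bool = False  # alpha -> 0 limit
    baseline_log2_range: tuple[float, float] = (3.0, 11.0)
    baseline_overrides: dict[str, float] = field(default_factory=dict)
    gene_length_range: tuple[int, int] = (500, 5000)
    size_factor_sd: float = 0.15
    effects: tuple[EffectBlock, ...] = ()
    contamination: dict[str, float] = field(
        default_factory=lambda: {"total": 0.10, "ribosomal": 0.01, "unbound": 0.10}
    )
    contaminant_genes: tuple[str, ...] = ()
    # splicing
    psi_blocks: tuple[PsiBlock, ...] = ()
    psi_baseline_range: tuple[float, float] = (0.25, 0.6)
    dpsi: float = 0.4
    psi_rho: float = 0.05
    coverage_mean: float = 100.0
    coverage_dispersion: float = 0.1
    splice_replicates: int = 6
    # motif planting
    planted_motif: str = "TTTATT"
    motif_insert_prob: float = 0.6
    flank_window: int = 200

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f, c in self.contamination.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"contamination[{f}] not in [0,1]")
        if not 0.0 <= self.motif_insert_prob <= 1.0:
            raise ValueError("motif_insert_prob not in [0,1]")
        if not 0.0 <= self.psi_rho < 1.0:
            raise ValueError("psi_rho not in [0,1)")
        for block in self.effects:
            if not all(np.isfinite(
                [block.lfc_condition_total, block.lfc_condition_ribo,
                 block.lfc_genotype_ribo, block.lfc_genotype_total, block.lfc_binding]
            )):
                raise ValueError("non-finite LFC in effect block")


@dataclass
class TruthTables:
    """Planted truth: per-gene LFCs/flags, per-event psi, motif
    insertions and contamination — the reference for recovery tests."""

    genes: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    motif_insertions: pd.DataFrame | None = None
    contamination: dict[str, float] = field(default_factory=dict)
    planted_motif: str = ""


def gene_ids(config: SimulationConfig) -> list[str]:
    ids = [f"g{i:04d}" for i in range(config.n_genes - len(config.contaminant_genes))]
    return ids + list(config.contaminant_genes)


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for gt in config.genotypes:
        for fr in config.fractions:
            for cond in tio.CONDITIONS:
                for rep in range(1, config.replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{gt}_{fr}_{'ldf' if cond == 'LDF' else 'con'}_r{rep}",
                            "fraction": fr,
                            "condition": cond,
                            "genotype": gt,
                            "sex": "unknown",
                            "pair_id": f"{gt}_{fr}_m{rep}",
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float, poisson: bool) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    if poisson or alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimulationConfig) -> tuple[tio.GeneCountMatrix, TruthTables]:
    """Draw the full gene-level count matrix plus its truth tables."""
    rng = np.random.default_rng([config.seed, 0])
    ids = gene_ids(config)
    idx = pd.Index(ids, name="gene_id")
    design = _design(config)

    lo, hi = config.baseline_log2_range
    q = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)
    lengths = rng.integers(*config.gene_length_range, size=config.n_genes)

    truth = pd.DataFrame(
        {
            "baseline_mean": q,
            "length": lengths,
            "lfc_condition_total": 0.0,
            "lfc_condition_ribo": 0.0,
            "lfc_genotype_ribo": 0.0,
            "lfc_genotype_total": 0.0,
            "lfc_binding": 0.0,
            "is_contaminant": [g in config.contaminant_genes for g in ids],
        },
        index=idx,
    )
    for g, mean in config.baseline_overrides.items():
        if g not in truth.index:
            raise ValueError(f"baseline override for unknown gene '{g}'")
        truth.loc[g, "baseline_mean"] = mean
    for block in config.effects:
        unknown = [g for g in block.genes if g not in truth.index]
        if unknown:
            raise ValueError(f"effect block references unknown gene(s): {unknown}")
        gl = list(block.genes)
        truth.loc[gl, "lfc_condition_total"] += block.lfc_condition_total
        truth.loc[gl, "lfc_condition_ribo"] += block.lfc_condition_ribo
        truth.loc[gl, "lfc_genotype_ribo"] += block.lfc_genotype_ribo
        truth.loc[gl, "lfc_genotype_total"] += block.lfc_genotype_total
        truth.loc[gl, "lfc_binding"] += block.lfc_binding
    truth["te_shift"] = truth["lfc_condition_ribo"] != truth["lfc_condition_total"]

    # contaminant profile: library mass concentrated uniformly on markers
    contam = np.zeros(config.n_genes)
    if config.contaminant_genes:
        mass = truth["baseline_mean"].sum()
        w = mass / len(config.contaminant_genes)
        contam[[ids.index(g) for g in config.contaminant_genes]] = w

    s = np.exp(rng.normal(0.0, config.size_factor_sd, size=len(design)))
    s /= np.exp(np.mean(np.log(s)))

    counts = np.empty((config.n_genes, len(design)), dtype=np.int64)
    base = truth["baseline_mean"].to_numpy()
    for j, (sid, row) in enumerate(design.iterrows()):
        lfc = np.zeros(config.n_genes)
        if row["condition"] == "LDF":
            if row["fraction"] == "total":
                lfc += truth["lfc_condition_total"].to_numpy()
            elif row["fraction"] == "ribosomal":
                lfc += truth["lfc_condition_ribo"].to_numpy()
        if row["genotype"] == "ECKO":
            if row["fraction"] == "ribosomal":
                lfc += truth["lfc_genotype_ribo"].to_numpy()
            elif row["fraction"] == "total":
                lfc += truth["lfc_genotype_total"].to_numpy()
        if row["fraction"] == "ribosomal":
            lfc += truth["lfc_binding"].to_numpy()
        c = config.contamination.get(row["fraction"], 0.0)
        mu = s[j] * ((1.0 - c) * base * 2.0**lfc + c * contam)
        counts[:, j] = _nb_draw(rng, mu, config.nb_dispersion, config.poisson)

    gcm = tio.GeneCountMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=design.index),
        samples=design,
        gene_lengths=pd.Series(lengths, index=idx, name="length"),
    )
    tt = TruthTables(
        genes=truth,
        contamination=dict(config.contamination),
        planted_motif=config.planted_motif,
    )
    return gcm, tt


# ---------------------------------------------------------------------------
# Splicing + genome + motif planting
# ---------------------------------------------------------------------------

_EXON_U, _EXON_C, _EXON_D = 120, 90, 130
_INTRON = 500  # > flank window so flanks stay intronic
_SPACER = 200


def _layout_events(config: SimulationConfig) -> tuple[list[ExonEvent], int]:
    events = []
    pos = _SPACER
    for i in range(config.n_events):
        u_start = pos
        u_end = u_start + _EXON_U
        c_start = u_end + _INTRON
        c_end = c_start + _EXON_C
        d_start = c_end + _INTRON
        d_end = d_start + _EXON_D
        strand = "+" if i % 2 == 0 else "-"
        events.append(ExonEvent(f"ev{i:03d}", "chrSim", strand,
                                u_start, u_end, c_start, c_end, d_start, d_end))
        pos = d_end + _SPACER
    return events, pos + _SPACER


def _plant_motif(
    genome: list[str],
    event: ExonEvent,
    which: str,
    offset: int,
    motif: str,
    window: int,
) -> None:
    """Write ``motif`` at transcript-orientation ``offset`` inside one
    flank, editing the genome in place."""
    if which == "upstream":
        gwin = (event.c_start - window, event.c_start) if event.strand == "+" else (
            event.c_end, event.c_end + window)
    else:
        gwin = (event.c_end, event.c_end + window) if event.strand == "+" else (
            event.c_start - window, event.c_start)
    lo, hi = gwin
    if event.strand == "+":
        genome[lo + offset : lo + offset + len(motif)] = list(motif)
    else:
        rc = revcomp(motif)
        # transcript offset o maps to genomic [hi - o - len, hi - o)
        genome[hi - offset - len(motif) : hi - offset] = list(rc)


def simulate_splicing(
    config: SimulationConfig,
) -> tuple[list[ExonEvent], pd.DataFrame, dict[str, str], TruthTables]:
    """Simulate cassette-exon junction counts, the hosting genome, and
    planted-motif truth.

    Returns (events, junction table indexed by (chrom, start, end,
    strand) x splice samples, genome, truth).  The first
    ``n_regulated_events`` events receive the LDF delta-psi and carry
    the planted 6-mer in their flanks with the configured probability.
    """
    rng = np.random.default_rng([config.seed, 1])
    events, genome_len = _layout_events(config)
    if config.n_regulated_events > config.n_events:
        raise ValueError("n_regulated_events > n_events")
    genome_arr = rng.choice(list("ACGT"), size=genome_len)
    genome = list(genome_arr)

    psi_by_event: dict[str, tuple[float, float]] = {}
    explicit = {b.event_id: b for b in config.psi_blocks}
    for i, ev in enumerate(events):
        if ev.event_id in explicit:
            b = explicit[ev.event_id]
            base, d = b.psi_contra, b.dpsi
        else:
            base = rng.uniform(*config.psi_baseline_range)
            d = config.dpsi if i < config.n_regulated_events else 0.0
        psi_by_event[ev.event_id] = (
            float(np.clip(base, 0.0, 1.0)),
            float(np.clip(base + d, 0.02, 0.98)) if d else float(np.clip(base, 0.0, 1.0)),
        )

    samples = [f"ribo_{arm}_r{i}" for arm in ("con", "ldf")
               for i in range(1, config.splice_replicates + 1)]
    arm_of = {s: ("LDF" if "_ldf_" in s else "contralateral") for s in samples}

    motif_rows = []
    window, motif = config.flank_window, config.planted_motif
    rows = {}
    for i, ev in enumerate(events):
        regulated = i < config.n_regulated_events or (
            ev.event_id in explicit and explicit[ev.event_id].dpsi != 0
        )
        psi_con, psi_ldf = psi_by_event[ev.event_id]
        i1_counts, i2_counts, e_counts = [], [], []
        for s in samples:
            psi = psi_ldf if arm_of[s] == "LDF" else psi_con
            # an included transcript yields two inclusion-junction reads,
            # a skipped one a single exclusion read, so the inclusion
            # *read* fraction is 2*psi/(1+psi); the standard estimator
            # ((i1+i2)/2) / ((i1+i2)/2 + e) then recovers psi unbiasedly
            read_frac = 2.0 * psi / (1.0 + psi)
            T = int(_nb_draw(rng, np.array([config.coverage_mean]),
                             config.coverage_dispersion, False)[0])
            if config.psi_rho > 0 and 0 < read_frac < 1:
                a = read_frac * (1 - config.psi_rho) / config.psi_rho
                b = (1 - read_frac) * (1 - config.psi_rho) / config.psi_rho
                p = rng.beta(a, b)
            else:
                p = read_frac
            inc = rng.binomial(T, p)
            i1 = rng.binomial(inc, 0.5)
            i1_counts.append(i1)
            i2_counts.append(inc - i1)
            e_counts.append(T - inc)
        rows[ev.i1] = rows.get(ev.i1, np.zeros(len(samples), dtype=np.int64)) + np.array(i1_counts)
        rows[ev.i2] = rows.get(ev.i2, np.zeros(len(samples), dtype=np.int64)) + np.array(i2_counts)
        rows[ev.e] = rows.get(ev.e, np.zeros(len(samples), dtype=np.int64)) + np.array(e_counts)

        if regulated:
            for which in ("upstream", "downstream"):
                if rng.uniform() < config.motif_insert_prob:
                    offset = int(rng.integers(0, window - len(motif) + 1))
                    _plant_motif(genome, ev, which, offset, motif, window)
                    motif_rows.append({"event_id": ev.event_id, "flank": which,
                                       "offset": offset, "kmer": motif})

    junctions = pd.DataFrame(
        rows, index=samples
    ).T.rename_axis(index=["chrom", "start", "end", "strand"]).sort_index()

    truth_events = pd.DataFrame(
        {
            "psi_contra": [psi_by_event[ev.event_id][0] for ev in events],
            "psi_ldf": [psi_by_event[ev.event_id][1] for ev in events],
            "regulated": [
                i < config.n_regulated_events
                or (ev.event_id in explicit and explicit[ev.event_id].dpsi != 0)
                for i, ev in enumerate(events)
            ],
        },
        index=pd.Index([ev.event_id for ev in events], name="event_id"),
    )
    truth_events["dpsi"] = truth_events["psi_ldf"] - truth_events["psi_contra"]

    tt = TruthTables(
        events=truth_events,
        motif_insertions=pd.DataFrame(
            motif_rows, columns=["event_id", "flank", "offset", "kmer"]
        ),
        planted_motif=motif,
    )
    return events, junctions, {"chrSim": "".join(genome)}, tt


DEFAULT_MOTIF_SETS = {
    # illustrative AU-rich (Elavl1-like) and CU-rich (Ptbp1-like) 6-mer
    # sets plus GC-rich decoys; not a curated motif database
    "Elavl1": {"TTTATT", "TTTTTT", "ATTTAT", "TATTTA"},
    "Ptbp1": {"TCTTCT", "CTTCTT", "TTCTCT", "CTCTCT"},
    "DecoyGC": {"GCGCGC", "CGCGCG"},
    "DecoyMix": {"ACGTAC", "GTACGT"},
}


def emit_dataset(config: SimulationConfig, outdir: str | Path, force: bool = False) -> dict:
    """Write the complete synthetic dataset plus truth and a manifest.

    Outputs: counts.tsv + metadata.tsv, per-sample SJ.out.tab junction
    files, events.tsv, genome.fa, motifs.txt, gene_sets.gmt
    (truth-derived sets for ORA), truth_*.tsv and manifest.json
    recording the seed and config hash.  Byte-identical across reruns
    with the same config.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} exists; use force=True")
    outdir.mkdir(parents=True, exist_ok=True)

    gcm, truth_counts = simulate_counts(config)
    events, junctions, genome, truth_splice = simulate_splicing(config)

    tio.write_counts_tsv(gcm, outdir / "counts.tsv", outdir / "metadata.tsv")
    tio.write_junctions_sj_tab(junctions, outdir / "junctions")
    write_events_tsv(events, outdir / "events.tsv")
    tio.write_fasta(genome, outdir / "genome.fa")

    motif_sets = dict(DEFAULT_MOTIF_SETS)
    if not any(config.planted_motif in s for s in motif_sets.values()):
        motif_sets["PlantedRBP"] = {config.planted_motif}
    tio.write_motif_config(motif_sets, outdir / "motifs.txt")

    tg = truth_counts.genes
    gene_sets = {
        "planted_condition_up_ribo": sorted(tg.index[tg["lfc_condition_ribo"] > 0]),
        "planted_condition_down_ribo": sorted(tg.index[tg["lfc_condition_ribo"] < 0]),
        "planted_te_shift": sorted(tg.index[tg["te_shift"]]),
        "first_hundred": sorted(tg.index[:100]),
    }
    gene_sets = {k: v for k, v in gene_sets.items() if v}
    tio.write_gmt(gene_sets, outdir / "gene_sets.gmt")

    tio.write_results_table(tg, outdir / "truth_genes.tsv", what="truth_genes")
    tio.write_results_table(truth_splice.events, outdir / "truth_events.tsv", what="truth_events")
    tio.write_results_table(
        truth_splice.motif_insertions, outdir / "truth_motif.tsv",
        what="truth_motif", index=False,
    )

    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "planted_motif": config.planted_motif,
        "contamination": config.contamination,
        "n_genes": config.n_genes,
        "n_events": config.n_events,
        "files": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
            and p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
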