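"""Flank 6-mer RBP motif enrichment around regulated skipped exons.

Strand-aware 200 bp windows immediately upstream and downstream of the
cassette exon are extracted in transcript orientation, 6-mers are
counted over overlapping windows, and each 6-mer's occurrence rate in
the regulated (foreground) flanks is compared against a
coverage-matched background of non-regulated exons with a two-sided
Fisher exact test, BH-corrected across all emitted 6-mers.  Per-RBP
motif sets (e.g. AU-rich Elavl1 6-mers) are then ranked by their best
member 6-mer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .splicing import ExonEvent

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 200
DEFAULT_K = 6
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def all_kmers(k: int = DEFAULT_K) -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class FlankPair:
    """The two flanks of one cassette exon, in transcript orientation
    (pre-mRNA 5'->3'); minus-strand sequences are reverse-complemented."""

    event_id: str
    upstream_seq: str
    downstream_seq: str
    clipped: bool = False


def extract_flanks(
    events: list[ExonEvent], genome: dict[str, str], window: int = DEFAULT_WINDOW
) -> list[FlankPair]:
    """Extract the ``window`` bp upstream and downstream of each cassette
    exon, strand-aware.

    Plus strand: upstream = genome[c_start-window, c_start), downstream =
    genome[c_end, c_end+window).  Minus strand: the two genomic windows
    swap roles and are reverse-complemented.  Windows are clipped at
    contig bounds (``clipped=True``); events with a zero-length flank
    are dropped with a warning.
    """
    out = []
    for ev in events:
        if ev.chrom not in genome:
            raise KeyError(f"chromosome '{ev.chrom}' absent from genome")
        seq = genome[ev.chrom]
        left_lo = max(0, ev.c_start - window)
        left = seq[left_lo : ev.c_start]
        right = seq[ev.c_end : ev.c_end + window]
        clipped = len(left) < window or len(right) < window
        if ev.strand == "+":
            up, down = left, right
        else:
            up, down = revcomp(right), revcomp(left)
        if not up or not down:
            logger.warning("event %s: zero-length flank, dropped", ev.event_id)
            continue
        out.append(FlankPair(ev.event_id, up, down, clipped))
    return out


def count_kmers(seqs: list[str], k: int = DEFAULT_K) -> tuple[dict[str, int], int]:
    """Count k-mer occurrences over overlapping windows.

    Returns ({kmer: occurrences}, positions) where positions is the
    total number of valid scanned windows, sum over sequences of
    max(len-k+1, 0); windows containing N are skipped and excluded from
    positions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    positions = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            positions += 1
            counts[w] = counts.get(w, 0) + 1
    return counts, positions


def match_background(
    regulated: list[ExonEvent],
    candidates: list[ExonEvent],
    level: dict[str, float],
    bins: int = 10,
    ratio: int = 3,
    seed: int = 0,
) -> list[ExonEvent]:
    """Sample a detection-level-matched background from non-regulated
    candidate exons.

    ``level`` maps event_id to a per-event coverage metric (mean
    junction-cluster coverage across samples).  Regulated events are
    binned into ``bins`` quantile bins of level; from each bin, up to
    ``ratio`` times that bin's foreground count is sampled without
    replacement from candidates falling in the same bin.  Bins short of
    candidates take all available and log the deficit.  Deterministic in
    ``seed``.
    """
    reg_ids = {ev.event_id for ev in regulated}
    candidates = [ev for ev in candidates if ev.event_id not in reg_ids]
    if not candidates:
        raise ValueError("no background candidates")
    fg_levels = np.array([level[ev.event_id] for ev in regulated])
    edges = np.quantile(fg_levels, np.linspace(0, 1, bins + 1))

    def bin_of(x: float) -> int | None:
        # candidates outside the foreground's level range are not a
        # detection-level match for any bin
        if x < edges[0] or x > edges[-1]:
            return None
        return min(int(np.searchsorted(edges, x, side="right") - 1), bins - 1)

    rng = np.random.default_rng(seed)
    chosen: list[ExonEvent] = []
    cand_by_bin: dict[int, list[ExonEvent]] = {}
    for ev in candidates:
        b = bin_of(level[ev.event_id])
        if b is not None:
            cand_by_bin.setdefault(b, []).append(ev)
    fg_per_bin: dict[int, int] = {}
    for x in fg_levels:
        b = bin_of(x)
        fg_per_bin[b] = fg_per_bin.get(b, 0) + 1
    for b in sorted(fg_per_bin):
        want = ratio * fg_per_bin[b]
        pool = sorted(cand_by_bin.get(b, []), key=lambda ev: ev.event_id)
        if len(pool) < want:
            logger.warning("background bin %d: %d candidates for %d wanted", b, len(pool), want)
            chosen.extend(pool)
        else:
            take = rng.choice(len(pool), size=want, replace=False)
            chosen.extend(pool[i] for i in sorted(take))
    return chosen


def kmer_enrichment(
    fg: list[FlankPair],
    bg: list[FlankPair],
    region: str = "both",
    k: int = DEFAULT_K,
    alphabet_complete: bool = True,
    mode: str = "occurrence",
) -> pd.DataFrame:
    """Per-k-mer Fisher enrichment of foreground vs background flanks.

    ``region`` selects upstream, downstream or both flank sequences.
    In ``occurrence`` mode the 2x2 table is (occurrences, other scanned
    positions) in fg vs bg; in ``presence`` mode it is (flank pairs with
    >= 1 occurrence, without) — less powerful but robust to repeats.
    Odds ratios use a 0.5 Haldane correction when any cell is 0; BH is
    applied across all emitted k-mers (all 4^k when
    ``alphabet_complete``).
    """
    if region not in ("upstream", "downstream", "both"):
        raise ValueError(f"bad region: {region}")
    if mode not in ("occurrence", "presence"):
        raise ValueError(f"bad mode: {mode}")

    def seqs_of(pairs: list[FlankPair]) -> list[str]:
        if region == "upstream":
            return [p.upstream_seq for p in pairs]
        if region == "downstream":
            return [p.downstream_seq for p in pairs]
        return [p.upstream_seq for p in pairs] + [p.downstream_seq for p in pairs]

    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")

    if mode == "occurrence":
        fg_counts, fg_pos = count_kmers(seqs_of(fg), k)
        bg_counts, bg_pos = count_kmers(seqs_of(bg), k)
    else:
        def presence(pairs: list[FlankPair]):
            counts: dict[str, int] = {}
            for p in pairs:
                text = {
                    "upstream": p.upstream_seq,
                    "downstream": p.downstream_seq,
                    "both": p.upstream_seq + "#" + p.downstream_seq,
                }[region]
                seen, _ = count_kmers([text.replace("#", "N")], k)
                for km in seen:
                    counts[km] = counts.get(km, 0) + 1
            return counts, len(pairs)

        fg_counts, fg_pos = presence(fg)
        bg_counts, bg_pos = presence(bg)

    if fg_pos == 0:
        raise ValueError("no scannable foreground positions")

    kmers = all_kmers(k) if alphabet_complete else sorted(set(fg_counts) | set(bg_counts))
    rows = []
    for km in kmers:
        a = fg_counts.get(km, 0)
        b = fg_pos - a
        c = bg_counts.get(km, 0)
        d = bg_pos - c
        p = 1.0 if a + c == 0 else fisher_two_sided(a, b, c, d)
        if min(a, b, c, d) == 0:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orat = (a * d) / (b * c)
        rows.append((km, a, fg_pos, c, bg_pos, orat, p))
    out = pd.DataFrame(
        rows,
        columns=["kmer", "fg_count", "fg_positions", "bg_count", "bg_positions",
                 "odds_ratio", "fisher_p"],
    ).set_index("kmer")
    out["log2_or"] = np.log2(out["odds_ratio"])
    out["neglog10_p"] = -np.log10(np.maximum(out["fisher_p"], 1e-300))
    out["bh_q"] = bh_adjust(out["fisher_p"])
    out["region"] = region
    return out


def rbp_aggregate(
    table: pd.DataFrame, motif_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Aggregate the per-k-mer table to per-RBP scores and ranks.

    Primary score: minimum BH q over the RBP's k-mers; secondary: mean
    -log10 Fisher p over the set.  Ranked by (primary asc, secondary
    desc), deterministic ties by name.
    """
    if not motif_sets:
        raise ValueError("empty motif set list")
    known = set(table.index)
    rows = []
    for name, kmers in motif_sets.items():
        missing = set(kmers) - known
        if missing:
            raise ValueError(f"RBP '{name}': k-mer(s) not in enrichment table: {sorted(missing)}")
        sub = table.loc[sorted(kmers)]
        rows.append(
            {
                "rbp": name,
                "n_kmers": len(kmers),
                "best_kmer": sub["bh_q"].idxmin(),
                "best_q": float(sub["bh_q"].min()),
                "best_p": float(sub["fisher_p"].min()),
                "mean_neglog10_p": float(sub["neglog10_p"].mean()),
            }
        )
    out = pd.DataFrame(rows).set_index("rbp")
    out = out.sort_values(
        by=["best_q", "mean_neglog10_p", "rbp"], ascending=[True, False, True],
        kind="mergesort",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
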