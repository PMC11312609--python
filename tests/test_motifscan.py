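"""Flank extraction, k-mer counting, matched background, Fisher enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trapseq.motifscan import (
    FlankPair,
    all_kmers,
    count_kmers,
    extract_flanks,
    fisher_two_sided,
    kmer_enrichment,
    match_background,
    rbp_aggregate,
    revcomp,
)
from trapseq.splicing import ExonEvent


def toy_event(strand, c_start=4, c_end=6, event_id="ev"):
    # exons sized 1 around a tiny cassette on an 8 bp chromosome
    return ExonEvent(event_id, "c", strand, 0, 1, c_start, c_end, 7, 8)


class TestExtractFlanks:
    def test_plus_strand_windows(self):
        # chrom AACCGGTT, cassette [4,6): upstream = genome[2,4) = CC
        fp = extract_flanks([toy_event("+")], {"c": "AACCGGTT"}, window=2)[0]
        assert fp.upstream_seq == "CC"
        assert fp.downstream_seq == "TT"

    def test_minus_strand_windows(self):
        # same exon on -: upstream = revcomp(genome[6,8) = TT) = AA
        fp = extract_flanks([toy_event("-")], {"c": "AACCGGTT"}, window=2)[0]
        assert fp.upstream_seq == "AA"
        assert fp.downstream_seq == "GG"

    def test_clipping_at_contig_edge(self):
        ev = ExonEvent("e", "c", "+", 0, 1, 1, 3, 6, 8)
        fp = extract_flanks([ev], {"c": "AACCGGTT"}, window=200)[0]
        assert fp.clipped
        assert fp.upstream_seq == "A"  # truncated to length 1 at the contig start
        assert fp.downstream_seq == "CGGTT"

    def test_missing_chrom_rejected(self):
        with pytest.raises(KeyError, match="chr9"):
            extract_flanks([ExonEvent("e", "chr9", "+", 0, 1, 4, 6, 7, 8)], {"c": "A" * 8})

    def test_strand_involution(self, rng):
        """A mirrored event on the reverse-complemented genome yields the
        same transcript-orientation flanks."""
        L = 600
        genome = "".join(rng.choice(list("ACGT"), size=L))
        mirror = revcomp(genome)
        for _ in range(20):
            c_start = int(rng.integers(150, 300))
            c_end = c_start + int(rng.integers(20, 80))
            ev = ExonEvent("e", "c", "+", 10, 20, c_start, c_end, 500, 510)
            ev_m = ExonEvent("e", "c", "-", L - 510, L - 500, L - c_end, L - c_start,
                             L - 20, L - 10)
            fp = extract_flanks([ev], {"c": genome}, window=50)[0]
            fp_m = extract_flanks([ev_m], {"c": mirror}, window=50)[0]
            assert fp.upstream_seq == fp_m.upstream_seq
            assert fp.downstream_seq == fp_m.downstream_seq


class TestCountKmers:
    def test_overlapping_windows(self):
        counts, pos = count_kmers(["AAAAAAA"], k=6)
        assert counts == {"AAAAAA": 2}
        assert pos == 2

    def test_distinct_windows(self):
        counts, pos = count_kmers(["ACGTACGTA"], k=6)
        assert pos == 4
        assert len(counts) == 4
        assert all(v == 1 for v in counts.values())

    def test_n_windows_skipped(self):
        counts, pos = count_kmers(["AANAAA"], k=6)
        assert counts == {} and pos == 0

    @given(st.lists(st.text(alphabet="ACGT", min_size=0, max_size=30), max_size=5))
    @settings(deadline=None, max_examples=50)
    def test_occurrences_sum_to_positions(self, seqs):
        counts, pos = count_kmers(seqs, k=6)
        assert sum(counts.values()) == pos == sum(max(len(s) - 5, 0) for s in seqs)


class TestMatchBackground:
    def levels(self, events, vals):
        return {ev.event_id: v for ev, v in zip(events, vals)}

    def make_events(self, n):
        return [toy_event("+", event_id=f"e{i:03d}") for i in range(n)]

    def test_exact_levels_ratio_one(self):
        evs = self.make_events(20)
        fg, cand = evs[:10], evs[10:]
        level = {**self.levels(fg, range(10)), **self.levels(cand, range(10))}
        bg = match_background(fg, cand, level, bins=5, ratio=1, seed=1)
        assert len(bg) == 10

    def test_seed_determinism(self):
        evs = self.make_events(40)
        fg, cand = evs[:10], evs[10:]
        level = self.levels(evs, list(np.linspace(0, 100, 40)))
        b1 = match_background(fg, cand, level, seed=7)
        b2 = match_background(fg, cand, level, seed=7)
        assert [e.event_id for e in b1] == [e.event_id for e in b2]

    def test_top_decile_foreground_draws_top_decile_background(self):
        evs = self.make_events(120)
        fg, cand = evs[:10], evs[10:]
        level = {**self.levels(fg, np.linspace(95, 100, 10)),
                 **self.levels(cand, np.linspace(1, 110, 110))}
        bg = match_background(fg, cand, level, bins=10, ratio=1, seed=3)
        assert all(level[e.event_id] >= 94 for e in bg)

    def test_no_candidates_rejected(self):
        evs = self.make_events(2)
        with pytest.raises(ValueError, match="candidates"):
            match_background(evs, evs, self.levels(evs, [1, 2]))


def flanks(seqs):
    return [FlankPair(f"f{i}", s, s) for i, s in enumerate(seqs)]


class TestKmerEnrichment:
    def test_absent_kmer_neutral(self):
        t = kmer_enrichment(flanks(["ACACACAC"]), flanks(["ACACACAC"]), region="both")
        row = t.loc["GGGGGG"]
        assert row["fisher_p"] == 1.0
        assert row["odds_ratio"] == pytest.approx(1.0, rel=0.1)

    def test_hand_fisher_table(self):
        assert fisher_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70)

    def test_emits_full_alphabet(self):
        t = kmer_enrichment(flanks(["ACGTACGTACGT"]), flanks(["ACGTACGT"]), region="upstream")
        assert len(t) == 4096
        assert sorted(t.index) == sorted(all_kmers(6))

    def test_enriched_kmer_ranks_first(self, rng):
        fg_seqs = ["".join(rng.choice(list("ACGT"), size=60)) + "TTTATT" for _ in range(30)]
        bg_seqs = ["".join(rng.choice(list("ACGT"), size=66)) for _ in range(90)]
        t = kmer_enrichment(flanks(fg_seqs), flanks(bg_seqs), region="both")
        assert t["fisher_p"].idxmin() == "TTTATT"

    def test_presence_mode_counts_pairs(self):
        fg = flanks(["TTTATTAA", "ACACACAC"])
        bg = flanks(["GGGGGGGG"])
        t = kmer_enrichment(fg, bg, region="both", mode="presence")
        assert t.loc["TTTATT", "fg_count"] == 1
        assert t.loc["TTTATT", "fg_positions"] == 2

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            kmer_enrichment([], flanks(["ACGTACGT"]))


class TestRbpAggregate:
    def table(self):
        return kmer_enrichment(
            flanks(["TTTATTTTTATT", "TTTATTACGTAC"]), flanks(["GCGCGCGCGCGC"] * 3),
            region="both",
        )

    def test_planted_rbp_ranks_first(self):
        t = self.table()
        out = rbp_aggregate(t, {"Hit": {"TTTATT"}, "Miss": {"GGGGGG"}})
        assert out.index[0] == "Hit"
        assert out.loc["Hit", "rank"] == 1

    def test_identical_sets_tie_break_alphabetical(self):
        t = self.table()
        out = rbp_aggregate(t, {"Zeta": {"TTTATT"}, "Alpha": {"TTTATT"}})
        assert list(out.index) == ["Alpha", "Zeta"]
        assert out.loc["Alpha", "best_q"] == out.loc["Zeta", "best_q"]

    def test_all_absent_kmers_best_q_one(self):
        t = self.table()
        out = rbp_aggregate(t, {"Ghost": {"AATTCC"}})
        assert out.loc["Ghost", "best_q"] == pytest.approx(1.0)

    def test_empty_motif_sets_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rbp_aggregate(self.table(), {})
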