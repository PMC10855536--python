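from __future__ import annotations

import numpy as np
import pytest

from ervamp._dna import reverse_complement
from ervamp.align import (AlignmentHit, AlignmentScoring, GenomeAligner,
                          accept_hit, align_read_glocal, resolve_ties)

BASES = np.array(list("ACGT"))


def _seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def _mutate(seq, pos):
    return seq[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]] \
        + seq[pos + 1:]


class TestExactDP:
    def test_exact_substring_scores_read_length(self, rng):
        ref = _seq(rng, 500)
        read = ref[100:240]
        hits = align_read_glocal(read, ref)
        assert len(hits) == 1
        h = hits[0]
        assert (h.score, h.start, h.mismatches, h.gap_bases) == (140, 100, 0, 0)
        assert h.cigar == "140M"

    def test_one_substitution_costs_eleven(self, rng):
        ref = _seq(rng, 500)
        read = _mutate(ref[100:240], 70)
        hits = align_read_glocal(read, ref)
        assert hits[0].score == 140 - 11
        assert hits[0].mismatches == 1

    def test_one_base_deletion_in_read(self, rng):
        ref = _seq(rng, 400)
        read = ref[50:120] + ref[121:190]  # read skips one reference base
        hits = align_read_glocal(read, ref)
        assert hits[0].score == len(read) - 10
        assert hits[0].gap_bases == 1
        assert hits[0].aligned_ref_span == len(read) + 1

    def test_duplicated_position_gives_two_equal_hits(self, rng):
        core = _seq(rng, 80)
        ref = _seq(rng, 100) + core + _seq(rng, 100) + core + _seq(rng, 100)
        hits = align_read_glocal(core, ref)
        assert len(hits) == 2
        assert {h.start for h in hits} == {100, 280}
        assert len({h.score for h in hits}) == 1

    def test_reverse_complement_flips_strand_same_score(self, rng):
        ref = _seq(rng, 300)
        read = ref[40:160]
        fwd = align_read_glocal(read, ref)
        rev = align_read_glocal(reverse_complement(read), ref)
        assert fwd[0].score == rev[0].score
        assert fwd[0].strand == "+" and rev[0].strand == "-"
        assert fwd[0].start == rev[0].start

    def test_score_bounded_by_read_length(self, rng):
        for _ in range(20):
            read = _seq(rng, int(rng.integers(10, 40)))
            ref = _seq(rng, 200)
            hits = align_read_glocal(read, ref)
            assert hits[0].score <= len(read)
            if hits[0].score == len(read):
                assert read in ref or reverse_complement(read) in ref

    def test_hit_score_identity(self, rng):
        """Score decomposes into matches, mismatches and gap bases at the
        stated costs, with the whole read consumed (no clipping)."""
        import re
        ref = _seq(rng, 300)
        read = _mutate(ref[50:150], 30)[:40] + ref[91:150]
        for h in align_read_glocal(read, ref):
            ops = {op: sum(int(n) for n, o in
                           re.findall(r"(\d+)([MID])", h.cigar) if o == op)
                   for op in "MID"}
            assert ops["M"] + ops["I"] == len(read)
            assert ops["M"] + ops["D"] == h.aligned_ref_span
            assert ops["I"] + ops["D"] == h.gap_bases
            assert h.score == (ops["M"] - h.mismatches) - 10 * h.mismatches \
                - 10 * h.gap_bases


class TestAcceptance:
    def test_default_threshold(self):
        good = AlignmentHit("c", 0, "+", 140, 0, 0, 140)
        assert accept_hit(good, 140)
        borderline = AlignmentHit("c", 0, "+", 107, 3, 0, 140)
        assert accept_hit(borderline, 140)
        bad = AlignmentHit("c", 0, "+", 96, 4, 0, 140)
        assert not accept_hit(bad, 140)

    def test_threshold_override(self):
        hit = AlignmentHit("c", 0, "+", -1000, 100, 10, 140)
        assert accept_hit(hit, 140, AlignmentScoring(min_accept_score=-10**9))


class TestResolveTies:
    def _hits(self):
        return [AlignmentHit("c1", 100, "+", 50, 0, 0, 50),
                AlignmentHit("c2", 900, "+", 50, 0, 0, 50)]

    def test_single_hit(self):
        h = self._hits()[:1]
        assert resolve_ties(h, 0, "r") is h[0]

    def test_deterministic_per_read(self):
        hits = self._hits()
        choices = {resolve_ties(hits, 42, "read_7").chrom for _ in range(5)}
        assert len(choices) == 1

    def test_order_independent(self):
        hits = self._hits()
        a = resolve_ties(hits, 3, "rX")
        b = resolve_ties(hits[::-1], 3, "rX")
        assert (a.chrom, a.start) == (b.chrom, b.start)

    def test_uniform_over_reads(self):
        hits = self._hits()
        picks = sum(resolve_ties(hits, 1, f"read{i}").chrom == "c1"
                    for i in range(10_000))
        assert 4800 <= picks <= 5200

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_ties([], 0, "r")


class TestGenomeAligner:
    def test_agrees_with_exact_dp(self, rng):
        """The seeded aligner reproduces the exact DP decision on a small
        genome, for clean, substituted and single-indel reads."""
        genome = {"cA": _seq(rng, 3000), "cB": _seq(rng, 2000)}
        aligner = GenomeAligner(genome, seed=5)
        full_ref = {c: genome[c] for c in genome}
        for trial in range(60):
            chrom = "cA" if rng.random() < 0.6 else "cB"
            start = int(rng.integers(0, len(genome[chrom]) - 160))
            read = genome[chrom][start:start + 150]
            kind = trial % 3
            if kind == 1:
                read = _mutate(read, int(rng.integers(0, len(read))))
            elif kind == 2:
                cut = int(rng.integers(10, len(read) - 10))
                read = read[:cut] + read[cut + 1:]  # deletion in read
            if rng.random() < 0.5:
                read = reverse_complement(read)
            m = aligner.map_read(f"t{trial}", read)
            exact_best = max(align_read_glocal(read, genome[c])[0].score
                             for c in genome)
            assert m.hit is not None
            assert m.hit.score == exact_best

    def test_unmappable_read_rejected(self, rng):
        genome = {"c": _seq(rng, 3000)}
        aligner = GenomeAligner(genome, seed=0)
        read = _seq(rng, 150)  # random read, not from the genome
        assert aligner.map_read("r", read).hit is None

    def test_mismatch_qc_below_error_budget(self, small_cohort,
                                            small_sim_config):
        """On synthetic reads the accumulated mismatch percentage stays
        below the generator substitution rate plus 3 sigma."""
        genome, truth, reads_by_sample = small_cohort
        aligner = GenomeAligner(genome, seed=2)
        n_bases = 0
        for reads in reads_by_sample.values():
            for read in reads[:200]:
                aligner.map_read(read.read_id, read.sequence)
                n_bases += len(read)
        rate = small_sim_config.sub_rate
        bound = 100 * (rate + 3 * np.sqrt(rate / n_bases))
        assert 0 < aligner.mismatch_percent < bound

    def test_multimapper_split_between_identical_copies(self, rng):
        core = _seq(rng, 200)
        genome = {"c": _seq(rng, 500) + core + _seq(rng, 800) + core
                  + _seq(rng, 500)}
        aligner = GenomeAligner(genome, seed=9)
        read = core[20:170]
        starts = [aligner.map_read(f"r{i}", read).hit.start
                  for i in range(400)]
        first = sum(s == 520 for s in starts)
        assert {s for s in starts} == {520, 1520}
        assert 120 <= first <= 280  # roughly balanced
        assert aligner.map_read("rX", read).n_best == 2
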