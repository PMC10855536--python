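"""End-to-end ("glocal") read alignment with amplicon-resequencing scoring.

Reads must align over their entire length — no soft clipping — at any
position of the reference, on either strand. Scoring is match +1,
mismatch -10, gap -10 per gap base, which makes every error an order of
magnitude more expensive than a match is rewarding: alignments are either
near-perfect or rejected. Multi-mappers (reads equally consistent with
several near-identical ERV copies) are resolved uniformly at random among
the best-scoring hits, with the draw keyed to (seed, read id) so that runs
are reproducible and independent of input order.

Two entry points:

* :func:`align_read_glocal` — exact dynamic programming over a full
  reference string; used for small references and as the ground truth the
  fast path is tested against.
* :class:`GenomeAligner` — k-mer-seeded aligner for genome-scale input.
  It is exact for alignments with at most one gap event; candidates that
  still score below the acceptance threshold fall back to a banded DP, so
  multi-gap reads are either recovered exactly or rejected, never
  misassigned.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from ._dna import encode, reverse_complement


@dataclass(frozen=True)
class AlignmentScoring:
    """Alignment scores; ``min_accept_score`` of ``None`` means the per-read
    default ``read_len - 33`` (at most three penalized events)."""

    match: int = 1
    mismatch: int = -10
    gap_per_base: int = -10
    min_accept_score: int | None = None

    #: margin subtracted from read length for the default acceptance threshold
    DEFAULT_ACCEPT_MARGIN = 33

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch) or self.gap_per_base >= 0:
            raise ValueError("require match > 0 > mismatch and gap_per_base < 0")

    def accept_threshold(self, read_len: int) -> float:
        if self.min_accept_score is not None:
            return self.min_accept_score
        return read_len * self.match - self.DEFAULT_ACCEPT_MARGIN


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    start: int  # 0-based on the plus strand of chrom
    strand: str
    score: int
    mismatches: int
    gap_bases: int
    aligned_ref_span: int
    cigar: str = ""

    @property
    def end(self) -> int:
        return self.start + self.aligned_ref_span


@dataclass
class MappedRead:
    read_id: str
    hit: AlignmentHit | None
    n_best: int
    best_score: int | None
    read_len: int

    @property
    def mapped(self) -> bool:
        return self.hit is not None


def accept_hit(hit: AlignmentHit, read_len: int,
               scoring: AlignmentScoring | None = None) -> bool:
    """Mapped/unmapped decision: score must reach the acceptance threshold."""
    scoring = scoring or AlignmentScoring()
    return hit.score >= scoring.accept_threshold(read_len)


def resolve_ties(hits: Sequence[AlignmentHit], rng_seed: int,
                 read_id: str = "") -> AlignmentHit:
    """Uniform choice among equal-best hits, reproducible per (seed, read id).

    The draw is keyed by hashing ``(rng_seed, read_id)``, so the choice for
    a given read does not depend on the order reads are processed in.
    """
    if not hits:
        raise ValueError("resolve_ties requires at least one hit")
    if len(hits) == 1:
        return hits[0]
    ordered = sorted(hits, key=lambda h: (h.chrom, h.start, h.strand, h.cigar))
    digest = hashlib.blake2b(f"{rng_seed}\x00{read_id}".encode(),
                             digest_size=8).digest()
    draw = int.from_bytes(digest, "big")
    return ordered[draw % len(ordered)]


# ------------------------------------------------------------ exact DP path

def _dp_matrix(read_bits: np.ndarray, ref_bits: np.ndarray,
               scoring: AlignmentScoring) -> np.ndarray:
    """Full (L+1)x(G+1) glocal DP matrix, int32.

    Row 0 is all zeros (free start anywhere in the reference); the best
    score is the maximum of the last row (free end). Horizontal moves
    (reference gap) within a row are resolved with a decayed running
    maximum, which is exact for linear gap costs.
    """
    L, G = len(read_bits), len(ref_bits)
    g = -scoring.gap_per_base  # positive cost
    H = np.zeros((L + 1, G + 1), dtype=np.int32)
    idx = np.arange(G + 1, dtype=np.int32) * g
    sub_match = np.int32(scoring.match)
    sub_mismatch = np.int32(scoring.mismatch)
    for i in range(1, L + 1):
        prev = H[i - 1]
        sub = np.where(ref_bits == read_bits[i - 1], sub_match, sub_mismatch)
        cand = np.empty(G + 1, dtype=np.int32)
        cand[0] = prev[0] - g
        np.maximum(prev[:-1] + sub, prev[1:] - g, out=cand[1:])
        # cand[j] or a gap chain from the left: running max of cand + g*j
        H[i] = np.maximum.accumulate(cand + idx) - idx
    return H


def _traceback(H: np.ndarray, read_bits: np.ndarray, ref_bits: np.ndarray,
               end_j: int, scoring: AlignmentScoring,
               ) -> tuple[int, int, int, str]:
    """Recover (start, mismatches, gap_bases, cigar) for an optimal path
    ending at reference column ``end_j``. Diagonal moves are preferred,
    then read-gaps, then reference-gaps, making the traceback deterministic."""
    i, j = H.shape[0] - 1, end_j
    mismatches = gap_bases = 0
    ops: list[str] = []
    g = scoring.gap_per_base
    while i > 0:
        h = H[i, j]
        if j > 0 and h == H[i - 1, j - 1] + (
                scoring.match if ref_bits[j - 1] == read_bits[i - 1]
                else scoring.mismatch):
            if ref_bits[j - 1] != read_bits[i - 1]:
                mismatches += 1
            ops.append("M")
            i, j = i - 1, j - 1
        elif h == H[i - 1, j] + g:
            ops.append("I")  # read base opposite a gap
            gap_bases += 1
            i -= 1
        elif j > 0 and h == H[i, j - 1] + g:
            ops.append("D")  # reference base opposite a gap
            gap_bases += 1
            j -= 1
        else:  # pragma: no cover - would indicate a DP inconsistency
            raise AssertionError("traceback dead end")
    ops.reverse()
    cigar_parts: list[str] = []
    for op in ops:
        if cigar_parts and cigar_parts[-1][-1] == op:
            n = int(cigar_parts[-1][:-1]) + 1
            cigar_parts[-1] = f"{n}{op}"
        else:
            cigar_parts.append(f"1{op}")
    return j, mismatches, gap_bases, "".join(cigar_parts)


def align_read_glocal(read: str, reference: str,
                      scoring: AlignmentScoring | None = None,
                      chrom: str = "", both_strands: bool = True,
                      ) -> list[AlignmentHit]:
    """Exact glocal alignment of ``read`` against ``reference``.

    Returns every hit achieving the maximum score over the requested
    strands, sorted by (start, strand). Intended for small references
    (memory is O(len(read) x len(reference))).
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    scoring = scoring or AlignmentScoring()
    ref_bits = encode(reference)
    hits: list[AlignmentHit] = []
    best = None
    for strand in ("+", "-") if both_strands else ("+",):
        seq = read if strand == "+" else reverse_complement(read)
        read_bits = encode(seq)
        H = _dp_matrix(read_bits, ref_bits, scoring)
        last = H[-1]
        score = int(last.max())
        if best is None or score > best:
            best = score
            hits = []
        if score == best:
            for end_j in np.flatnonzero(last == score).tolist():
                start, mm, gaps, cigar = _traceback(H, read_bits, ref_bits,
                                                    end_j, scoring)
                if end_j - start == 0:
                    continue  # degenerate all-gap placement
                hits.append(AlignmentHit(chrom, start, strand, score, mm, gaps,
                                         end_j - start, cigar))
    # distinct end columns can describe the same interval; keep unique hits
    uniq = {(h.start, h.strand, h.aligned_ref_span, h.cigar): h for h in hits}
    return sorted(uniq.values(), key=lambda h: (h.start, h.strand))


# ------------------------------------------------------------- fast aligner

def _kmer_code(bits: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit k-mer codes for every position; second array flags validity
    (windows containing non-ACGT are invalid)."""
    two_bit = np.full(len(bits), 255, dtype=np.uint8)
    for code, val in ((1, 0), (2, 1), (4, 2), (8, 3)):
        two_bit[bits == code] = val
    n = len(bits) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        col = two_bit[i:i + n]
        valid &= col != 255
        codes = codes * 4 + np.where(col == 255, 0, col)
    return codes, valid


class GenomeAligner:
    """Seed-and-verify glocal aligner over a whole (small) genome.

    Seeds are exact k-mers sampled evenly along the read on both strands;
    each seed hit proposes a diagonal. Candidate diagonals are scored
    ungapped with vectorised mismatch counting, then refined by an exact
    single-gap split search, with a banded full DP as a fallback for
    candidates still below the acceptance threshold. All best-scoring
    hits are collected and one is drawn by :func:`resolve_ties`.
    """

    def __init__(self, genome: Mapping[str, str],
                 scoring: AlignmentScoring | None = None, *,
                 seed: int = 0, k: int = 13, n_seeds: int = 8, band: int = 3,
                 max_fallback_clusters: int = 6):
        self.scoring = scoring or AlignmentScoring()
        self.seed = seed
        self.k = k
        self.n_seeds = n_seeds
        self.band = band
        self.max_fallback_clusters = max_fallback_clusters
        self.chroms = list(genome)
        self._bits = {c: encode(genome[c].upper()) for c in self.chroms}
        self._index: dict[int, list[tuple[str, int]]] = {}
        for chrom in self.chroms:
            codes, valid = _kmer_code(self._bits[chrom], k)
            for pos in np.flatnonzero(valid).tolist():
                self._index.setdefault(int(codes[pos]), []).append((chrom, pos))
        # QC accumulators
        self.stats = {"total": 0, "mapped": 0, "unmapped": 0,
                      "mismatch_bases": 0, "gap_bases": 0, "aligned_bases": 0,
                      "multi_best": 0}

    # -- candidate generation ------------------------------------------------

    def _seed_offsets(self, L: int) -> list[int]:
        span = L - self.k
        if span < 0:
            return []
        n = min(self.n_seeds, span + 1)
        return sorted({round(span * i / max(n - 1, 1)) for i in range(n)})

    def _candidates(self, read_bits: np.ndarray) -> set[tuple[str, int]]:
        cands: set[tuple[str, int]] = set()
        L = len(read_bits)
        codes, valid = _kmer_code(read_bits, self.k)
        for off in self._seed_offsets(L):
            if off < len(valid) and valid[off]:
                for chrom, pos in self._index.get(int(codes[off]), ()):
                    cands.add((chrom, pos - off))
        return cands

    # -- scoring -------------------------------------------------------------

    def _ungapped(self, chrom: str, diag: int, read_bits: np.ndarray) -> int | None:
        bits = self._bits[chrom]
        L = len(read_bits)
        if diag < 0 or diag + L > len(bits):
            return None
        mm = int(np.count_nonzero(bits[diag:diag + L] != read_bits))
        return self._score(L, mm, 0, 0)

    def _score(self, L: int, mm: int, read_gap: int, ref_gap: int) -> int:
        s = self.scoring
        return ((L - mm - read_gap) * s.match + mm * s.mismatch
                + (read_gap + ref_gap) * s.gap_per_base)

    def _split_search(self, chrom: str, diag: int, read_bits: np.ndarray,
                      want_details: int | None = None,
                      ) -> list[tuple[int, int, str, int, int]]:
        """Best single-gap alignments (gap of 1..band bases) with the read
        prefix anchored on ``diag``.

        Returns (score, g, gap_type, split_index, mismatches) per gap size
        and type. With ``want_details`` set, only combinations reaching
        that score compute the split index (the cheap path returns -1).
        """
        bits = self._bits[chrom]
        L = len(read_bits)
        out: list[tuple[int, int, str, int, int]] = []
        if diag < 0 or diag + L > len(bits):
            return out
        mm0 = (bits[diag:diag + L] != read_bits)
        c0 = np.concatenate(([0], np.cumsum(mm0)))
        for g in range(1, self.band + 1):
            # deletion: g reference bases skipped after an interior split
            # (a boundary "deletion" is an ungapped placement on a shifted
            # diagonal, not a gap)
            if diag + L + g <= len(bits) and L >= 2:
                mmg = (bits[diag + g:diag + g + L] != read_bits)
                cg = np.concatenate(([0], np.cumsum(mmg)))
                tot = c0[1:L] + (cg[L] - cg[1:L])
                mm = int(tot.min())
                score = self._score(L, mm, 0, g)
                i = -1
                if want_details is not None and score >= want_details:
                    i = 1 + int(np.argmin(tot))
                out.append((score, g, "D", i, mm))
            # insertion: g read bases opposite a gap after the split
            if g < L and diag + L - g <= len(bits):
                mmg = (bits[diag:diag + L - g] != read_bits[g:])
                cg = np.concatenate(([0], np.cumsum(mmg)))
                tot = c0[:L - g + 1] + (cg[L - g] - cg[:L - g + 1])
                mm = int(tot.min())
                score = self._score(L, mm, g, 0)
                i = -1
                if want_details is not None and score >= want_details:
                    i = int(np.argmin(tot))
                out.append((score, g, "I", i, mm))
        return out

    def _banded_fallback(self, chrom: str, diags: list[int],
                         read_bits: np.ndarray, seq: str,
                         ) -> list[AlignmentHit]:
        """Exact DP on a window around a cluster of diagonals (rare path)."""
        bits = self._bits[chrom]
        L = len(read_bits)
        lo = max(0, min(diags) - self.band)
        hi = min(len(bits), max(diags) + L + self.band)
        if hi - lo <= 0:
            return []
        window = bits[lo:hi]
        H = _dp_matrix(read_bits, window, self.scoring)
        last = H[-1]
        score = int(last.max())
        hits = []
        for end_j in np.flatnonzero(last == score).tolist():
            start, mm, gaps, cigar = _traceback(H, read_bits, window, end_j,
                                                self.scoring)
            if end_j - start == 0:
                continue
            hits.append(AlignmentHit(chrom, lo + start, "?", score, mm, gaps,
                                     end_j - start, cigar))
        return hits

    # -- public mapping API --------------------------------------------------

    def map_read(self, read_id: str, sequence: str) -> MappedRead:
        L = len(sequence)
        self.stats["total"] += 1
        per_strand: dict[str, np.ndarray] = {
            "+": encode(sequence.upper()),
            "-": encode(reverse_complement(sequence.upper())),
        }
        cand: dict[str, set[tuple[str, int]]] = {
            s: self._candidates(bits) for s, bits in per_strand.items()}

        # lightweight records: (score, strand, chrom, diag, kind, extra)
        records: list[tuple[int, str, str, int, str, tuple]] = []
        best: int | None = None

        for strand, cands in cand.items():
            rb = per_strand[strand]
            for chrom, diag in cands:
                score = self._ungapped(chrom, diag, rb)
                if score is None:
                    continue
                if best is None or score > best:
                    best = score
                records.append((score, strand, chrom, diag, "U", ()))

        perfect = L * self.scoring.match
        if best is None or best < perfect:
            for strand, cands in cand.items():
                rb = per_strand[strand]
                for chrom, diag in cands:
                    for score, g, gap_type, _, mm in self._split_search(
                            chrom, diag, rb):
                        if best is None or score > best:
                            best = score
                        records.append((score, strand, chrom, diag,
                                        gap_type, (g, mm)))

        threshold = self.scoring.accept_threshold(L)
        fallback_hits: list[tuple[int, str, AlignmentHit]] = []
        if (best is None or best < threshold) and any(cand.values()):
            for strand, chrom, cluster in self._fallback_clusters(cand, records, L):
                rb = per_strand[strand]
                for hit in self._banded_fallback(chrom, cluster, rb, sequence):
                    if best is None or hit.score > best:
                        best = hit.score
                    fallback_hits.append((hit.score, strand, hit))

        if best is None or best < threshold:
            self.stats["unmapped"] += 1
            return MappedRead(read_id, None, 0, best, L)

        # materialize only the winners, dedupe by position
        hits_by_pos: dict[tuple[str, int, str], AlignmentHit] = {}
        for score, strand, chrom, diag, kind, extra in records:
            if score != best:
                continue
            hit = self._materialize(score, chrom, diag, kind, extra,
                                    per_strand[strand], strand)
            if hit is not None:
                hits_by_pos.setdefault((hit.chrom, hit.start, hit.strand), hit)
        for score, strand, hit in fallback_hits:
            if score == best:
                hit = replace(hit, strand=strand)
                hits_by_pos.setdefault((hit.chrom, hit.start, hit.strand), hit)

        hits = list(hits_by_pos.values())
        chosen = resolve_ties(hits, self.seed, read_id)
        self.stats["mapped"] += 1
        if len(hits) > 1:
            self.stats["multi_best"] += 1
        self.stats["mismatch_bases"] += chosen.mismatches
        self.stats["gap_bases"] += chosen.gap_bases
        self.stats["aligned_bases"] += L
        return MappedRead(read_id, chosen, len(hits), best, L)

    def _materialize(self, score: int, chrom: str, diag: int, kind: str,
                     extra: tuple, read_bits: np.ndarray, strand: str,
                     ) -> AlignmentHit | None:
        L = len(read_bits)
        if kind == "U":
            mm = (L * self.scoring.match - score) // (
                self.scoring.match - self.scoring.mismatch)
            return AlignmentHit(chrom, diag, strand, score, int(mm), 0, L,
                                f"{L}M")
        g, mm = extra
        for s, gg, gap_type, i, m in self._split_search(chrom, diag, read_bits,
                                                        want_details=score):
            if s == score and gg == g and gap_type == kind and i >= 0:
                if gap_type == "D":
                    return AlignmentHit(chrom, diag, strand, score, m, g,
                                        L + g, _split_cigar(i, g, L - i, "D"))
                return AlignmentHit(chrom, diag, strand, score, m, g, L - g,
                                    _split_cigar(i, g, L - i - g, "I"))
        return None

    def _fallback_clusters(self, cand: Mapping[str, set[tuple[str, int]]],
                           records: list, L: int,
                           ) -> list[tuple[str, str, list[int]]]:
        """Cluster candidate diagonals per (strand, chrom) and keep the
        most promising clusters (by their best cheap score) for the exact
        banded DP; reads needing the fallback are rare."""
        best_by_key: dict[tuple[str, str, int], int] = {}
        for score, strand, chrom, diag, _, _ in records:
            key = (strand, chrom, diag)
            if key not in best_by_key or score > best_by_key[key]:
                best_by_key[key] = score
        clusters: list[tuple[int, str, str, list[int]]] = []
        for strand, cands in cand.items():
            by_chrom: dict[str, list[int]] = {}
            for chrom, diag in cands:
                by_chrom.setdefault(chrom, []).append(diag)
            for chrom, diags in by_chrom.items():
                diags.sort()
                current = [diags[0]]
                for d in diags[1:] + [None]:
                    if d is not None and d - current[-1] <= L:
                        current.append(d)
                    else:
                        cluster_best = max(
                            (best_by_key.get((strand, chrom, dd), -10 ** 9)
                             for dd in current), default=-10 ** 9)
                        clusters.append((cluster_best, strand, chrom, current))
                        if d is not None:
                            current = [d]
        clusters.sort(key=lambda t: -t[0])
        return [(strand, chrom, diags) for _, strand, chrom, diags
                in clusters[: self.max_fallback_clusters]]

    def map_reads(self, reads: Iterable) -> Iterator[MappedRead]:
        for read in reads:
            yield self.map_read(read.read_id, read.sequence)

    @property
    def mismatch_percent(self) -> float:
        """Accumulated mismatch percentage over all mapped reads (QC)."""
        if self.stats["aligned_bases"] == 0:
            return 0.0
        return 100.0 * self.stats["mismatch_bases"] / self.stats["aligned_bases"]


def _split_cigar(left: int, g: int, right: int, op: str) -> str:
    parts = []
    if left:
        parts.append(f"{left}M")
    parts.append(f"{g}{op}")
    if right:
        parts.append(f"{right}M")
    return "".join(parts)


# ---------------------------------------------------------------- output

def write_alignments_tsv(mapped: Iterable[MappedRead], path: str | Path) -> None:
    """SAM-like TSV: one row per read with mapping decision and hit details."""
    with open(path, "w") as fh:
        fh.write("read_id\tmapped\tchrom\tpos\tstrand\tscore\tmismatches"
                 "\tgap_bases\tcigar\tn_best\n")
        for m in mapped:
            if m.hit is None:
                fh.write(f"{m.read_id}\t0\t*\t-1\t*\t"
                         f"{'' if m.best_score is None else m.best_score}"
                         f"\t\t\t*\t0\n")
            else:
                h = m.hit
                fh.write(f"{m.read_id}\t1\t{h.chrom}\t{h.start}\t{h.strand}\t"
                         f"{h.score}\t{h.mismatches}\t{h.gap_bases}\t{h.cigar}"
                         f"\t{m.n_best}\n")


def read_alignments_tsv(path: str | Path) -> Iterator[MappedRead]:
    """Stream MappedRead records back from :func:`write_alignments_tsv` output."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"not an alignments TSV: {path}")
        for line in fh:
            (read_id, mapped_flag, chrom, pos, strand, score, mm, gaps,
             cigar, n_best) = line.rstrip("\n").split("\t")
            if mapped_flag == "0":
                best = int(score) if score else None
                yield MappedRead(read_id, None, 0, best, 0)
                continue
            span = sum(int(n) for n, op in _iter_cigar(cigar) if op in "MD")
            hit = AlignmentHit(chrom, int(pos), strand, int(score), int(mm),
                               int(gaps), span, cigar)
            read_len = sum(int(n) for n, op in _iter_cigar(cigar) if op in "MI")
            yield MappedRead(read_id, hit, int(n_best), int(score), read_len)


def _iter_cigar(cigar: str) -> Iterator[tuple[int, str]]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def write_sam(mapped: Iterable[MappedRead], genome_lengths: Mapping[str, int],
              path: str | Path, reads_by_id: Mapping[str, str] | None = None,
              ) -> None:
    """Minimal SAM emission (header + mapped records with NM tag)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in genome_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for m in mapped:
            seq = (reads_by_id or {}).get(m.read_id, "*")
            if m.hit is None:
                fh.write(f"{m.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            h = m.hit
            flag = 16 if h.strand == "-" else 0
            nm = h.mismatches + h.gap_bases
            fh.write(f"{m.read_id}\t{flag}\t{h.chrom}\t{h.start + 1}\t60\t"
                     f"{h.cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{nm}\n")
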