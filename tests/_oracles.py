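"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and shares no code with the package
internals: primer matching goes through Biopython's IUPAC tables, the
alignment oracle is a plain textbook DP (checked itself against exhaustive
path enumeration on tiny strings), and BH is the literal step-up formula.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ------------------------------------------------------------- virtual PCR

def naive_primer_hits(genome: str, primer: str, max_mm: int, protect: int,
                      three_prime_right: bool) -> list[tuple[int, int]]:
    """(start, mismatches) of every match of ``primer`` written left-to-right
    in ``genome``; protected positions are at the right end when the primer
    3' end points right, else at the left."""
    L = len(primer)
    hits = []
    prot_idx = set(range(L - protect, L)) if three_prime_right \
        else set(range(protect))
    for start in range(len(genome) - L + 1):
        window = genome[start:start + L]
        mm = 0
        ok = True
        for i, (p, b) in enumerate(zip(primer, window)):
            if b not in ambiguous_dna_values[p]:
                if i in prot_idx:
                    ok = False
                    break
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            hits.append((start, mm))
    return hits


def naive_find_amplicons(genome: dict[str, str], fwd: str, rev: str,
                         max_mm: int, protect: int, min_len: int,
                         max_len: int, both_strands: bool = True,
                         ) -> set[tuple[str, int, int, str]]:
    """All (chrom, start, end, strand) a degenerate primer pair amplifies,
    by scanning every position."""
    out: set[tuple[str, int, int, str]] = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        fwd_hits = naive_primer_hits(seq, fwd, max_mm, protect, True)
        rc_rev_hits = naive_primer_hits(seq, revcomp(rev), max_mm, protect,
                                        False)
        for f, _ in fwd_hits:
            for r, _ in rc_rev_hits:
                end = r + len(rev)
                if r >= f + len(fwd) and min_len <= end - f <= max_len:
                    out.add((chrom, f, end, "+"))
        if both_strands:
            rev_hits = naive_primer_hits(seq, rev, max_mm, protect, True)
            rc_fwd_hits = naive_primer_hits(seq, revcomp(fwd), max_mm,
                                            protect, False)
            for r, _ in rev_hits:
                for f, _ in rc_fwd_hits:
                    end = f + len(fwd)
                    if f >= r + len(rev) and min_len <= end - r <= max_len:
                        out.add((chrom, r, end, "-"))
    return out


# ---------------------------------------------------------------- alignment

def reference_glocal_score(read: str, ref: str, match: int = 1,
                           mismatch: int = -10, gap: int = -10,
                           both_strands: bool = True) -> int:
    """Textbook O(L*G) DP: read-global, reference-local, linear gaps."""
    def one_strand(r: str) -> int:
        L, G = len(r), len(ref)
        prev = [0] * (G + 1)
        best = None
        for i in range(1, L + 1):
            cur = [prev[0] + gap]
            for j in range(1, G + 1):
                s = match if r[i - 1] == ref[j - 1] else mismatch
                cur.append(max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap))
            prev = cur
        return max(prev)

    score = one_strand(read)
    if both_strands:
        score = max(score, one_strand(revcomp(read)))
    return score


def exhaustive_glocal_score(read: str, ref: str, match: int = 1,
                            mismatch: int = -10, gap: int = -10) -> int:
    """Enumerate every alignment path recursively (tiny inputs only,
    single strand)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        # best score aligning read[i:] starting at ref position j,
        # with free trailing reference
        if i == len(read):
            return 0
        options = [rec(i + 1, j) + gap]  # read base opposite a gap
        if j < len(ref):
            s = match if read[i] == ref[j] else mismatch
            options.append(rec(i + 1, j + 1) + s)
            options.append(rec(i, j + 1) + gap)  # ref base opposite a gap
        return max(options)

    return max(rec(0, j) for j in range(len(ref) + 1))


# ----------------------------------------------------------------- BH-FDR

def brute_force_bh(pvalues: list[float]) -> list[float]:
    """p_adj_i = min over j with p_j >= p_i of (m * p_(j) / rank_j)."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    for pos, i in enumerate(indexed):
        best = min(min(pvalues[indexed[q]] * m / (q + 1)
                       for q in range(pos, m)), 1.0)
        adj[i] = best
    return adj
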