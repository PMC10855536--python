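"""Virtual PCR: enumerate genomic loci amplifiable by a degenerate primer pair.

Endogenous-retrovirus families consist of many nearly identical genomic
copies; an amplicon assay with a (possibly degenerate) primer pair samples
the subset of copies whose primer-binding sites are conserved well enough.
This module scans a genome for every position where the forward and reverse
primer can anneal facing each other within a product-size window, allowing a
configurable number of mismatches per primer while protecting the primer's
3' end (where polymerase extension is intolerant of mispairing).

Coordinates are 0-based half-open throughout; BED is the interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from ._dna import IUPAC_MASKS, encode, primer_masks, reverse_complement, validate_iupac

#: sentinel returned by :func:`match_primer` when the window is rejected
NO_MATCH = None


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both written 5'->3' on their own strand.

    ``max_mismatches_per_primer`` is the annealing tolerance of the virtual
    PCR; ``three_prime_protected`` is the number of 3'-terminal bases in
    which no mismatch is tolerated at all.
    """

    forward: str
    reverse: str
    max_mismatches_per_primer: int = 2
    three_prime_protected: int = 3

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primer sequences must be non-empty")
        validate_iupac(self.forward, "forward primer")
        validate_iupac(self.reverse, "reverse primer")
        if self.max_mismatches_per_primer < 0:
            raise ValueError("max_mismatches_per_primer must be >= 0")
        if self.max_mismatches_per_primer > min(len(self.forward), len(self.reverse)):
            raise ValueError("mismatch budget exceeds primer length")
        if self.three_prime_protected < 0:
            raise ValueError("three_prime_protected must be >= 0")


@dataclass(frozen=True)
class PcrScanParams:
    """Product-size window and strand handling for the genome scan."""

    min_amplicon_len: int = 100
    max_amplicon_len: int = 2000
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_amplicon_len <= self.max_amplicon_len):
            raise ValueError("require 0 < min_amplicon_len <= max_amplicon_len")


@dataclass(frozen=True)
class AmpliconLocus:
    """One predicted primer-delimited genomic segment (an amplifiable copy).

    ``sequence`` is primer-inclusive and reported on the strand the forward
    primer binds, so for a minus-strand locus it is the reverse complement
    of the plus-strand genomic slice ``[start, end)``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    fwd_mismatches: int
    rev_mismatches: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("locus length does not match sequence length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


def match_primer(
    primer: str,
    genome_window: str,
    three_prime_protected: int = 0,
    max_mismatches: int | None = None,
) -> int | None:
    """Count IUPAC-aware mismatches of ``primer`` against an equal-length window.

    Returns the mismatch count, or :data:`NO_MATCH` (``None``) if the count
    exceeds ``max_mismatches`` or any mismatch falls within the protected
    3'-terminal positions. The window must consist of A/C/G/T.
    """
    if len(genome_window) != len(primer):
        raise ValueError("window length must equal primer length")
    bad = set(genome_window.upper()) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide characters in window: {sorted(bad)}")
    masks = primer_masks(primer)
    window = encode(genome_window)
    miss = (window & masks) == 0
    n = int(miss.sum())
    if max_mismatches is not None and n > max_mismatches:
        return NO_MATCH
    if three_prime_protected and miss[len(primer) - three_prime_protected:].any():
        return NO_MATCH
    return n


def _scan(
    genome_bits: np.ndarray,
    primer: str,
    max_mm: int,
    protect: int,
    protect_3prime_at_end: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """All start positions (and mismatch counts) where ``primer`` matches
    the encoded sequence as written.

    ``protect_3prime_at_end`` selects whether the ``protect`` mismatch-free
    bases sit at the right (primer as written) or left (reverse-complemented
    primer) end of the scanned pattern.
    """
    masks = primer_masks(primer)
    L = len(primer)
    n = len(genome_bits) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mm = np.zeros(n, dtype=np.int16)
    for i in range(L):
        mm += (genome_bits[i:i + n] & masks[i]) == 0
    ok = mm <= max_mm
    if protect:
        prot_mm = np.zeros(n, dtype=np.int16)
        rng = range(L - protect, L) if protect_3prime_at_end else range(protect)
        for i in rng:
            prot_mm += (genome_bits[i:i + n] & masks[i]) == 0
        ok &= prot_mm == 0
    pos = np.flatnonzero(ok)
    return pos, mm[pos].astype(np.int64)


def _pair_hits(
    fwd_pos: np.ndarray,
    fwd_mm: np.ndarray,
    rev_end: np.ndarray,
    rev_mm: np.ndarray,
    fwd_len: int,
    rev_len: int,
    params: PcrScanParams,
) -> list[tuple[int, int, int, int]]:
    """All (start, end, fwd_mm, rev_mm) with primers facing each other and
    product length inside the window."""
    out: list[tuple[int, int, int, int]] = []
    order = np.argsort(rev_end, kind="stable")
    rev_end_s, rev_mm_s = rev_end[order], rev_mm[order]
    for f, fm in zip(fwd_pos.tolist(), fwd_mm.tolist()):
        lo = np.searchsorted(rev_end_s, max(f + params.min_amplicon_len,
                                            f + fwd_len + rev_len))
        hi = np.searchsorted(rev_end_s, f + params.max_amplicon_len, side="right")
        for e, rm in zip(rev_end_s[lo:hi].tolist(), rev_mm_s[lo:hi].tolist()):
            out.append((f, e, fm, rm))
    return out


def find_amplicons(
    genome: Mapping[str, str],
    primers: PrimerPair,
    params: PcrScanParams | None = None,
) -> list[AmpliconLocus]:
    """Enumerate every amplicon the primer pair would produce from ``genome``.

    A plus-strand locus has the forward primer annealing on the plus strand
    and the reverse primer on the minus strand downstream of it; a
    minus-strand locus is the mirror image. All conformant pairs are
    reported, including overlapping or nested products. Loci are ordered by
    (chrom, start, end, strand) and labelled ``"<chrom>-<k>"`` with ``k``
    counting per chromosome.
    """
    params = params or PcrScanParams()
    if not genome:
        raise ValueError("empty genome")
    mm_budget = primers.max_mismatches_per_primer
    protect = primers.three_prime_protected

    raw: list[tuple[str, int, int, str, int, int]] = []
    for chrom in genome:
        seq = genome[chrom].upper()
        if not seq:
            continue
        bits = encode(seq)
        # plus strand: FWD as written ... revcomp(REV)
        f_pos, f_mm = _scan(bits, primers.forward, mm_budget, protect, True)
        r_pos, r_mm = _scan(bits, reverse_complement(primers.reverse), mm_budget,
                            protect, False)
        r_end = r_pos + len(primers.reverse)
        for s, e, fm, rm in _pair_hits(f_pos, f_mm, r_end, r_mm,
                                       len(primers.forward), len(primers.reverse),
                                       params):
            raw.append((chrom, s, e, "+", fm, rm))
        if params.both_strands:
            # minus strand: revcomp(FWD) downstream of REV as written
            f2_pos, f2_mm = _scan(bits, reverse_complement(primers.forward),
                                  mm_budget, protect, False)
            r2_pos, r2_mm = _scan(bits, primers.reverse, mm_budget, protect, True)
            f2_end = f2_pos + len(primers.forward)
            for s, e, rm, fm in _pair_hits(r2_pos, r2_mm, f2_end, f2_mm,
                                           len(primers.reverse), len(primers.forward),
                                           params):
                raw.append((chrom, s, e, "-", fm, rm))

    raw.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    loci: list[AmpliconLocus] = []
    counters: dict[str, int] = {}
    for chrom, s, e, strand, fm, rm in raw:
        counters[chrom] = counters.get(chrom, 0) + 1
        seq = genome[chrom][s:e].upper()
        if strand == "-":
            seq = reverse_complement(seq)
        loci.append(AmpliconLocus(
            locus_id=f"{chrom}-{counters[chrom]}",
            chrom=chrom, start=s, end=e, strand=strand, sequence=seq,
            fwd_mismatches=fm, rev_mismatches=rm,
        ))
    return loci


# ---------------------------------------------------------------- file I/O

def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) genome FASTA into an ordered {name: sequence} dict."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_loci_bed(loci: Iterable[AmpliconLocus], path: str | Path) -> None:
    """Write loci as BED6 (score column = total primer mismatches)."""
    with open(path, "w") as fh:
        for loc in loci:
            score = loc.fwd_mismatches + loc.rev_mismatches
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}"
                     f"\t{score}\t{loc.strand}\n")


def read_loci_bed(path: str | Path, genome: Mapping[str, str] | None = None,
                  ) -> list[AmpliconLocus]:
    """Read BED6 loci back; sequences are restored from ``genome`` if given."""
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, name, score, strand = line.rstrip("\n").split("\t")[:6]
            start, end = int(s), int(e)
            if genome is not None:
                seq = genome[chrom][start:end].upper()
                if strand == "-":
                    seq = reverse_complement(seq)
            else:
                seq = "N" * (end - start)  # placeholder; counting needs coords only
            loci.append(AmpliconLocus(name, chrom, start, end, strand, seq, 0, 0))
    return loci


def write_amplicon_fasta(loci: Iterable[AmpliconLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f">{loc.locus_id} {loc.chrom}:{loc.start}-{loc.end}({loc.strand})\n")
            for i in range(0, len(loc.sequence), 80):
                fh.write(loc.sequence[i:i + 80] + "\n")
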