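"""Read ingestion, primer trimming and length filtering.

Amplicon reads begin at one of the two primers and may run into the
reverse complement of the other, so a read can carry primer sequence at
zero, one or both ends and in either orientation. Primer bases are not
genomic signal (they are synthesised into every molecule), so they are
removed before mapping; afterwards only reads strictly longer than the
length floor are kept.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._dna import IUPAC_MASKS, encode, primer_masks, reverse_complement
from .insilico_pcr import PrimerPair


@dataclass
class SequencingRead:
    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for read {self.read_id!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"quality/sequence length mismatch for {self.read_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadFilterParams:
    """Post-trim length floor (strict ``>``) and primer-locating tolerance."""

    min_len_exclusive: int = 135
    trim_budget: int = 1

    def __post_init__(self) -> None:
        if self.min_len_exclusive < 0:
            raise ValueError("min_len_exclusive must be >= 0")
        if self.trim_budget < 0:
            raise ValueError("trim_budget must be >= 0")


@dataclass
class TrimReport:
    """Which ends were trimmed, and by which primer."""

    trimmed_5p: bool = False
    trimmed_3p: bool = False
    primer_5p: str | None = None  # "forward" | "reverse"
    primer_3p: str | None = None

    @property
    def untrimmed(self) -> bool:
        return not (self.trimmed_5p or self.trimmed_3p)


def _hamming_iupac(pattern: str, window: str) -> int:
    """IUPAC-aware mismatch count between a primer pattern and an ACGT window."""
    masks = primer_masks(pattern)
    return int(((encode(window) & masks) == 0).sum())


def trim_primers(
    read: SequencingRead,
    primers: PrimerPair,
    budget: int = 1,
) -> tuple[SequencingRead, TrimReport]:
    """Remove primer sequence from the read ends, if present.

    The 5' end is compared against both primers as written, the 3' end
    against both reverse complements; the better-matching primer wins an
    end if it fits within ``budget`` mismatches. A read shorter than a
    primer is returned untouched.
    """
    seq = read.sequence
    report = TrimReport()
    candidates_5p = [("forward", primers.forward), ("reverse", primers.reverse)]
    candidates_3p = [("reverse", reverse_complement(primers.reverse)),
                     ("forward", reverse_complement(primers.forward))]

    cut5 = 0
    best = budget + 1
    for name, pat in candidates_5p:
        if len(seq) >= len(pat):
            mm = _hamming_iupac(pat, seq[: len(pat)])
            if mm < best:
                best, cut5, report.primer_5p = mm, len(pat), name
    if best > budget:
        cut5, report.primer_5p = 0, None
    else:
        report.trimmed_5p = True

    cut3 = 0
    best = budget + 1
    for name, pat in candidates_3p:
        if len(seq) - cut5 >= len(pat):
            mm = _hamming_iupac(pat, seq[len(seq) - len(pat):])
            if mm < best:
                best, cut3, report.primer_3p = mm, len(pat), name
    if best > budget:
        cut3, report.primer_3p = 0, None
    else:
        report.trimmed_3p = True

    if cut5 == 0 and cut3 == 0:
        return read, report
    end = len(seq) - cut3
    qual = read.qualities[cut5:end] if read.qualities is not None else None
    return SequencingRead(read.read_id, seq[cut5:end], qual), report


def length_filter(
    reads: Iterable[SequencingRead],
    params: ReadFilterParams | None = None,
) -> tuple[list[SequencingRead], int]:
    """Keep reads strictly longer than the floor; return (kept, dropped count)."""
    params = params or ReadFilterParams()
    kept, dropped = [], 0
    for read in reads:
        if len(read) > params.min_len_exclusive:
            kept.append(read)
        else:
            dropped += 1
    return kept, dropped


# ---------------------------------------------------------------- FASTQ I/O

def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SequencingRead]:
    """Stream a FASTQ file (plain or gzip)."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield SequencingRead(header[1:].split()[0].rstrip("\n"), seq, qual or None)


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = read.qualities or "I" * len(read)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def trim_and_filter_file(
    fastq_in: str | Path,
    fastq_out: str | Path,
    primers: PrimerPair,
    params: ReadFilterParams | None = None,
) -> dict[str, int]:
    """Trim + length-filter a FASTQ file; returns per-category read tallies."""
    params = params or ReadFilterParams()
    tallies = {"input": 0, "trimmed_both": 0, "trimmed_one": 0, "untrimmed": 0,
               "kept": 0, "dropped_short": 0}

    def _process():
        for read in read_fastq(fastq_in):
            tallies["input"] += 1
            trimmed, rep = trim_primers(read, primers, params.trim_budget)
            if rep.trimmed_5p and rep.trimmed_3p:
                tallies["trimmed_both"] += 1
            elif rep.untrimmed:
                tallies["untrimmed"] += 1
            else:
                tallies["trimmed_one"] += 1
            if len(trimmed) > params.min_len_exclusive:
                tallies["kept"] += 1
                yield trimmed
            else:
                tallies["dropped_short"] += 1

    write_fastq(_process(), fastq_out)
    return tallies
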