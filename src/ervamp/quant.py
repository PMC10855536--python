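"""Per-locus read counting and relative-frequency conversion.

A mapped read is attributed to a locus when at least ``min_overlap`` of its
aligned reference span falls inside the locus interval (default 0.9; the
amplicon design means on-target reads lie entirely within a locus, so the
rule only matters for boundary-spanning or spurious alignments). Reads
overlapping no locus are tallied off-target, preserving the per-sample
identity ``mapped == on_target + off_target``.

Relative frequency is a locus's count as a percentage of a per-sample
denominator — either the on-target total (rows then sum to exactly 100) or
all mapped reads. Downstream differential expression consumes the raw
counts; frequencies serve the fold-change descriptive statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import MappedRead
from .insilico_pcr import AmpliconLocus

logger = logging.getLogger(__name__)


@dataclass
class LocusCountMatrix:
    """Raw counts (loci x samples) plus per-sample mapping tallies.

    ``totals`` has one row per sample with columns
    ``mapped_total, on_target_total, off_target, unmapped``;
    ``groups`` maps sample -> group label (e.g. case/control).
    """

    counts: pd.DataFrame
    totals: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        on_target = self.counts.sum(axis=0)
        if not (on_target.to_numpy()
                == self.totals["on_target_total"].to_numpy()).all():
            raise ValueError("on_target_total does not equal column sums")
        if (self.totals["on_target_total"] > self.totals["mapped_total"]).any():
            raise ValueError("on-target total exceeds mapped total")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def loci(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class FrequencyMatrix:
    """Percentages with the same shape as the count matrix; samples with a
    zero denominator are flagged and carry NaN, never a fabricated 0."""

    frequencies: pd.DataFrame
    denominator: str
    flagged_samples: list[str]
    groups: pd.Series


class _LocusIntervals:
    """Per-chromosome sorted interval lookup for a (small) locus set."""

    def __init__(self, loci: Sequence[AmpliconLocus]):
        self.by_chrom: dict[str, list[AmpliconLocus]] = {}
        for loc in loci:
            self.by_chrom.setdefault(loc.chrom, []).append(loc)
        for lst in self.by_chrom.values():
            lst.sort(key=lambda l: l.start)

    def best_overlap(self, chrom: str, start: int, end: int,
                     ) -> tuple[AmpliconLocus | None, int]:
        """Locus with the largest overlap of [start, end), ties to the
        leftmost locus."""
        best, best_ov = None, 0
        for loc in self.by_chrom.get(chrom, ()):
            if loc.start >= end:
                break
            ov = min(end, loc.end) - max(start, loc.start)
            if ov > best_ov:
                best, best_ov = loc, ov
        return best, best_ov


def count_sample(mapped: Iterable[MappedRead], loci: Sequence[AmpliconLocus],
                 min_overlap: float = 0.9,
                 ) -> tuple[pd.Series, dict[str, int]]:
    """Count one sample's mapped reads per locus.

    Returns (per-locus counts, tallies) where tallies carries
    ``mapped_total``, ``on_target_total``, ``off_target`` and ``unmapped``.
    """
    intervals = _LocusIntervals(loci)
    known_chroms = set(intervals.by_chrom)
    counts = pd.Series(0, index=[l.locus_id for l in loci], dtype=np.int64)
    tallies = {"mapped_total": 0, "on_target_total": 0, "off_target": 0,
               "unmapped": 0}
    for m in mapped:
        if m.hit is None:
            tallies["unmapped"] += 1
            continue
        tallies["mapped_total"] += 1
        h = m.hit
        if h.chrom not in known_chroms:
            warnings.warn(f"hit on chromosome {h.chrom!r} with no loci; "
                          "counted off-target", stacklevel=2)
            tallies["off_target"] += 1
            continue
        loc, ov = intervals.best_overlap(h.chrom, h.start, h.end)
        if loc is not None and ov >= min_overlap * h.aligned_ref_span:
            counts[loc.locus_id] += 1
            tallies["on_target_total"] += 1
        else:
            tallies["off_target"] += 1
    return counts, tallies


def assign_to_loci(mapped_by_sample: Mapping[str, Iterable[MappedRead]],
                   loci: Sequence[AmpliconLocus],
                   groups: Mapping[str, str],
                   min_overlap: float = 0.9) -> LocusCountMatrix:
    """Build the loci x samples count matrix from per-sample mapped reads."""
    cols, tall_rows = {}, {}
    for sample, mapped in mapped_by_sample.items():
        counts, tallies = count_sample(mapped, loci, min_overlap)
        cols[sample] = counts
        tall_rows[sample] = tallies
    counts = pd.DataFrame(cols)
    totals = pd.DataFrame(tall_rows).T[
        ["mapped_total", "on_target_total", "off_target", "unmapped"]]
    group_series = pd.Series({s: groups[s] for s in counts.columns})
    return LocusCountMatrix(counts, totals, group_series)


def to_frequencies(matrix: LocusCountMatrix,
                   denominator: str = "on_target") -> FrequencyMatrix:
    """Convert counts to per-sample percentages.

    ``denominator`` is ``"on_target"`` (counted reads; rows sum to exactly
    100) or ``"all_mapped"``. A sample with a zero denominator is flagged
    and its frequencies are NaN.
    """
    if denominator == "on_target":
        denom = matrix.totals["on_target_total"]
    elif denominator == "all_mapped":
        denom = matrix.totals["mapped_total"]
    else:
        raise ValueError("denominator must be 'on_target' or 'all_mapped'")
    flagged = denom.index[denom == 0].tolist()
    if flagged:
        logger.warning("zero %s denominator for samples %s; frequencies "
                       "undefined", denominator, flagged)
    safe = denom.replace(0, np.nan)
    freqs = 100.0 * matrix.counts / safe
    return FrequencyMatrix(freqs, denominator, flagged, matrix.groups)


def low_count_filter(matrix: LocusCountMatrix, min_count: int = 1,
                     sample_fraction: float = 0.5,
                     ) -> tuple[list[str], list[str]]:
    """Exclude loci with fewer than ``min_count`` reads in more than
    ``sample_fraction`` of samples (strict 'more than').

    Returns (retained locus ids, excluded locus ids).
    """
    n_samples = matrix.counts.shape[1]
    n_below = (matrix.counts < min_count).sum(axis=1)
    excluded_mask = n_below > sample_fraction * n_samples
    retained = matrix.counts.index[~excluded_mask].tolist()
    excluded = matrix.counts.index[excluded_mask].tolist()
    return retained, excluded


# ---------------------------------------------------------------- file I/O

def write_counts_tsv(matrix: LocusCountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("locus_id").to_csv(path, sep="\t")


def write_frequencies_tsv(freqs: FrequencyMatrix, path: str | Path) -> None:
    freqs.frequencies.rename_axis("locus_id").to_csv(path, sep="\t",
                                                     float_format="%.6f")


def write_sample_qc_tsv(matrix: LocusCountMatrix, path: str | Path,
                        mismatch_percent: float | None = None) -> None:
    qc = matrix.totals.copy()
    with np.errstate(invalid="ignore"):
        qc["on_target_percent"] = np.where(
            qc["mapped_total"] > 0,
            100.0 * qc["on_target_total"] / qc["mapped_total"], np.nan)
    if mismatch_percent is not None:
        qc["run_mismatch_percent"] = mismatch_percent
    qc.rename_axis("sample").to_csv(path, sep="\t", float_format="%.4f")


def read_counts_tsv(path: str | Path,
                    sample_sheet: pd.DataFrame | None = None,
                    ) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with at least columns ``sample`` and ``group``."""
    sheet = pd.read_csv(path, sep="\t")
    missing = {"sample", "group"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet
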