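"""Synthetic-data generator for the amplicon-expression pipeline.

Emulates the statistical structure of a locus-specific ERV amplicon
experiment so that every stage can be tested against known ground truth:

* a genome carrying ``n_loci`` divergent copies of a proviral ENV-like
  consensus segment, each flanked by primer-binding sites that may carry
  up to two planted (non-3'-protected) mismatches;
* per-sample per-locus expression with one dominant locus (~48% of reads)
  and a long tail of rare loci, case/control groups, and planted fold
  changes on chosen loci;
* single-end amplicon reads starting at either primer, with substitution
  errors and homopolymer-biased indels in the style of semiconductor
  sequencing.

Every read id encodes its source locus, so pipeline output can be audited
read by read. All randomness descends from one seed via spawned
``SeedSequence`` streams; the same config is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import IUPAC_SETS, reverse_complement
from .insilico_pcr import AmpliconLocus, PrimerPair, write_loci_bed

_BASES = np.array(list("ACGT"))

#: a degenerate primer pair of the kind used for ERV ENV assays
#: (invented sequences; real assay primers are supplied by the user)
DEFAULT_PRIMERS = PrimerPair(
    forward="TGGGAATTCCTRAATGCCTATTC",
    reverse="CATACGTTAYCTGGTCCTGAACA",
)

#: read depth matching the study-scale preset (mean reads per sample)
PAPER_SCALE_READS = 70694


@dataclass
class SimConfig:
    """All knobs of the generator, with study-shaped defaults.

    Defaults follow the conditions the pipeline is meant to reproduce:
    27 amplifiable copies, 8 vs 8 groups, one locus carrying ~48% of
    reads with a long low-frequency tail, and reads a couple of hundred
    bases long with low substitution and indel error rates. Read depth
    defaults to 6000 per sample, a scaled-down working depth; set
    ``reads_per_sample`` to :data:`PAPER_SCALE_READS` for study-scale
    runs.
    """

    seed: int = 0
    n_loci: int = 27
    consensus_len: int = 600
    divergence_range: tuple[float, float] = (0.02, 0.08)
    genome_background_len: int = 20000
    n_chroms: int = 5
    primers: PrimerPair = DEFAULT_PRIMERS
    primer_site_mismatch_range: tuple[int, int] = (0, 2)
    group_sizes: tuple[int, int] = (8, 8)  # (control, case)
    dominant_mass: float = 0.48
    second_mass: float = 0.075
    tail_top: float = 0.10
    tail_bottom: float = 2e-4
    planted_effects: tuple[tuple[int, float], ...] = ((12, 4.0), (18, 0.5))
    reads_per_sample: int = 6000
    depth_cv: float = 0.3
    #: minimum background gap between adjacent loci; keep it large enough
    #: that a forward site of one locus cannot pair with the reverse site
    #: of the next within the virtual-PCR product window (i.e. spacing +
    #: 2 x amplicon length must exceed max_amplicon_len of the scan)
    locus_spacing: int = 800
    read_len_range: tuple[int, int] = (150, 190)
    sub_rate: float = 0.005
    indel_rate: float = 0.001
    homopolymer_factor: float = 4.0
    minus_strand_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        lo, hi = self.read_len_range
        if lo > hi or lo < 1:
            raise ValueError("invalid read_len_range")
        for idx, fold in self.planted_effects:
            if not 0 <= idx < self.n_loci:
                raise ValueError(f"planted locus index {idx} out of range")
            if fold < 0:
                raise ValueError("planted fold must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    loci: list[AmpliconLocus]
    proportions: pd.DataFrame        # loci x {control, case} expected fractions
    planted: tuple[tuple[str, float], ...]  # (locus_id, fold)
    sample_groups: pd.Series = field(default_factory=pd.Series)
    true_counts: pd.DataFrame | None = None  # loci x samples source counts


def _concretize(rng: np.random.Generator, primer: str) -> str:
    """Replace IUPAC degeneracies by a concrete base drawn from the code's set."""
    return "".join(b if b in "ACGT" else rng.choice(list(IUPAC_SETS[b]))
                   for b in primer)


def _plant_mismatches(rng: np.random.Generator, site: str, primer: str,
                      n_mm: int, protect: int) -> str:
    """Introduce ``n_mm`` substitutions outside the primer's protected
    3' positions, each to a base outside the primer's IUPAC set."""
    site_l = list(site)
    eligible = [i for i in range(len(site) - protect)]
    for i in rng.choice(eligible, size=n_mm, replace=False):
        allowed = set(IUPAC_SETS[primer[i]])
        choices = [b for b in "ACGT" if b not in allowed]
        site_l[i] = str(rng.choice(choices))
    return "".join(site_l)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute a ``rate`` fraction of positions to a different base."""
    seq_l = list(seq)
    n_sub = int(round(rate * len(seq)))
    for i in rng.choice(len(seq), size=n_sub, replace=False):
        seq_l[i] = str(rng.choice([b for b in "ACGT" if b != seq_l[i]]))
    return "".join(seq_l)


def baseline_proportions(config: SimConfig) -> np.ndarray:
    """Deterministic control-group locus proportions: one dominant locus,
    one secondary, and a log-spaced tail rescaled to absorb the rest."""
    n = config.n_loci
    if n == 1:
        return np.array([1.0])
    if n == 2:
        p = np.array([config.dominant_mass, 1.0 - config.dominant_mass])
        return p
    tail = np.geomspace(config.tail_top, config.tail_bottom, n - 2)
    tail *= (1.0 - config.dominant_mass - config.second_mass) / tail.sum()
    return np.concatenate(([config.dominant_mass, config.second_mass], tail))


def group_proportions(config: SimConfig, locus_ids: Sequence[str],
                      ) -> pd.DataFrame:
    """Expected locus proportions per group. The case group multiplies the
    planted loci by their fold and renormalizes."""
    base = baseline_proportions(config)
    case = base.copy()
    for idx, fold in config.planted_effects:
        case[idx] *= fold
    case /= case.sum()
    return pd.DataFrame({"control": base, "case": case}, index=list(locus_ids))


def build_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Assemble the synthetic genome and its ground-truth locus set.

    Loci are distributed round-robin over ``n_chroms`` chromosomes at
    non-overlapping positions inside random background sequence; a locus
    may be inserted on the minus strand. Deterministic under the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    primers = config.primers
    consensus = _random_seq(rng, config.consensus_len)

    amplicons: list[tuple[str, str, int, int]] = []  # (seq, strand, fmm, rmm)
    lo_mm, hi_mm = config.primer_site_mismatch_range
    for _ in range(config.n_loci):
        div = rng.uniform(*config.divergence_range)
        core = _diverge(rng, consensus, div)
        fmm = int(rng.integers(lo_mm, hi_mm + 1))
        rmm = int(rng.integers(lo_mm, hi_mm + 1))
        fwd_site = _plant_mismatches(rng, _concretize(rng, primers.forward),
                                     primers.forward, fmm,
                                     primers.three_prime_protected)
        rev_site = _plant_mismatches(rng, _concretize(rng, primers.reverse),
                                     primers.reverse, rmm,
                                     primers.three_prime_protected)
        amp = fwd_site + core + reverse_complement(rev_site)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        amplicons.append((amp, strand, fmm, rmm))

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
    for i in range(config.n_loci):
        per_chrom[chrom_names[i % config.n_chroms]].append(i)

    bg_len = max(config.genome_background_len // config.n_chroms, 200)
    genome: dict[str, str] = {}
    placements: list[tuple[str, int, int, int]] = []  # (chrom, start, end, amp idx)
    margin = 100
    for chrom in chrom_names:
        idxs = per_chrom[chrom]
        k = len(idxs)
        base_gap = max(config.locus_spacing, (bg_len - margin) // (k + 1) if k else 0)
        parts: list[str] = []
        pos = 0
        for amp_i in idxs:
            gap = base_gap + int(rng.integers(0, base_gap // 4 + 1))
            parts.append(_random_seq(rng, gap))
            pos += gap
            amp, strand, _, _ = amplicons[amp_i]
            inserted = amp if strand == "+" else reverse_complement(amp)
            parts.append(inserted)
            placements.append((chrom, pos, pos + len(amp), amp_i))
            pos += len(amp)
        parts.append(_random_seq(rng, margin))
        genome[chrom] = "".join(parts)

    # locus ids mirror the virtual-PCR labelling: per-chromosome ordinals
    placements.sort(key=lambda t: (t[0], t[1]))
    loci: list[AmpliconLocus] = []
    order: list[int] = []
    counters: dict[str, int] = {}
    for chrom, start, end, amp_i in placements:
        counters[chrom] = counters.get(chrom, 0) + 1
        amp, strand, fmm, rmm = amplicons[amp_i]
        loci.append(AmpliconLocus(f"{chrom}-{counters[chrom]}", chrom, start,
                                  end, strand, amp, fmm, rmm))
        order.append(amp_i)

    # proportions are defined over config locus indices; re-index by id
    props_cfg = group_proportions(config, [str(i) for i in range(config.n_loci)])
    props = props_cfg.iloc[order]
    props.index = [loc.locus_id for loc in loci]
    planted = tuple((loci[order.index(idx)].locus_id, fold)
                    for idx, fold in config.planted_effects)
    return genome, SimTruth(loci=loci, proportions=props, planted=planted)


def _apply_errors(rng: np.random.Generator, seq: str, config: SimConfig) -> str:
    """Substitutions at ``sub_rate`` plus 1-base indels at ``indel_rate``,
    the latter multiplied inside homopolymer runs."""
    out: list[str] = []
    prev = ""
    for base in seq:
        p_indel = config.indel_rate * (
            config.homopolymer_factor if base == prev else 1.0)
        r = rng.random()
        if r < p_indel / 2:
            prev = base
            continue  # deletion
        if r < p_indel:
            out.append(base)  # insertion: duplicate the base
        if rng.random() < config.sub_rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        else:
            out.append(base)
        prev = base
    return "".join(out)


def simulate_reads(
    genome: Mapping[str, str],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[dict[str, list], SimTruth]:
    """Draw per-sample reads from the truth proportions.

    Returns ({sample: [SequencingRead, ...]}, truth) with
    ``truth.sample_groups`` and ``truth.true_counts`` filled in. Sample
    names are ``ctrl01..`` and ``case01..``; read ids encode sample,
    ordinal, source locus and primer end for auditing.
    """
    from .reads import SequencingRead  # local import to avoid a cycle

    n_control, n_case = config.group_sizes
    samples = ([(f"ctrl{i + 1:02d}", "control") for i in range(n_control)]
               + [(f"case{i + 1:02d}", "case") for i in range(n_case)])
    locus_ids = [loc.locus_id for loc in truth.loci]
    amp_seqs = {loc.locus_id: loc.sequence for loc in truth.loci}

    ss = np.random.SeedSequence(config.seed).spawn(len(samples) + 2)
    reads_by_sample: dict[str, list] = {}
    true_counts = pd.DataFrame(0, index=locus_ids,
                               columns=[s for s, _ in samples], dtype=np.int64)
    lo_len, hi_len = config.read_len_range

    for (sample, group), seed_child in zip(samples, ss[2:]):
        rng = np.random.default_rng(seed_child)
        depth = config.reads_per_sample
        if config.depth_cv > 0:
            sigma = np.sqrt(np.log1p(config.depth_cv ** 2))
            depth = max(1, int(round(depth * rng.lognormal(-sigma ** 2 / 2,
                                                           sigma))))
        p = truth.proportions[group].reindex(locus_ids).to_numpy()
        counts = rng.multinomial(depth, p)
        true_counts[sample] = counts
        reads = []
        n = 0
        for locus_id, k in zip(locus_ids, counts):
            amp = amp_seqs[locus_id]
            for _ in range(k):
                n += 1
                end = "F" if rng.random() < 0.5 else "R"
                rl = int(rng.integers(lo_len, hi_len + 1))
                rl = min(rl, len(amp))
                raw = amp[:rl] if end == "F" else reverse_complement(amp)[:rl]
                seq = _apply_errors(rng, raw, config)
                read_id = f"{sample}:{n:06d}:{locus_id}:{end}"
                reads.append(SequencingRead(read_id, seq, "I" * len(seq)))
        # shuffle so file order carries no locus signal
        rng.shuffle(reads)
        reads_by_sample[sample] = reads

    truth.sample_groups = pd.Series({s: g for s, g in samples})
    truth.true_counts = true_counts
    return reads_by_sample, truth


# ---------------------------------------------------------------- file I/O

def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_simulation(outdir: str | Path, config: SimConfig,
                     gzip_fastq: bool = True) -> SimTruth:
    """Run the full generator and write genome FASTA, truth BED, per-sample
    FASTQ, truth counts TSV and sample sheet TSV under ``outdir``."""
    from .reads import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = build_genome(config)
    reads_by_sample, truth = simulate_reads(genome, truth, config)

    write_genome_fasta(genome, outdir / "genome.fa")
    write_loci_bed(truth.loci, outdir / "truth_loci.bed")
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    for sample, reads in reads_by_sample.items():
        write_fastq(reads, fastq_dir / f"{sample}{suffix}")
    truth.true_counts.rename_axis("locus_id").to_csv(
        outdir / "truth_counts.tsv", sep="\t")
    truth.proportions.rename_axis("locus_id").to_csv(
        outdir / "truth_proportions.tsv", sep="\t", float_format="%.8g")
    sheet = pd.DataFrame({"sample": truth.sample_groups.index,
                          "group": truth.sample_groups.values})
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "truth_planted.tsv", "w") as fh:
        fh.write("locus_id\tfold\n")
        for locus_id, fold in truth.planted:
            fh.write(f"{locus_id}\t{fold}\n")
    return truth
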