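"""End-to-end orchestration: simulate -> virtual PCR -> trim/filter ->
align -> count -> group statistics, with a run manifest.

Each stage consumes and produces plain files (FASTA/BED/FASTQ/TSV), so the
stages are independently runnable and the whole run is reproducible: the
same config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .align import AlignmentScoring, GenomeAligner, write_alignments_tsv
from .destats import NbFitParams, compare_groups, summarize_rfc, write_comparison_tsv
from .insilico_pcr import (AmpliconLocus, PcrScanParams, PrimerPair,
                           find_amplicons, read_genome_fasta,
                           write_amplicon_fasta, write_loci_bed)
from .quant import (LocusCountMatrix, assign_to_loci, low_count_filter,
                    to_frequencies, write_counts_tsv, write_frequencies_tsv,
                    write_sample_qc_tsv)
from .reads import ReadFilterParams, length_filter, read_fastq, trim_primers
from .simulate import SimConfig, write_simulation

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration (exit code 2)."""


class DataError(RuntimeError):
    """A stage failed on its input data (exit code 3)."""


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    outdir: str = "ervamp_out"
    seed: int = 0
    simulate: SimConfig | None = field(default_factory=SimConfig)
    # external inputs, used when simulate is None
    genome_fasta: str | None = None
    fastq_dir: str | None = None
    sample_sheet: str | None = None
    primers: PrimerPair | None = None  # defaults to the simulation primers
    scan: PcrScanParams = field(default_factory=PcrScanParams)
    read_filter: ReadFilterParams = field(default_factory=ReadFilterParams)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    min_overlap: float = 0.9
    denominator: str = "on_target"
    case_group: str = "case"
    control_group: str = "control"
    low_count_min: int = 1
    low_count_fraction: float = 0.5
    gzip_fastq: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        try:
            kwargs: dict[str, Any] = {}
            sub_types = {"simulate": SimConfig, "scan": PcrScanParams,
                         "read_filter": ReadFilterParams,
                         "scoring": AlignmentScoring, "primers": PrimerPair}
            for key, value in raw.items():
                if key in sub_types and isinstance(value, dict):
                    if key == "simulate" and "primers" in value:
                        value = dict(value)
                        value["primers"] = PrimerPair(**value["primers"])
                    kwargs[key] = sub_types[key](**value)
                elif key == "simulate" and value in (None, False):
                    kwargs[key] = None
                else:
                    kwargs[key] = value
            config = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        if config.simulate is None and not (
                config.genome_fasta and config.fastq_dir and config.sample_sheet):
            raise ConfigError("without a simulate block, genome_fasta, "
                              "fastq_dir and sample_sheet are required")
        if config.simulate is not None:
            # one seed drives everything
            config.simulate = dataclasses.replace(config.simulate,
                                                  seed=config.seed)
        return config

    def resolved_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns a result bundle with the key tables.

    Writes counts, frequencies, per-locus comparison, QC and a manifest
    into ``config.outdir``. Raises :class:`DataError` with a stage tag on
    failure.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"ervamp_version": __version__,
                                "seed": config.seed,
                                "parameters": config.resolved_dict(),
                                "stages": {}}

    # -- stage: simulate (or load external inputs) ---------------------------
    if config.simulate is not None:
        sim_dir = outdir / "sim"
        truth = write_simulation(sim_dir, config.simulate,
                                 gzip_fastq=config.gzip_fastq)
        genome = read_genome_fasta(sim_dir / "genome.fa")
        sheet = pd.DataFrame({"sample": truth.sample_groups.index,
                              "group": truth.sample_groups.values})
        suffix = ".fastq.gz" if config.gzip_fastq else ".fastq"
        fastq_paths = {s: sim_dir / "fastq" / f"{s}{suffix}"
                       for s in truth.sample_groups.index}
        primers = config.primers or config.simulate.primers
        manifest["stages"]["simulate"] = {
            "n_loci": len(truth.loci),
            "samples": list(truth.sample_groups.index)}
    else:
        try:
            genome = read_genome_fasta(config.genome_fasta)
            sheet = pd.read_csv(config.sample_sheet, sep="\t")
        except (OSError, ValueError) as exc:
            raise DataError(f"[input] {exc}") from exc
        fastq_dir = Path(config.fastq_dir)
        fastq_paths = {}
        for sample in sheet["sample"]:
            for suffix in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
                p = fastq_dir / f"{sample}{suffix}"
                if p.exists():
                    fastq_paths[sample] = p
                    break
            else:
                raise DataError(f"[input] no FASTQ for sample {sample!r}")
        if config.primers is None:
            raise ConfigError("primers required when not simulating")
        primers = config.primers
    groups = dict(zip(sheet["sample"], sheet["group"]))

    # -- stage: virtual PCR --------------------------------------------------
    try:
        loci = find_amplicons(genome, primers, config.scan)
    except ValueError as exc:
        raise DataError(f"[pcr] {exc}") from exc
    if not loci:
        raise DataError("[pcr] no amplicon loci found for the primer pair")
    write_loci_bed(loci, outdir / "loci.bed")
    write_amplicon_fasta(loci, outdir / "amplicons.fa")
    manifest["stages"]["pcr"] = {"n_loci": len(loci)}
    logger.info("virtual PCR: %d loci", len(loci))

    # -- stages: trim/filter + align (streamed per sample) -------------------
    aligner = GenomeAligner(genome, config.scoring, seed=config.seed)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    mapped_by_sample: dict[str, list] = {}
    trim_tallies: dict[str, dict[str, int]] = {}
    for sample in sheet["sample"]:
        tall = {"input": 0, "kept": 0, "dropped_short": 0}
        kept_reads = []
        for read in read_fastq(fastq_paths[sample]):
            tall["input"] += 1
            trimmed, _rep = trim_primers(read, primers,
                                         config.read_filter.trim_budget)
            if len(trimmed) > config.read_filter.min_len_exclusive:
                tall["kept"] += 1
                kept_reads.append(trimmed)
            else:
                tall["dropped_short"] += 1
        trim_tallies[sample] = tall
        mapped = [aligner.map_read(r.read_id, r.sequence) for r in kept_reads]
        write_alignments_tsv(mapped, aln_dir / f"{sample}.tsv")
        mapped_by_sample[sample] = mapped
    manifest["stages"]["trim_filter"] = trim_tallies
    manifest["stages"]["align"] = dict(aligner.stats)
    manifest["stages"]["align"]["mismatch_percent"] = aligner.mismatch_percent

    # -- stage: count --------------------------------------------------------
    matrix = assign_to_loci(mapped_by_sample, loci, groups, config.min_overlap)
    freqs = to_frequencies(matrix, config.denominator)
    write_counts_tsv(matrix, outdir / "counts.tsv")
    write_frequencies_tsv(freqs, outdir / "frequencies.tsv")
    write_sample_qc_tsv(matrix, outdir / "sample_qc.tsv",
                        aligner.mismatch_percent)
    manifest["stages"]["count"] = {
        "on_target_total": int(matrix.totals["on_target_total"].sum()),
        "off_target": int(matrix.totals["off_target"].sum()),
        "unmapped": int(matrix.totals["unmapped"].sum())}

    # -- stage: stats --------------------------------------------------------
    retained, excluded = low_count_filter(matrix, config.low_count_min,
                                          config.low_count_fraction)
    try:
        comparison = compare_groups(matrix.counts.loc[retained],
                                    freqs.frequencies.loc[retained],
                                    groups, config.case_group,
                                    config.control_group)
    except ValueError as exc:
        raise DataError(f"[stats] {exc}") from exc
    write_comparison_tsv(comparison, outdir / "comparison.tsv")
    summary = pd.DataFrame([
        {"subset": name, **summarize_rfc(comparison, subset=name)}
        for name in ("all", "changed_only")])
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    manifest["stages"]["stats"] = {"retained_loci": len(retained),
                                   "excluded_loci": excluded,
                                   "n_fdr05": int((comparison["p_adj"] < 0.05)
                                                  .sum())}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"loci": loci, "counts": matrix, "frequencies": freqs,
            "comparison": comparison, "summary": summary,
            "manifest": manifest}
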