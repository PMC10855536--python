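from __future__ import annotations

import numpy as np
import pytest

from ervamp._dna import reverse_complement
from ervamp.insilico_pcr import find_amplicons
from ervamp.simulate import (SimConfig, baseline_proportions, build_genome,
                             group_proportions, simulate_reads,
                             write_simulation)


class TestBuildGenome:
    def test_truth_bed_has_n_loci(self, small_genome, small_sim_config):
        genome, truth = small_genome
        assert len(truth.loci) == small_sim_config.n_loci
        for loc in truth.loci:
            segment = genome[loc.chrom][loc.start:loc.end]
            expected = loc.sequence if loc.strand == "+" \
                else reverse_complement(loc.sequence)
            assert segment == expected

    def test_loci_are_divergent_within_range(self, small_genome,
                                             small_sim_config):
        _, truth = small_genome
        lo, hi = small_sim_config.divergence_range
        plen = len(small_sim_config.primers.forward)
        cores = [l.sequence[plen:-len(small_sim_config.primers.reverse)]
                 for l in truth.loci]
        # pairwise divergence of two copies is at most the sum of their
        # divergences from the consensus (and > 0 for distinct copies)
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                diff = np.mean([a != b for a, b in zip(cores[i], cores[j])])
                assert 0 < diff <= 2 * hi + 0.01

    def test_single_locus_genome(self):
        config = SimConfig(seed=1, n_loci=1, consensus_len=200, n_chroms=1,
                           planted_effects=())
        genome, truth = build_genome(config)
        assert len(truth.loci) == 1
        assert len(genome) == 1

    def test_deterministic_under_seed(self, small_sim_config):
        g1, t1 = build_genome(small_sim_config)
        g2, t2 = build_genome(small_sim_config)
        assert g1 == g2
        assert [(l.locus_id, l.start) for l in t1.loci] == \
            [(l.locus_id, l.start) for l in t2.loci]

    def test_different_seed_differs(self, small_sim_config):
        import dataclasses
        other = dataclasses.replace(small_sim_config, seed=99)
        g1, _ = build_genome(small_sim_config)
        g2, _ = build_genome(other)
        assert g1 != g2

    def test_virtual_pcr_finds_exactly_the_truth(self, small_genome,
                                                 small_sim_config,
                                                 small_scan_params):
        genome, truth = small_genome
        found = find_amplicons(genome, small_sim_config.primers,
                               small_scan_params)
        assert {(l.chrom, l.start, l.end, l.strand) for l in found} == \
            {(l.chrom, l.start, l.end, l.strand) for l in truth.loci}


class TestProportions:
    def test_baseline_structure(self):
        config = SimConfig()
        p = baseline_proportions(config)
        assert p.shape == (27,)
        assert np.isclose(p.sum(), 1.0)
        assert np.isclose(p[0], 0.48)
        assert np.isclose(p[1], 0.075)
        assert (np.diff(p[2:]) < 0).all()  # monotone tail
        assert p[-1] < 1e-3

    def test_planted_fold_in_case_group(self):
        config = SimConfig(planted_effects=((12, 4.0),))
        props = group_proportions(config, [str(i) for i in range(27)])
        ratio = (props.loc["12", "case"] / props.loc["12", "control"])
        # renormalization slightly shrinks the realized ratio
        assert 3.9 < ratio <= 4.0
        assert np.isclose(props["case"].sum(), 1.0)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, small_genome):
        import dataclasses
        config = dataclasses.replace(
            SimConfig(seed=11, n_loci=8, consensus_len=300, n_chroms=3,
                      reads_per_sample=200, group_sizes=(1, 1),
                      planted_effects=()),
            sub_rate=0.0, indel_rate=0.0)
        genome, truth = build_genome(config)
        reads, truth = simulate_reads(genome, truth, config)
        amp = {l.locus_id: l.sequence for l in truth.loci}
        for read in reads["ctrl01"]:
            locus_id, end = read.read_id.split(":")[2:4]
            source = amp[locus_id] if end == "F" \
                else reverse_complement(amp[locus_id])
            assert source.startswith(read.sequence)

    def test_dominant_locus_within_multinomial_envelope(self):
        config = SimConfig(seed=5, reads_per_sample=10_000, depth_cv=0.0,
                           group_sizes=(1, 0), planted_effects=())
        genome, truth = build_genome(config)
        _, truth = simulate_reads(genome, truth, config)
        dominant_id = truth.proportions["control"].idxmax()
        observed = truth.true_counts.loc[dominant_id, "ctrl01"]
        n, p = 10_000, 0.48
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) < 3 * sigma

    def test_planted_fold_visible_in_truth_counts(self):
        config = SimConfig(seed=7, reads_per_sample=20_000, depth_cv=0.0,
                           group_sizes=(4, 4), planted_effects=((12, 4.0),))
        genome, truth = build_genome(config)
        _, truth = simulate_reads(genome, truth, config)
        locus_id = truth.planted[0][0]
        case_cols = [s for s, g in truth.sample_groups.items() if g == "case"]
        ctrl_cols = [s for s, g in truth.sample_groups.items()
                     if g == "control"]
        case_rate = truth.true_counts.loc[locus_id, case_cols].sum() \
            / truth.true_counts[case_cols].sum().sum()
        ctrl_rate = truth.true_counts.loc[locus_id, ctrl_cols].sum() \
            / truth.true_counts[ctrl_cols].sum().sum()
        assert 3.0 < case_rate / ctrl_rate < 5.0

    def test_read_ids_audit_source_locus(self, small_cohort):
        _, truth, reads_by_sample = small_cohort
        locus_ids = {l.locus_id for l in truth.loci}
        for sample, reads in reads_by_sample.items():
            for read in reads[:20]:
                parts = read.read_id.split(":")
                assert parts[0] == sample
                assert parts[2] in locus_ids


class TestWriteSimulation:
    def test_outputs_exist_and_are_deterministic(self, tmp_path):
        config = SimConfig(seed=3, n_loci=4, consensus_len=200, n_chroms=2,
                           reads_per_sample=50, group_sizes=(2, 2),
                           planted_effects=((2, 3.0),))
        t1 = write_simulation(tmp_path / "a", config, gzip_fastq=False)
        t2 = write_simulation(tmp_path / "b", config, gzip_fastq=False)
        for name in ("genome.fa", "truth_loci.bed", "truth_counts.tsv",
                     "samples.tsv", "truth_planted.tsv"):
            a = (tmp_path / "a" / name).read_bytes()
            b = (tmp_path / "b" / name).read_bytes()
            assert a == b, name
        fq = tmp_path / "a" / "fastq"
        assert sorted(p.name for p in fq.iterdir()) == \
            ["case01.fastq", "case02.fastq", "ctrl01.fastq", "ctrl02.fastq"]
        assert t1.true_counts.equals(t2.true_counts)
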