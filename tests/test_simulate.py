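"""Synthetic genome and library generation with planted ground truth."""
import re

import numpy as np
import pytest

from xlsite.ingest import collapse_barcoded, truncation_sites
from xlsite.io import (read_cdna_tsv, read_segments_bed, write_cdna_tsv,
                       write_fasta, write_segments_bed)
from xlsite.simulate import (SimulationConfig, SizingError, generate_genome,
                             simulate_cdnas, simulate_library)
from xlsite._seq import as_genome


SMALL = SimulationConfig(genome_length=8_000, n_cdnas=2_000, seed=42)


class TestConfigValidation:
    def test_probabilities_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            SimulationConfig(readthrough_fraction=1.5)

    def test_background_rate_cannot_exceed_readthrough_rate(self):
        with pytest.raises(ValueError):
            SimulationConfig(del_rate_background=0.2, del_rate_readthrough=0.1)

    def test_oversized_features_raise_sizing_error(self):
        cfg = SimulationConfig(genome_length=500,
                               ycay_cluster_spec=((10, 5),) * 20)
        with pytest.raises(SizingError):
            generate_genome(cfg)


class TestGenerateGenome:
    def test_same_seed_gives_identical_genomes_and_truth(self, tmp_path):
        g1, s1, t1 = generate_genome(SMALL)
        g2, s2, t2 = generate_genome(SMALL)
        assert g1 == g2
        assert s1.equals(s2)
        assert t1.sites == t2.sites
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(g1, p1)
        write_fasta(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_planted_motifs_match_ycay_pattern(self):
        genome, _, truth = generate_genome(SMALL)
        for chrom, strand, q in truth.ycay_motifs:
            if strand == "+":
                sub = genome[chrom][q : q + 4]
            else:
                from xlsite._seq import revcomp

                sub = revcomp(genome[chrom][q - 3 : q + 1])
            assert re.fullmatch(r"[CT]CA[CT]", sub)

    def test_planted_ttt_runs_are_exact_length(self):
        cfg = SimulationConfig(genome_length=8_000, ttt_run_spec=((3, 10),),
                               seed=7)
        genome, _, truth = generate_genome(cfg)
        runs3 = [r for r in truth.ttt_runs if r[2] == 3]
        assert len(runs3) == 10
        for chrom, start, length in runs3:
            window = genome[chrom][start - 1 : start + length + 1]
            # a brute-force regex oracle: TTT not embedded in a longer run
            assert re.fullmatch(r"[^T]TTT[^T]", window)

    def test_sites_lie_inside_genome(self):
        genome, _, truth = generate_genome(SMALL)
        for s in truth.sites:
            assert 0 <= s.position < len(genome[s.chrom])
        assert truth.weights.sum() == pytest.approx(1.0)

    def test_segments_partition_each_chromosome(self):
        cfg = SimulationConfig(genome_length=8_000, n_chromosomes=2, seed=1)
        genome, segments, _ = generate_genome(cfg)
        for chrom, g in segments.groupby("chrom"):
            g = g.sort_values("start")
            assert g["start"].iloc[0] == 0
            assert g["end"].iloc[-1] == len(genome[chrom])
            assert np.all(g["end"].to_numpy()[:-1] == g["start"].to_numpy()[1:])

    def test_adding_chromosomes_preserves_earlier_ones(self):
        g1, _, _ = generate_genome(SMALL)
        cfg2 = SimulationConfig(genome_length=8_000, n_cdnas=2_000, seed=42,
                                n_chromosomes=2)
        g2, _, _ = generate_genome(cfg2)
        assert g1["chr1"] == g2["chr1"]


class TestSimulateCdnas:
    def test_pure_truncation_recovers_planted_sites_exactly(self):
        cfg = SimulationConfig(genome_length=8_000, n_cdnas=2_000, seed=3,
                               readthrough_fraction=0.0,
                               del_rate_readthrough=0.0,
                               del_rate_background=0.0,
                               pcr_duplication_rate=0.0)
        genome, _, truth = generate_genome(cfg)
        records = simulate_cdnas(genome, truth, cfg)
        observed = {(s.chrom, s.strand, s.position)
                    for s in truncation_sites(records)}
        planted = {(s.chrom, s.strand, s.position) for s in truth.sites}
        assert observed <= planted
        assert len(observed) > 0.9 * len(planted)  # all but unsampled sites

    def test_degenerate_rates_put_deletion_in_every_read(self):
        cfg = SimulationConfig(genome_length=8_000, n_cdnas=500, seed=3,
                               readthrough_fraction=1.0,
                               del_rate_readthrough=1.0)
        genome, _, truth = generate_genome(cfg)
        records = simulate_cdnas(genome, truth, cfg)
        assert all(len(r.deletions) == 1 for r in records)

    def test_no_pcr_duplication_collapse_preserves_count(self):
        cfg = SimulationConfig(genome_length=8_000, n_cdnas=2_000, seed=5,
                               pcr_duplication_rate=0.0, barcode_length=16)
        genome, _, truth = generate_genome(cfg)
        records = simulate_cdnas(genome, truth, cfg)
        assert len(records) == cfg.n_cdnas
        assert len(collapse_barcoded(records)) == cfg.n_cdnas

    def test_readthrough_deletion_rate_converges(self):
        n = 20_000
        cfg = SimulationConfig(genome_length=20_000, n_cdnas=n, seed=11,
                               readthrough_fraction=1.0,
                               pcr_duplication_rate=0.0)
        genome, _, truth = generate_genome(cfg)
        records = simulate_cdnas(genome, truth, cfg)
        prop = sum(1 for r in records if r.deletions) / n
        sd = np.sqrt(0.11 * 0.89 / n)
        assert abs(prop - 0.11) < 3 * sd

    def test_deletions_concentrate_at_homopolymer_runs(self):
        from dataclasses import replace

        from xlsite._seq import homopolymer_runs

        cfg = SimulationConfig(genome_length=20_000, n_cdnas=20_000, seed=13,
                               readthrough_fraction=1.0,
                               pcr_duplication_rate=0.0,
                               homopolymer_del_bias=10.0)
        genome, _, truth = generate_genome(cfg)
        _, _, run_len = homopolymer_runs(genome["chr1"])

        def in_run_fraction(config):
            records = simulate_cdnas(genome, truth, config)
            dels = [r.deletions[0] for r in records if r.deletions]
            return np.mean([run_len[d] >= 3 for d in dels])

        biased = in_run_fraction(cfg)
        unbiased = in_run_fraction(replace(cfg, homopolymer_del_bias=1.0))
        assert biased > 2 * unbiased

    def test_same_seed_reproduces_records(self):
        genome, _, truth = generate_genome(SMALL)
        a = simulate_cdnas(genome, truth, SMALL)
        b = simulate_cdnas(genome, truth, SMALL)
        assert a == b


class TestRoundTrips:
    def test_fasta_segments_cdnas_truth_round_trip(self, tmp_path):
        genome, segments, truth, records = simulate_library(SMALL)
        fa = tmp_path / "genome.fa"
        bed = tmp_path / "segments.bed"
        tsv = tmp_path / "cdnas.tsv"
        truth_tsv = tmp_path / "truth.tsv"
        write_fasta(genome, fa)
        write_segments_bed(segments, bed)
        write_cdna_tsv(records, tsv)
        truth.write_tsv(truth_tsv)

        assert as_genome(str(fa)) == genome
        seg2 = read_segments_bed(bed)
        assert seg2[["chrom", "start", "end", "segment_type"]].equals(
            segments[["chrom", "start", "end", "segment_type"]]
        )
        assert read_cdna_tsv(tsv) == records
        truth2 = truth.read_sites_tsv(truth_tsv)
        assert [(s.chrom, s.strand, s.position) for s in truth.sites] == \
            list(truth2[["chrom", "strand", "position"]].itertuples(index=False,
                                                                    name=None))
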