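"""Motif occurrence/closest/background/enrichment/composition profiles."""
import re

import numpy as np
import pandas as pd
import pytest

from xlsite._seq import motif_starts, revcomp
from xlsite.profiles import (assign_segments, closest_motif, enrichment,
                             motif_occurrence, motif_variant_proportions,
                             nucleotide_composition, randomized_background,
                             BackgroundModel, OffsetProfile)

from conftest import make_site


def segments_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "segment_type",
                                       "score", "strand"])


class TestMotifStarts:
    def test_overlapping_instances_counted(self):
        # YCAY on CCACCAC: instances start at 0 and 3
        hits = np.flatnonzero(motif_starts("CCACCAC", "YCAY"))
        assert hits.tolist() == [0, 3]


class TestMotifOccurrence:
    def test_single_planted_instance(self):
        seq = "G" * 100
        p = 50
        genome = {"chr1": seq[: p + 1] + "TCAT" + seq[p + 5 :]}
        prof = motif_occurrence([make_site(position=p)], "YCAY", genome, 10)
        expected = np.zeros(21)
        expected[10 + 1] = 1
        assert np.array_equal(prof.values, expected)

    def test_minus_strand_mirror_of_plus_example(self):
        seq = "G" * 100
        p = 50
        plus_genome = {"chr1": seq[: p + 1] + "TCAT" + seq[p + 5 :]}
        minus_genome = {"chr1": revcomp(plus_genome["chr1"])}
        p_minus = len(seq) - 1 - p
        prof_plus = motif_occurrence([make_site(position=p)], "YCAY",
                                     plus_genome, 10)
        prof_minus = motif_occurrence(
            [make_site(strand="-", position=p_minus)], "YCAY", minus_genome, 10
        )
        assert np.array_equal(prof_plus.values, prof_minus.values)

    def test_matches_regex_oracle_on_random_genome(self, rng):
        n = 400
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}
        sites = [make_site(strand=s, position=int(p))
                 for s, p in zip("++--++--", rng.integers(60, n - 60, 8))]
        window = 25
        prof = motif_occurrence(sites, "YCAY", genome, window)
        oracle = np.zeros(2 * window + 1)
        pat = re.compile(r"(?=([CT]CA[CT]))")
        for s in sites:
            seq = genome["chr1"]
            if s.strand == "+":
                sub = seq[s.position - window : s.position + window + 4]
                for m in pat.finditer(sub):
                    if m.start() <= 2 * window:
                        oracle[m.start()] += 1
            else:
                sub = revcomp(seq[s.position - window - 3 : s.position + window + 1])
                for m in pat.finditer(sub):
                    if m.start() <= 2 * window:
                        oracle[m.start()] += 1
        assert np.array_equal(prof.values, oracle)

    def test_unstranded_site_split_over_both_strands(self):
        genome = {"chr1": "G" * 30 + "TCAT" + "G" * 30}
        prof = motif_occurrence([make_site(strand=".", position=29)], "YCAY",
                                genome, 5)
        assert prof.n_sites == 1.0
        assert prof.values[5 + 1] == 0.5  # plus-strand half-weight hit


class TestClosestMotif:
    @pytest.mark.parametrize(
        "offsets,expected",
        [((-5, 5), -5), ((1,), 1), ((-3, 2), 2)],
    )
    def test_distance_and_upstream_tie_rule(self, offsets, expected):
        p = 60
        seq = list("G" * 140)
        for o in offsets:
            seq[p + o : p + o + 4] = "TCAT"
        genome = {"chr1": "".join(seq)}
        prof = closest_motif([make_site(position=p)], "YCAY", genome, 20)
        hits = prof.offsets[prof.values > 0]
        assert hits.tolist() == [expected]

    def test_at_most_one_record_per_site(self, rng):
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 500))}
        sites = [make_site(position=int(p))
                 for p in rng.integers(60, 440, 20)]
        prof = closest_motif(sites, "YCAY", genome, 30)
        assert prof.values.sum() <= len(sites)


class TestRandomizedBackground:
    def test_uniform_sequence_background_is_flat_at_composition_expectation(self, rng):
        # P(YCAY at a fixed offset) = (1/2)(1/4)(1/4)(1/2) = 1/64 on uniform ACGT
        n = 6000
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}
        segments = segments_frame([("chr1", 0, n, "genic", 0, ".")])
        sites = [make_site(position=int(p)) for p in rng.integers(100, n - 100, 50)]
        bg = randomized_background(sites, segments, "YCAY", genome, n=100,
                                   window=50, seed=9)
        freq = bg.mean / bg.n_sites
        assert abs(freq.mean() - 1 / 64) < 0.002
        assert np.all(np.abs(freq - 1 / 64) < 0.008)

    def test_seeded_runs_reproduce_exactly(self, toy_genome):
        segments = segments_frame([("chr1", 0, 50, "genic", 0, ".")])
        sites = [make_site(position=25)]
        a = randomized_background(sites, segments, "YCAY", toy_genome, n=1,
                                  window=10, seed=4)
        b = randomized_background(sites, segments, "YCAY", toy_genome, n=1,
                                  window=10, seed=4)
        assert np.array_equal(a.mean, b.mean)

    def test_degenerate_single_nt_segment_keeps_site_position(self, toy_genome):
        segments = segments_frame([("chr1", 9, 10, "genic", 0, ".")])
        sites = [make_site(position=9)]
        bg = randomized_background(sites, segments, "YCAY", toy_genome, n=5,
                                   window=10, seed=0)
        obs = motif_occurrence(sites, "YCAY", toy_genome, 10)
        assert np.array_equal(bg.mean, obs.values)

    def test_sites_outside_segments_are_excluded_with_tally(self, toy_genome):
        segments = segments_frame([("chr1", 0, 10, "genic", 0, ".")])
        assigned, n_outside = assign_segments(
            [("chr1", "+", 5, 1.0), ("chr1", "+", 45, 1.0)], segments
        )
        assert len(assigned) == 1 and n_outside == 1

    def test_background_converges_between_100_and_500_randomizations(self, rng):
        n = 3000
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}
        segments = segments_frame([("chr1", 0, n, "genic", 0, ".")])
        sites = [make_site(position=int(p)) for p in rng.integers(100, n - 100, 40)]
        m100 = randomized_background(sites, segments, "YCAY", genome, n=100,
                                     window=50, seed=1).mean.mean()
        m500 = randomized_background(sites, segments, "YCAY", genome, n=500,
                                     window=50, seed=2).mean.mean()
        assert abs(m100 - m500) / m500 < 0.02


class TestEnrichment:
    def test_identical_profiles_ratio_one(self):
        offsets = np.arange(-5, 6)
        obs = OffsetProfile(offsets, np.full(11, 3.0), 10)
        bg = BackgroundModel(offsets, np.full(11, 3.0), 100, 5, 10, "YCAY")
        enr = enrichment(obs, bg)
        assert np.allclose(enr.ratio, 1.0)

    def test_spike_smoothing_spreads_mean(self):
        offsets = np.arange(-5, 6)
        vals = np.zeros(11)
        vals[5] = 5.0
        obs = OffsetProfile(offsets, vals, 10)
        bg = BackgroundModel(offsets, np.ones(11), 100, 5, 10, "YCAY")
        enr = enrichment(obs, bg)
        assert np.allclose(enr.smoothed[3:8], 1.0)

    def test_zero_background_reported_missing(self):
        offsets = np.arange(-2, 3)
        obs = OffsetProfile(offsets, np.ones(5), 10)
        bg = BackgroundModel(offsets, np.array([1, 0, 1, 1, 1.0]), 100, 2, 10, "Y")
        enr = enrichment(obs, bg)
        assert np.isnan(enr.ratio[1])

    def test_threshold_region_finds_longest_run(self):
        offsets = np.arange(-4, 5)
        smoothed = np.array([1, 3, 3, 1, 1, 3, 3, 3, 1.0])
        from xlsite.profiles import EnrichmentProfile

        enr = EnrichmentProfile(offsets, smoothed, smoothed)
        assert enr.threshold_region(2.0) == (1, 3)


class TestComposition:
    def test_planted_base_at_offset_zero(self):
        genome = {"chr1": "G" * 40 + "T" + "G" * 40}
        prof = nucleotide_composition([make_site(position=40)], genome, 10)
        freq = prof.frequencies
        t_row = prof.bases.index("T")
        assert freq[t_row, 10] == 1.0

    def test_frequencies_sum_to_one_per_offset(self, rng):
        n = 500
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}
        sites = [make_site(strand=s, position=int(p))
                 for s, p in zip("+-+-", rng.integers(60, n - 60, 4))]
        prof = nucleotide_composition(sites, genome, 20)
        assert np.allclose(prof.frequencies.sum(axis=0), 1.0)

    def test_uniform_genome_frequencies_near_quarter(self, rng):
        n = 4000
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}
        sites = [make_site(position=int(p)) for p in rng.integers(100, n - 100, 300)]
        prof = nucleotide_composition(sites, genome, 10)
        # 3 sigma for a binomial(300, 1/4) frequency is ~0.075
        assert np.all(np.abs(prof.frequencies - 0.25) < 0.1)


class TestVariantProportions:
    def test_single_variant_dominates_near_range(self):
        genome = {"chr1": "G" * 50 + "G" + "TCAC" + "G" * 50}
        props = motif_variant_proportions([make_site(position=50)], genome)
        assert props.loc["TCAC", "near"] == 1.0

    def test_proportions_sum_to_one_per_range(self, rng):
        n = 2000
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}
        sites = [make_site(position=int(p)) for p in rng.integers(100, n - 100, 60)]
        props = motif_variant_proportions(sites, genome)
        assert props["near"].sum() == pytest.approx(1.0)
        assert props["wide"].sum() == pytest.approx(1.0)

    def test_empty_range_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            motif_variant_proportions([make_site(position=25)], toy_genome,
                                      near_range=(3, 1))

    def test_planted_variant_shift_recovered(self, rng):
        """A site set built with mostly-TCAC motifs right at the site but a
        mixed wide neighbourhood shows the near-range composition shift."""
        chunks = []
        sites = []
        pos = 0
        for i in range(40):
            pad = "".join("AG"[j] for j in rng.integers(0, 2, 50))
            chunks.append(pad)
            pos += 50
            near = "TCAC" if i % 4 else "CCAT"   # 75% TCAC at the site
            wide = "CCAT" if i % 2 else "TCAT"   # mixed farther out
            chunks.append(near + "AAAGGAAAGG" + wide)
            sites.append(make_site(position=pos - 1))
            pos += 18
        genome = {"chr1": "".join(chunks) + "G" * 60}
        props = motif_variant_proportions(sites, genome,
                                          near_range=(0, 2), wide_range=(-20, 20))
        assert props.loc["TCAC", "near"] == pytest.approx(0.75)
        assert props.loc["CCAT", "wide"] > props.loc["CCAT", "near"]


def test_strand_covariance_profiles_invariant_under_genome_flip(rng):
    n = 600
    genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}
    flipped = {"chr1": revcomp(genome["chr1"])}
    sites = [make_site(strand=s, position=int(p))
             for s, p in zip("++--", rng.integers(80, n - 80, 4))]
    mirrored = [make_site(strand="-" if s.strand == "+" else "+",
                          position=n - 1 - s.position) for s in sites]
    for fn in (motif_occurrence, closest_motif):
        a = fn(sites, "YCAY", genome, 25)
        b = fn(mirrored, "YCAY", flipped, 25)
        assert np.array_equal(a.values, b.values)
    ca = nucleotide_composition(sites, genome, 25)
    cb = nucleotide_composition(mirrored, flipped, 25)
    assert np.array_equal(ca.counts, cb.counts)
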