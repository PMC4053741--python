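"""Synthetic genomes and cDNA libraries with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* a toy genome with planted YCAY clusters (closely spaced YCAY tetramers,
  configurable count and spacing) and TTT homopolymer runs, the remainder
  uniform over ACGT;
* cross-link sites placed one nucleotide transcript-upstream of each motif
  of each cluster (so the motif sits at offset +1), with per-site occupancy
  weights equal to the local motif-cluster score of the realized sequence,
  emulating affinity that grows with the number of proximal motifs;
* a two-population cDNA library: read-through cDNAs (probability f) whose
  5' ends extend past the cross-link site and which carry an elevated
  per-read deletion rate, and truncated cDNAs starting one nucleotide 3' of
  the site with a low background deletion rate;
* deletion placement biased toward homonucleotide runs, with the aligner's
  homopolymer ambiguity emulated by shifting each in-run deletion to the
  highest genomic coordinate of its run (which is what produces the
  two-strand profile shift that TTT re-definition corrects);
* random barcodes and geometric PCR duplication.

Identical config and seed give byte-identical outputs; chromosomes draw from
deterministic sub-streams so adding chromosomes does not perturb earlier
ones.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import homopolymer_runs, random_bases, revcomp
from .records import CrossLinkSite, MappedCdna

YCAY_VARIANTS = ("TCAT", "TCAC", "CCAT", "CCAC")
_SPACER_ALPHABET = "AG"  # spacers that cannot create new YCAY or TTT instances


class SizingError(ValueError):
    """Requested planted features do not fit in the genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome and cDNA libraries.

    Defaults mirror the Nova iCLIP study conditions: read-through fraction
    0.18, per-read deletion rates 0.11 (read-through) and 0.004
    (background), ~50 nt cDNAs, deletions evaluated in the first 25 nt.
    """

    genome_length: int = 20_000
    n_chromosomes: int = 1
    #: one planted cluster per entry: (n_motifs, spacing_nt between motifs)
    ycay_cluster_spec: Tuple[Tuple[int, int], ...] = (
        (3, 3), (4, 3), (5, 2), (6, 2), (8, 2),
    )
    #: (run_length, count) of planted TTT (or longer) homopolymer runs
    ttt_run_spec: Tuple[Tuple[int, int], ...] = ((3, 10), (4, 4), (5, 2))
    readthrough_fraction: float = 0.18
    del_rate_readthrough: float = 0.11
    del_rate_background: float = 0.004
    homopolymer_del_bias: float = 10.0
    n_cdnas: int = 50_000
    barcode_length: int = 9
    pcr_duplication_rate: float = 0.2
    read_length: int = 50
    read_length_sd: float = 8.0
    min_read_length: int = 30
    #: truncated cDNAs start this many nt 3' of the site (1 = UV-C convention,
    #: 0 = the NSUN2 mode where cDNAs truncate directly at the site)
    truncation_offset: int = 1
    minus_strand_fraction: float = 0.5
    segment_size: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("readthrough_fraction", "del_rate_readthrough",
                     "del_rate_background", "pcr_duplication_rate",
                     "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.del_rate_background > self.del_rate_readthrough:
            raise ValueError(
                "del_rate_background must not exceed del_rate_readthrough "
                "(the mixture model the estimation assumes)"
            )
        if self.truncation_offset not in (0, 1):
            raise ValueError("truncation_offset must be 0 or 1")
        if self.min_read_length < 1 or self.read_length < self.min_read_length:
            raise ValueError("bad read length configuration")


@dataclass
class PlantedTruth:
    """Ground truth of a generated genome and library."""

    sites: List[CrossLinkSite]
    weights: np.ndarray                      # per-site occupancy weights (sum 1)
    ycay_motifs: List[Tuple[str, str, int]]  # (chrom, strand, transcript start)
    ttt_runs: List[Tuple[str, int, int]]     # (chrom, genomic start, length)
    readthrough_fraction: float
    del_rate_readthrough: float
    del_rate_background: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.chrom, s.strand, s.position, w)
            for s, w in zip(self.sites, self.weights)
        ]
        return pd.DataFrame(rows, columns=["chrom", "strand", "position", "weight"])

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_sites_tsv(path: str) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


_EDGE_MARGIN = 150   # keep features clear of chromosome ends (reads + windows)
_FEATURE_GAP = 60    # minimum spacing between planted features


def _place_features(rng: np.random.Generator, length: int,
                    sizes: Sequence[int]) -> List[int]:
    """Non-overlapping start positions for features of the given sizes."""
    need = sum(sizes) + (_FEATURE_GAP + 1) * len(sizes) + 2 * _EDGE_MARGIN
    if need > length:
        raise SizingError(
            f"planted features need ~{need} nt but the chromosome has {length}"
        )
    placed: List[Tuple[int, int]] = []
    out = []
    for size in sizes:
        for _attempt in range(10_000):
            start = int(rng.integers(_EDGE_MARGIN, length - _EDGE_MARGIN - size))
            lo, hi = start - _FEATURE_GAP, start + size + _FEATURE_GAP
            if all(hi <= a or lo >= b for a, b in placed):
                placed.append((start, start + size))
                out.append(start)
                break
        else:
            raise SizingError("could not place planted features without overlap")
    return out


def _build_cluster(rng: np.random.Generator, n_motifs: int,
                   spacing: int) -> Tuple[str, List[int]]:
    """Transcript-sense cluster sequence and motif start offsets within it."""
    parts: List[str] = []
    starts = []
    pos = 0
    for j in range(n_motifs):
        starts.append(pos)
        parts.append(YCAY_VARIANTS[int(rng.integers(len(YCAY_VARIANTS)))])
        pos += 4
        if j < n_motifs - 1:
            parts.append(random_bases(rng, spacing, _SPACER_ALPHABET))
            pos += spacing
    return "".join(parts), starts


def generate_genome(config: SimulationConfig):
    """Build the genome, segment annotation and planted truth.

    Returns ``(genome, segments, truth)`` where ``genome`` is a
    ``{chrom: sequence}`` dict, ``segments`` alternates genic/intergenic
    blocks of ``segment_size`` and ``truth`` records planted motifs, runs,
    cross-link sites and their occupancy weights.
    """
    genome: Dict[str, str] = {}
    seg_rows = []
    sites: List[CrossLinkSite] = []
    weights: List[float] = []
    motifs: List[Tuple[str, str, int]] = []
    runs: List[Tuple[str, int, int]] = []

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        rng = np.random.default_rng((config.seed, 7, ci))
        seq = np.frombuffer(random_bases(rng, config.genome_length).encode(),
                            dtype="S1").copy()

        cluster_seqs = []
        for n_motifs, spacing in config.ycay_cluster_spec:
            cluster_seqs.append((_build_cluster(rng, n_motifs, spacing), n_motifs))
        run_sizes = [ln for ln, count in config.ttt_run_spec for _ in range(count)]
        sizes = [len(cs[0][0]) for cs in cluster_seqs] + run_sizes
        positions = _place_features(rng, config.genome_length, sizes)
        cluster_pos = positions[: len(cluster_seqs)]
        run_pos = positions[len(cluster_seqs):]

        for ((cseq, rel_starts), n_motifs), g in zip(cluster_seqs, cluster_pos):
            minus = rng.random() < config.minus_strand_fraction
            if minus:
                stamped = revcomp(cseq)
                strand = "-"
                # transcript start of motif with sense offset i is g+len-1-i
                motif_starts_genomic = [g + len(cseq) - 1 - i for i in rel_starts]
                site_positions = [q + 1 for q in motif_starts_genomic]
            else:
                stamped = cseq
                strand = "+"
                motif_starts_genomic = [g + i for i in rel_starts]
                site_positions = [q - 1 for q in motif_starts_genomic]
            seq[g : g + len(cseq)] = np.frombuffer(stamped.encode(), dtype="S1")
            for q in motif_starts_genomic:
                motifs.append((chrom, strand, q))
            for p in site_positions:
                sites.append(CrossLinkSite(chrom, strand, p, 1, "truncation"))

        for run_len, g in zip(run_sizes, run_pos):
            seq[g : g + run_len] = b"T"
            # non-T flanks so the planted run is not embedded in a longer run
            for flank_pos in (g - 1, g + run_len):
                seq[flank_pos] = random_bases(rng, 1, "ACG").encode()
            runs.append((chrom, g, run_len))

        genome[chrom] = seq.tobytes().decode()

        # Occupancy: each site's weight is the local YCAY score of the
        # realized sequence at the site (affinity grows with the number of
        # proximal motifs), so planted cDNA counts track motif density.
        from .clusters import ycay_score

        score = ycay_score(genome[chrom], both_strands=True)
        weights.extend(float(max(1, score[s.position])) for s in sites[len(weights):])

        kinds = ("genic", "intergenic")
        for bi, s in enumerate(range(0, config.genome_length, config.segment_size)):
            seg_rows.append((chrom, s, min(s + config.segment_size,
                                           config.genome_length),
                             kinds[bi % 2], 0, "."))

    w = np.asarray(weights, dtype=float)
    truth = PlantedTruth(
        sites=sites,
        weights=w / w.sum() if len(w) else w,
        ycay_motifs=motifs,
        ttt_runs=runs,
        readthrough_fraction=config.readthrough_fraction,
        del_rate_readthrough=config.del_rate_readthrough,
        del_rate_background=config.del_rate_background,
    )
    segments = pd.DataFrame(
        seg_rows,
        columns=["chrom", "start", "end", "segment_type", "score", "strand"],
    )
    return genome, segments, truth


def _barcodes(rng: np.random.Generator, n: int, length: int) -> List[str]:
    idx = rng.integers(0, 4, (n, length))
    letters = np.array(list("ACGT"))
    return ["".join(row) for row in letters[idx]]


def simulate_cdnas(genome: Dict[str, str], truth: PlantedTruth,
                   config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None) -> List[MappedCdna]:
    """Simulate a mapped cDNA library (PCR duplicates included).

    Each cDNA picks a cross-link site by occupancy weight, is read-through
    with probability ``readthrough_fraction`` (5' end overshooting the site)
    or truncated (starting ``truncation_offset`` nt 3' of the site), and
    carries at most one single-nucleotide deletion placed in the first 25 nt
    of the read with the class-specific rate. Read-through deletions
    concentrate near the site and at homonucleotide runs
    (``homopolymer_del_bias``); any in-run deletion is then shifted to the
    run's highest genomic coordinate, emulating the aligner's homopolymer
    ambiguity resolution.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 11))
    if not truth.sites:
        raise ValueError("no planted cross-link sites")

    chroms = sorted(genome)
    run_end_at: Dict[str, np.ndarray] = {}
    run_len_at: Dict[str, np.ndarray] = {}
    for c in chroms:
        _, ends, lens = homopolymer_runs(genome[c])
        run_end_at[c], run_len_at[c] = ends, lens

    n = config.n_cdnas
    site_idx = rng.choice(len(truth.sites), size=n, p=truth.weights)
    is_rt = rng.random(n) < config.readthrough_fraction
    lengths = np.maximum(
        config.min_read_length,
        rng.normal(config.read_length, config.read_length_sd, n).astype(int),
    )
    overshoot = rng.integers(1, 16, n)
    del_rate = np.where(is_rt, config.del_rate_readthrough,
                        config.del_rate_background)
    has_del = rng.random(n) < del_rate
    barcodes = _barcodes(rng, n, config.barcode_length)
    if config.pcr_duplication_rate > 0:
        copies = rng.geometric(1.0 - config.pcr_duplication_rate, n)
    else:
        copies = np.ones(n, dtype=int)

    records: List[MappedCdna] = []
    window = 25
    for i in range(n):
        site = truth.sites[site_idx[i]]
        chrom_len = len(genome[site.chrom])
        L = int(lengths[i])
        d = site.position
        if site.strand == "+":
            start = d - int(overshoot[i]) if is_rt[i] else d + config.truncation_offset
            start = max(0, start)
            end = min(chrom_len, start + L)
        else:
            end = d + int(overshoot[i]) + 1 if is_rt[i] else d + 1 - config.truncation_offset
            end = min(chrom_len, end)
            start = max(0, end - L)
        deletions: Tuple[int, ...] = ()
        if has_del[i]:
            deletions = (_place_deletion(rng, site, is_rt[i], start, end, window,
                                         config, run_end_at[site.chrom],
                                         run_len_at[site.chrom]),)
        rec = MappedCdna(site.chrom, site.strand, start, end, barcodes[i], deletions)
        records.extend([rec] * int(copies[i]))
    return records


def _place_deletion(rng, site, is_rt, start, end, window, config,
                    run_end_at, run_len_at) -> int:
    """Pick the genomic position of one deletion within the read's 5' window."""
    if site.strand == "+":
        cand = np.arange(start, min(end, start + window))
    else:
        cand = np.arange(max(start, end - window), end)
    w = np.ones(len(cand), dtype=float)
    if is_rt:
        in_run = run_len_at[cand] >= 3
        w[in_run] *= config.homopolymer_del_bias
        near_site = np.abs(cand - site.position) <= 2
        w[near_site] *= 5.0
    pos = int(rng.choice(cand, p=w / w.sum()))
    # Aligner ambiguity: shift deletions inside homonucleotide runs to the
    # run's highest genomic coordinate (Novoalign-style, strand-independent
    # in genome space).
    if run_len_at[pos] >= 2:
        pos = min(int(run_end_at[pos]), end - 1)
    return pos


def simulate_library(config: SimulationConfig):
    """Convenience wrapper: genome + segments + truth + cDNA records."""
    genome, segments, truth = generate_genome(config)
    records = simulate_cdnas(genome, truth, config)
    return genome, segments, truth, records


def background_library_config(config: SimulationConfig) -> SimulationConfig:
    """Config for an mRNA-Seq-like background library (no read-through)."""
    return replace(config, readthrough_fraction=0.0)


def readthrough_library_config(config: SimulationConfig) -> SimulationConfig:
    """Config for a CLIP-like pure read-through library."""
    return replace(config, readthrough_fraction=1.0)
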