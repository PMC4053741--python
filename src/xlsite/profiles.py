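"""Motif occurrence, enrichment and composition profiles around cross-link sites.

All offsets are in transcript orientation with the cross-link site at 0:
negative offsets are transcript-upstream (5') of the site, positive offsets
downstream. A motif "at offset o" means its transcript 5' base sits o
nucleotides from the site; minus-strand sites are evaluated on the reverse
complement with offsets mirrored. Unstranded sites (intergenic regions) are
evaluated on both strands with half weight each.

The background model re-positions each site uniformly within its containing
annotated genomic segment (same strand), repeats the draw ``n`` times and
averages the occurrence profile, following the segment-randomisation scheme
used for CLIP/iCLIP backgrounds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._seq import BASES, Genome, as_genome, revcomp, sense_indicators
from .records import CrossLinkSite

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 30
BACKGROUND_WINDOW = 50
YCAY_VARIANTS = ("TCAT", "TCAC", "CCAT", "CCAC")


@dataclass
class OffsetProfile:
    """Per-offset weighted site counts in a window around cross-link sites."""

    offsets: np.ndarray
    values: np.ndarray
    n_sites: float
    motif: Optional[str] = None
    kind: str = "occurrence"

    @property
    def frequencies(self) -> np.ndarray:
        """Per-site occurrence frequency at each offset."""
        return self.values / self.n_sites

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.offsets, name="offset"),
                         name=self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


@dataclass
class CompositionProfile:
    """Per-offset base frequencies around cross-link sites (rows A,C,G,T)."""

    offsets: np.ndarray
    counts: np.ndarray           # shape (4, n_offsets)
    valid: np.ndarray            # per-offset number of contributing sites
    bases: str = BASES

    @property
    def frequencies(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.valid > 0, self.counts / self.valid, np.nan)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies.T, columns=list(self.bases))
        df.insert(0, "offset", self.offsets)
        return df


@dataclass
class BackgroundModel:
    """Mean randomized-background occurrence profile."""

    offsets: np.ndarray
    mean: np.ndarray
    n_randomizations: int
    window: int
    n_sites: float
    motif: str


@dataclass
class EnrichmentProfile:
    """Observed/background occurrence ratio with a +/-2 smoothed track."""

    offsets: np.ndarray
    ratio: np.ndarray
    smoothed: np.ndarray

    def threshold_region(self, threshold: float = 2.0) -> Optional[Tuple[int, int]]:
        """Longest contiguous offset run with smoothed enrichment >= threshold.

        Returns inclusive (start_offset, end_offset), or None if no offset
        crosses the threshold.
        """
        ok = np.isfinite(self.smoothed) & (self.smoothed >= threshold)
        best: Optional[Tuple[int, int]] = None
        i = 0
        while i < len(ok):
            if ok[i]:
                j = i
                while j + 1 < len(ok) and ok[j + 1]:
                    j += 1
                if best is None or j - i > best[1] - best[0]:
                    best = (i, j)
                i = j + 1
            else:
                i += 1
        if best is None:
            return None
        return int(self.offsets[best[0]]), int(self.offsets[best[1]])


def _expand_sites(sites: Sequence[CrossLinkSite]) -> List[Tuple[str, str, int, float]]:
    """Unstranded sites become two half-weight stranded sites."""
    out = []
    for s in sites:
        w = 1.0  # profiles count sites, not cDNAs
        if s.strand in ("+", "-"):
            out.append((s.chrom, s.strand, s.position, w))
        else:
            out.append((s.chrom, "+", s.position, 0.5 * w))
            out.append((s.chrom, "-", s.position, 0.5 * w))
    return out


class _IndicatorCache:
    """Per-(chrom, motif) motif-start indicator arrays for both senses."""

    def __init__(self, genome: Dict[str, str]):
        self.genome = genome
        self._cache: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}

    def get(self, chrom: str, motif: str) -> Tuple[np.ndarray, np.ndarray]:
        key = (chrom, motif)
        if key not in self._cache:
            self._cache[key] = sense_indicators(self.genome[chrom], motif)
        return self._cache[key]


def _padded_slice(arr: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """arr[lo:hi] with zero padding outside [0, len(arr))."""
    out = np.zeros(hi - lo, dtype=float)
    a, b = max(lo, 0), min(hi, len(arr))
    if a < b:
        out[a - lo : b - lo] = arr[a:b]
    return out


def _site_indicator_window(cache: _IndicatorCache, chrom: str, strand: str,
                           pos: int, motif: str, window: int) -> np.ndarray:
    """Motif-start indicators at transcript offsets -window..window of a site."""
    plus, minus = cache.get(chrom, motif)
    if strand == "+":
        return _padded_slice(plus, pos - window, pos + window + 1)
    # Minus strand: offset o corresponds to genomic position pos - o.
    return _padded_slice(minus, pos - window, pos + window + 1)[::-1]


def motif_occurrence(sites: Sequence[CrossLinkSite], motif: str,
                     genome: Union[str, Genome],
                     window: int = DEFAULT_WINDOW) -> OffsetProfile:
    """Count motif starts at each transcript offset around the sites.

    Overlapping instances are all counted. Offsets whose window extends past
    the chromosome contribute nothing for the affected sites.
    """
    genome = as_genome(genome)
    cache = _IndicatorCache(genome)
    total = np.zeros(2 * window + 1)
    n_sites = 0.0
    for chrom, strand, pos, w in _expand_sites(sites):
        total += w * _site_indicator_window(cache, chrom, strand, pos, motif, window)
        n_sites += w
    return OffsetProfile(np.arange(-window, window + 1), total, n_sites, motif,
                         "occurrence")


def closest_motif(sites: Sequence[CrossLinkSite], motif: str,
                  genome: Union[str, Genome],
                  window: int = DEFAULT_WINDOW) -> OffsetProfile:
    """Record, per site, only the motif start closest to the site.

    Distance is |start offset|; exact ties pick the upstream (negative)
    offset. Sites without an instance in the window contribute nothing.
    """
    genome = as_genome(genome)
    cache = _IndicatorCache(genome)
    offsets = np.arange(-window, window + 1)
    total = np.zeros(2 * window + 1)
    n_sites = 0.0
    for chrom, strand, pos, w in _expand_sites(sites):
        v = _site_indicator_window(cache, chrom, strand, pos, motif, window)
        n_sites += w
        hit = offsets[v > 0]
        if len(hit):
            o = min(hit, key=lambda o: (abs(o), o))
            total[o + window] += w
    return OffsetProfile(offsets, total, n_sites, motif, "closest")


def assign_segments(sites: Sequence[Tuple[str, str, int, float]],
                    segments: pd.DataFrame) -> Tuple[list, int]:
    """Attach the containing segment to each expanded site.

    Returns (list of (chrom, strand, pos, weight, seg_start, seg_len),
    number of sites outside every segment).
    """
    by_chrom: Dict[str, pd.DataFrame] = {
        str(c): g.sort_values("start") for c, g in segments.groupby("chrom")
    }
    assigned = []
    n_outside = 0
    for chrom, strand, pos, w in sites:
        seg = by_chrom.get(chrom)
        hit = None
        if seg is not None:
            starts = seg["start"].to_numpy()
            ends = seg["end"].to_numpy()
            i = np.searchsorted(starts, pos, side="right") - 1
            if i >= 0 and pos < ends[i]:
                hit = (int(starts[i]), int(ends[i] - starts[i]))
        if hit is None:
            n_outside += 1
            continue
        assigned.append((chrom, strand, pos, w, hit[0], hit[1]))
    if n_outside:
        logger.warning("%d sites fall outside every segment; excluded from "
                       "background", n_outside)
    return assigned, n_outside


def randomized_background(sites: Sequence[CrossLinkSite], segments: pd.DataFrame,
                          motif: str, genome: Union[str, Genome],
                          n: int = 100, window: int = BACKGROUND_WINDOW,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None) -> BackgroundModel:
    """Segment-randomized background occurrence model.

    Each randomization re-positions every site uniformly within its
    containing segment (keeping the strand) and recomputes the occurrence
    profile; the background is the per-offset mean over ``n`` randomizations.
    The original position may be redrawn.
    """
    genome = as_genome(genome)
    cache = _IndicatorCache(genome)
    if rng is None:
        rng = np.random.default_rng(seed)
    assigned, _ = assign_segments(_expand_sites(sites), segments)
    total = np.zeros(2 * window + 1)
    n_sites = sum(a[3] for a in assigned)
    for _ in range(n):
        for chrom, strand, _pos, w, seg_start, seg_len in assigned:
            newpos = seg_start + int(rng.integers(seg_len))
            total += w * _site_indicator_window(cache, chrom, strand, newpos,
                                                motif, window)
    return BackgroundModel(np.arange(-window, window + 1), total / n, n, window,
                           n_sites, motif)


def _smooth(x: np.ndarray, halfwidth: int = 2) -> np.ndarray:
    """Mean over offsets -halfwidth..+halfwidth, shrinking at the edges."""
    out = np.empty_like(x, dtype=float)
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - halfwidth), min(n, i + halfwidth + 1)
        seg = x[lo:hi]
        ok = np.isfinite(seg)
        out[i] = seg[ok].mean() if ok.any() else np.nan
    return out


def enrichment(observed: OffsetProfile, background: BackgroundModel,
               smooth_halfwidth: int = 2) -> EnrichmentProfile:
    """Observed/background occurrence ratio per offset.

    Profiles are aligned on their common offsets. Offsets with zero
    background are reported as missing (NaN). The smoothed track averages
    the ratio over -2..+2 around each offset to damp fluctuations before
    thresholding the enriched region.
    """
    common = np.intersect1d(observed.offsets, background.offsets)
    if len(common) == 0:
        raise ValueError("profiles share no offsets")
    obs = observed.values[np.isin(observed.offsets, common)]
    bg = background.mean[np.isin(background.offsets, common)]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(bg > 0, obs / np.where(bg > 0, bg, 1.0), np.nan)
    return EnrichmentProfile(common, ratio, _smooth(ratio, smooth_halfwidth))


def nucleotide_composition(sites: Sequence[CrossLinkSite],
                           genome: Union[str, Genome],
                           window: int = DEFAULT_WINDOW) -> CompositionProfile:
    """Per-offset base frequencies (transcript orientation) around sites."""
    genome = as_genome(genome)
    k = 2 * window + 1
    counts = np.zeros((4, k))
    valid = np.zeros(k)
    base_index = {b: i for i, b in enumerate(BASES)}
    for chrom, strand, pos, w in _expand_sites(sites):
        seq = genome[chrom]
        lo, hi = pos - window, pos + window + 1
        a, b = max(lo, 0), min(hi, len(seq))
        if a >= b:
            continue
        sub = seq[a:b]
        offs = np.arange(a - pos, b - pos)
        if strand == "-":
            sub = revcomp(sub)
            offs = -offs[::-1]
        for o, ch in zip(offs, sub):
            i = base_index.get(ch)
            if i is not None:
                counts[i, o + window] += w
                valid[o + window] += w
    return CompositionProfile(np.arange(-window, window + 1), counts, valid)


def motif_variant_proportions(sites: Sequence[CrossLinkSite],
                              genome: Union[str, Genome],
                              variants: Sequence[str] = YCAY_VARIANTS,
                              near_range: Tuple[int, int] = (0, 2),
                              wide_range: Tuple[int, int] = (-20, 20)) -> pd.DataFrame:
    """Proportion of each motif variant among instances starting in a range.

    ``near_range`` and ``wide_range`` are inclusive offset intervals; for
    each, the per-variant instance counts across all sites are normalised to
    proportions. Comparing the near and wide columns shows how the variant
    composition changes right at the cross-link site.
    """
    for name, (lo, hi) in (("near_range", near_range), ("wide_range", wide_range)):
        if lo > hi:
            raise ValueError(f"{name} is empty: {(lo, hi)}")
    window = max(abs(v) for rng_ in (near_range, wide_range) for v in rng_)
    profiles = {v: motif_occurrence(sites, v, genome, window) for v in variants}
    out = {}
    for label, (lo, hi) in (("near", near_range), ("wide", wide_range)):
        sel = (np.arange(-window, window + 1) >= lo) & \
              (np.arange(-window, window + 1) <= hi)
        counts = np.array([profiles[v].values[sel].sum() for v in variants])
        tot = counts.sum()
        if tot == 0:
            logger.warning("no variant instances in %s range %s", label, (lo, hi))
            out[label] = np.full(len(variants), np.nan)
        else:
            out[label] = counts / tot
    return pd.DataFrame(out, index=pd.Index(variants, name="variant"))
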