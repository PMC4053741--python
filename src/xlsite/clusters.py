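"""YCAY cluster scoring, segmentation and score/count correlation.

The YCAY score of a genomic position is the number of motif instances
completely contained in the 41-nt window centred on it (20 nt each side).
The score track is segmented into clusters by a peak-joining rule:

1. find the local maxima of the track;
2. a zero-score valley between maxima terminates clusters where the score
   reaches 0;
3. otherwise compare the valley minimum with 0.9-fold of the smaller of the
   two flanking maxima;
4. if the minimum is smaller, split at the middle of the minimal-value run;
5. if not, join the two peaks into one cluster and continue with the next
   maximum from step 2.

Each cluster's score is the maximum track score inside it. Clusters
containing at least one cross-link site enter a Spearman rank correlation
between cluster score and the highest cDNA count inside the cluster.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats

from ._seq import Genome, as_genome, motif_starts, revcomp_iupac
from .records import CrossLinkSite

logger = logging.getLogger(__name__)

SCORE_FLANK = 20          # 41-nt sliding window
VALLEY_FACTOR = 0.9


@dataclass
class ScoreTrack:
    """Per-position motif-cluster scores over ``[start, start + len(scores))``."""

    chrom: str
    start: int
    scores: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.scores)


@dataclass(frozen=True)
class MotifCluster:
    chrom: str
    start: int
    end: int
    cluster_score: int
    max_cdna_count: Optional[int] = None
    n_sites: int = 0


class SpearmanResult(NamedTuple):
    rho: float
    pvalue: float
    n_clusters: int


class InsufficientClustersError(ValueError):
    pass


def ycay_score(seq: str, motif: str = "YCAY", flank: int = SCORE_FLANK,
               both_strands: bool = False) -> np.ndarray:
    """Score every position of ``seq``.

    A motif instance starting at q counts toward position p iff it lies
    entirely within [p - flank, p + flank]; windows are truncated at the
    sequence boundaries. With ``both_strands`` instances of the motif on the
    reverse complement are counted too (by their genomic span), which is
    appropriate when ``seq`` is genomic rather than a transcript sense
    sequence.
    """
    n, m = len(seq), len(motif)
    if n < m:
        return np.zeros(n, dtype=int)
    starts = motif_starts(seq, motif)
    if both_strands:
        starts = starts | motif_starts(seq, revcomp_iupac(motif))
    starts = starts[: n - m + 1]
    csum = np.concatenate(([0], np.cumsum(starts)))
    p = np.arange(n)
    lo = np.clip(p - flank, 0, n - m)            # lowest candidate start
    hi = np.clip(p + flank - m + 1, -1, n - m)   # highest start fully contained
    score = np.where(hi >= lo, csum[np.clip(hi, 0, None) + 1] - csum[lo], 0)
    return score.astype(int)


def score_track(genome: Union[str, Genome], chrom: str, start: int = 0,
                end: Optional[int] = None, motif: str = "YCAY",
                flank: int = SCORE_FLANK, both_strands: bool = True) -> ScoreTrack:
    """Score a genomic region, using flanking sequence context when available.

    Motif instances on both strands count by default since the region is
    genomic (transcripts may lie on either strand); pass
    ``both_strands=False`` to score a known sense strand only. Positions
    within ``flank`` of a chromosome end use the truncated window (logged);
    inside the chromosome the full 41-nt window applies even at the region
    edges.
    """
    genome = as_genome(genome)
    seq = genome[chrom]
    if end is None:
        end = len(seq)
    pad = flank + len(motif)
    lo = max(0, start - pad)
    hi = min(len(seq), end + pad)
    if start < flank or end > len(seq) - flank:
        logger.info("score windows truncated at the %s boundary", chrom)
    scores = ycay_score(seq[lo:hi], motif, flank, both_strands)[start - lo : end - lo]
    return ScoreTrack(chrom, start, scores)


def _local_maxima(s: np.ndarray, i0: int, i1: int) -> List[tuple]:
    """(anchor, value) for each local maximum in the island [i0, i1).

    A maximal run of equal values flanked by strictly smaller values (the
    island boundary counts as smaller) is one maximum anchored at its
    midpoint.
    """
    res = []
    i = i0
    while i < i1:
        j = i
        while j + 1 < i1 and s[j + 1] == s[i]:
            j += 1
        left = s[i - 1] if i > i0 else -np.inf
        right = s[j + 1] if j + 1 < i1 else -np.inf
        if s[i] > left and s[i] > right:
            res.append(((i + j) // 2, float(s[i])))
        i = j + 1
    return res


def _segment_island(s: np.ndarray, i0: int, i1: int) -> List[tuple]:
    """Split one positive-score island into cluster intervals [a, b)."""
    maxima = _local_maxima(s, i0, i1)
    bounds = [i0]
    cur_anchor, cur_val = maxima[0]
    for a2, v2 in maxima[1:]:
        between = s[cur_anchor + 1 : a2]
        vmin = float(between.min())
        if vmin < VALLEY_FACTOR * min(cur_val, v2):
            # Leftmost maximal run of the minimum value between the anchors.
            idx = np.flatnonzero(between == vmin) + cur_anchor + 1
            k = 0
            while k + 1 < len(idx) and idx[k + 1] == idx[k] + 1:
                k += 1
            run_len = k + 1
            mid = int(idx[0]) + (run_len - 1) // 2
            bounds.append(mid + 1)
            cur_anchor, cur_val = a2, v2
        else:
            # Join; the merged peak is the larger maximum (left wins ties).
            if v2 > cur_val:
                cur_anchor, cur_val = a2, v2
    bounds.append(i1)
    return [(bounds[t], bounds[t + 1]) for t in range(len(bounds) - 1)]


def find_clusters(track: ScoreTrack) -> List[MotifCluster]:
    """Segment a score track into disjoint clusters covering all score > 0."""
    s = np.asarray(track.scores)
    clusters: List[MotifCluster] = []
    n = len(s)
    i = 0
    while i < n:
        if s[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and s[j + 1] > 0:
            j += 1
        for a, b in _segment_island(s, i, j + 1):
            clusters.append(
                MotifCluster(track.chrom, track.start + a, track.start + b,
                             int(s[a:b].max()))
            )
        i = j + 1
    return clusters


def assign_counts(clusters: Sequence[MotifCluster],
                  sites: Sequence[CrossLinkSite]) -> List[MotifCluster]:
    """Attach the highest site cDNA count and site tally to each cluster.

    Clusters are unstranded sequence features: sites of either strand on the
    cluster's chromosome are counted.
    """
    out = []
    for c in clusters:
        inside = [s for s in sites
                  if s.chrom == c.chrom and c.start <= s.position < c.end]
        out.append(replace(
            c,
            max_cdna_count=max((s.count for s in inside), default=None),
            n_sites=len(inside),
        ))
    return out


def correlate(clusters: Sequence[MotifCluster],
              sites: Optional[Sequence[CrossLinkSite]] = None,
              min_clusters: int = 3) -> SpearmanResult:
    """Spearman correlation of cluster score vs highest cDNA count.

    Only clusters containing at least one cross-link site qualify. The
    p-value uses the asymptotic two-sided t approximation with average ranks
    for ties. Zero variance in either variable yields an undefined (NaN)
    correlation.
    """
    if sites is not None:
        clusters = assign_counts(clusters, sites)
    qual = [c for c in clusters if c.n_sites >= 1 and c.max_cdna_count is not None]
    if len(qual) < min_clusters:
        raise InsufficientClustersError(
            f"only {len(qual)} clusters contain a cross-link site; "
            f"need >= {min_clusters}"
        )
    x = np.array([c.cluster_score for c in qual], dtype=float)
    y = np.array([c.max_cdna_count for c in qual], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in scores or counts: correlation undefined")
        return SpearmanResult(float("nan"), float("nan"), len(qual))
    res = stats.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue), len(qual))
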