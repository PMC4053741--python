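"""Two-component mixture model of read-through and truncated cDNAs.

An iCLIP library is a mixture of read-through cDNAs (reverse transcription
passed the cross-link, deletion rate p_RT) and truncated cDNAs (background
deletion rate p_BG). With p_iCLIP the observed deletion proportion,

    p_iCLIP = f * p_RT + (1 - f) * p_BG    =>    f = (p_iCLIP - p_BG) / (p_RT - p_BG)

gives the read-through fraction f of the whole library. The share of
deletion-bearing cDNAs that are read-through is the Bayes fraction

    k = f * p_RT / (f * p_RT + (1 - f) * p_BG)

and the read-through share among deletion-free cDNAs follows by removing the
deletion-bearing cDNAs from the read-through pool:

    (N * f - n_del * k) / (N - n_del)

p_RT is taken from a pure read-through library (CLIP) and p_BG from mRNA-Seq,
assuming the reverse-transcription and sequencing protocol (hence the
deletion process) is shared. Proportions are carried as exact rationals so
count-table reproductions are bit-stable; deletion proportions use a fixed
read-relative window (default 25 nt) to neutralise read-length differences
between libraries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence, Tuple, Union

from .ingest import MIN_LIBRARY_SIZE, deletion_proportion, require_min_library
from .records import MappedCdna

logger = logging.getLogger(__name__)

Proportion = Union[float, Fraction, Tuple[int, int]]


class DegenerateMixtureError(ValueError):
    """p_RT equals p_BG: the mixture fraction is unidentifiable."""


def _as_fraction(x: Proportion) -> Fraction:
    if isinstance(x, tuple):
        return Fraction(x[0], x[1])
    return Fraction(x)


def _check_proportion(name: str, x: Fraction) -> None:
    if not 0 <= x <= 1:
        raise ValueError(f"{name} must be in [0, 1], got {float(x)}")


def _clip01(x: Fraction, what: str) -> Fraction:
    if x < 0 or x > 1:
        logger.warning("%s = %.4f outside [0, 1]; inputs violate the mixture "
                       "ordering, clipping", what, float(x))
        return Fraction(min(max(x, 0), 1))
    return x


def estimate_f(p_iclip: Proportion, p_rt: Proportion, p_bg: Proportion) -> float:
    """Read-through fraction of the total library.

    Solves the two-component mixture for f. Inputs may be floats, Fractions
    or ``(numerator, denominator)`` count pairs. Values outside [0, 1]
    (inputs violating p_BG <= p_iCLIP <= p_RT) are clipped with a warning.
    """
    pi, pr, pb = (_as_fraction(x) for x in (p_iclip, p_rt, p_bg))
    for name, x in (("p_iclip", pi), ("p_rt", pr), ("p_bg", pb)):
        _check_proportion(name, x)
    if pr == pb:
        raise DegenerateMixtureError("p_rt == p_bg: mixture is unidentifiable")
    f = (pi - pb) / (pr - pb)
    return float(_clip01(f, "f"))


def estimate_k(f: Proportion, p_rt: Proportion, p_bg: Proportion) -> float:
    """Share of deletion-bearing cDNAs that are read-through (Bayes fraction)."""
    f_, pr, pb = (_as_fraction(x) for x in (f, p_rt, p_bg))
    _check_proportion("f", f_)
    denom = f_ * pr + (1 - f_) * pb
    if denom == 0:
        raise DegenerateMixtureError("no deletion-bearing cDNAs expected: k undefined")
    return float(f_ * pr / denom)


@dataclass(frozen=True)
class NoDeletionSplit:
    readthrough: float
    truncated: float


def truncated_fraction_among_no_del(total: int, n_del: int,
                                    f: Proportion, k: Proportion) -> NoDeletionSplit:
    """Read-through / truncated split among the deletion-free cDNAs.

    ``total`` is the unique-cDNA count of the library and ``n_del`` the number
    of unique cDNAs carrying a deletion anywhere in the read.
    """
    if not 0 <= n_del < total:
        raise ValueError("need 0 <= n_del < total")
    f_, k_ = _as_fraction(f), _as_fraction(k)
    rt = _clip01((total * f_ - n_del * k_) / (total - n_del),
                 "read-through share among deletion-free cDNAs")
    return NoDeletionSplit(float(rt), float(1 - rt))


@dataclass(frozen=True)
class LibraryDeletionStats:
    """Deletion accounting of one collapsed cDNA library."""

    total_unique_cdnas: int
    cdnas_with_any_deletion: int
    cdnas_with_deletion_in_window: int
    window_nt: int = 25

    def __post_init__(self) -> None:
        if not (0 <= self.cdnas_with_deletion_in_window
                <= self.cdnas_with_any_deletion
                <= self.total_unique_cdnas):
            raise ValueError("need windowed <= any <= total")

    @classmethod
    def from_records(cls, records: Sequence[MappedCdna], window_nt: int = 25,
                     min_library_size: int = MIN_LIBRARY_SIZE) -> "LibraryDeletionStats":
        require_min_library(records, min_library_size)
        any_prop = deletion_proportion(records, window_nt=10**9)
        win_prop = deletion_proportion(records, window_nt=window_nt)
        n = len(records)
        return cls(n, int(any_prop * n), int(win_prop * n), window_nt)

    @property
    def windowed_proportion(self) -> Fraction:
        return Fraction(self.cdnas_with_deletion_in_window, self.total_unique_cdnas)

    @property
    def any_proportion(self) -> Fraction:
        return Fraction(self.cdnas_with_any_deletion, self.total_unique_cdnas)

    @property
    def windowed_percent_printed(self) -> str:
        return format_percent(self.windowed_proportion)

    @property
    def any_percent_printed(self) -> str:
        return format_percent(self.any_proportion)


@dataclass(frozen=True)
class MixtureEstimate:
    """Joint result of the three closed-form mixture estimates."""

    f: float
    k: float
    readthrough_no_del: float
    truncated_no_del: float

    @classmethod
    def from_stats(cls, iclip: LibraryDeletionStats, readthrough: LibraryDeletionStats,
                   background: LibraryDeletionStats) -> "MixtureEstimate":
        """Estimate from windowed deletion stats of iCLIP, CLIP and mRNA-Seq."""
        pi = iclip.windowed_proportion
        pr = readthrough.windowed_proportion
        pb = background.windowed_proportion
        f = estimate_f(pi, pr, pb)
        k = estimate_k(f, pr, pb)
        split = truncated_fraction_among_no_del(
            iclip.total_unique_cdnas, iclip.cdnas_with_any_deletion, f, k
        )
        return cls(f, k, split.readthrough, split.truncated)


def format_percent(x: Proportion) -> str:
    """Render a proportion the way the deletion tables print it.

    One decimal below 10% (0.4%, 2.3%, 3.7%), whole percent above (11%).
    """
    pct = float(_as_fraction(x)) * 100.0
    if round(pct) >= 10:
        return f"{pct:.0f}%"
    return f"{pct:.1f}%"
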