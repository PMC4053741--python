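"""Core record types shared across the pipeline.

All genomic coordinates are 0-based half-open. A mapped cDNA occupies
``[start, end)`` on its chromosome; single-nucleotide deletion positions are
genomic coordinates inside that interval. Cross-link sites are
single-nucleotide positions with the strand of the transcript they belong to.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import pandas as pd

STRANDS = ("+", "-")

TRUNCATION = "truncation"
DELETION = "deletion"


@dataclass(frozen=True, slots=True)
class MappedCdna:
    """One uniquely aligned cDNA.

    Parameters
    ----------
    chrom, strand, start, end:
        Location of the alignment, 0-based half-open.
    barcode:
        Random barcode (UMI) of the reverse-transcription primer, or ``None``
        for barcode-free libraries (CLIP, mRNA-Seq).
    deletions:
        Genomic positions deleted in the read, sorted ascending.
    """

    chrom: str
    strand: str
    start: int
    end: int
    barcode: Optional[str] = None
    deletions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        dels = tuple(sorted(int(d) for d in self.deletions))
        object.__setattr__(self, "deletions", dels)
        if dels and not (self.start <= dels[0] and dels[-1] < self.end):
            raise ValueError(
                f"deletions {dels} outside read interval [{self.start}, {self.end})"
            )

    @property
    def read_length(self) -> int:
        return self.end - self.start

    @property
    def start5(self) -> int:
        """Genomic coordinate of the read's 5' end (read orientation).

        This is the grouping key for duplicate collapsing: ``start`` on the
        plus strand, ``end`` on the minus strand.
        """
        return self.start if self.strand == "+" else self.end

    def deletion_offsets(self) -> Tuple[int, ...]:
        """Read-relative (5'->3') offsets of the deletions, starting at 0."""
        if self.strand == "+":
            return tuple(d - self.start for d in self.deletions)
        return tuple(self.end - 1 - d for d in self.deletions)


@dataclass(frozen=True, slots=True)
class CrossLinkSite:
    """A single-nucleotide cross-link site with its supporting cDNA count."""

    chrom: str
    strand: str
    position: int
    count: int = 1
    source: str = TRUNCATION

    def __post_init__(self) -> None:
        if self.strand not in STRANDS + (".",):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.source not in (TRUNCATION, DELETION):
            raise ValueError(f"source must be truncation|deletion, got {self.source!r}")


@dataclass(frozen=True, slots=True)
class RedefinedSite:
    """A deletion site after homopolymer re-definition.

    ``position`` is the (possibly re-centred) site; ``original_position``
    preserves the aligner-assigned coordinate.
    """

    chrom: str
    strand: str
    position: int
    count: int
    original_position: int
    redefined: bool
    source: str = DELETION

    def __post_init__(self) -> None:
        if abs(self.position - self.original_position) > 2:
            raise ValueError("re-defined site may move at most 2 nt")


def sites_to_frame(sites: Iterable[CrossLinkSite]) -> pd.DataFrame:
    rows = [(s.chrom, s.strand, s.position, s.count, s.source) for s in sites]
    return pd.DataFrame(rows, columns=["chrom", "strand", "position", "count", "source"])


def frame_to_sites(frame: pd.DataFrame) -> list[CrossLinkSite]:
    return [
        CrossLinkSite(r.chrom, r.strand, int(r.position), int(r.count), r.source)
        for r in frame.itertuples()
    ]


def cdnas_to_frame(records: Iterable[MappedCdna]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.strand, r.start, r.end, r.barcode, r.deletions) for r in records
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", "barcode", "deletions"]
    )
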