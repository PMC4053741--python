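"""Derive truncation and deletion events from mapped cDNA records.

The truncation site of a cDNA is the nucleotide 5'-adjacent to the read in
transcript orientation (the base that reverse transcription stopped at but did
not copy): ``start - 1`` on the plus strand, ``end`` on the minus strand.

Duplicate collapsing follows the iCLIP random-barcode rules: cDNAs sharing a
barcode and the same 5' starting position are one molecule; among their
deletions the most frequent is retained, ties resolved toward the read 5' end.
Barcode-free libraries (CLIP, mRNA-Seq) are joined purely by starting
position, as if all reads carried the same barcode.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .records import DELETION, TRUNCATION, CrossLinkSite, MappedCdna

logger = logging.getLogger(__name__)

#: Libraries below this unique-cDNA count are refused by default.
MIN_LIBRARY_SIZE = 10_000


class LibraryTooSmallError(ValueError):
    pass


def derive_truncation_site(cdna: MappedCdna) -> Optional[CrossLinkSite]:
    """Cross-link site implied by a cDNA's truncation.

    Returns ``None`` (with a warning) when the site would fall off the
    chromosome start; callers tally skipped records.
    """
    if cdna.strand == "+":
        pos = cdna.start - 1
        if pos < 0:
            logger.warning("truncation site off chromosome start for %s", cdna)
            return None
    else:
        pos = cdna.end
    return CrossLinkSite(cdna.chrom, cdna.strand, pos, 1, TRUNCATION)


def select_deletion(cdna: MappedCdna) -> int:
    """The deletion closest to the beginning (5' end) of the read."""
    if not cdna.deletions:
        raise ValueError("cDNA has no deletions")
    return min(cdna.deletions) if cdna.strand == "+" else max(cdna.deletions)


def _collapse(records: Sequence[MappedCdna], use_barcode: bool) -> List[MappedCdna]:
    if not records:
        return []
    rows = []
    for r in records:
        sel = select_deletion(r) if r.deletions else -1
        rows.append((r.chrom, r.strand, r.start5, r.barcode if use_barcode else "",
                     r.start, r.end, sel))
    df = pd.DataFrame(
        rows, columns=["chrom", "strand", "start5", "barcode", "start", "end", "sel"]
    )
    df["has_del"] = df["sel"] >= 0
    keys = ["chrom", "strand", "start5", "barcode"]
    grp = df.groupby(keys, sort=True, dropna=False)
    agg = grp.agg(
        n=("sel", "size"),
        n_del=("has_del", "sum"),
        start=("start", "min"),
        end=("end", "max"),
    ).reset_index()
    # Majority vote on deletion presence; ties favour deletion-free (the
    # conservative choice for truncation analysis).
    agg["keep_del"] = 2 * agg["n_del"] > agg["n"]

    # For groups that keep a deletion: most frequent deletion position,
    # frequency ties broken by proximity to the read 5' end.
    sub = df[df["has_del"]].copy()
    chosen = {}
    if len(sub):
        counts = (
            sub.groupby(keys + ["sel"], dropna=False)
            .size()
            .reset_index(name="freq")
        )
        counts["tiebreak"] = counts["sel"].where(counts["strand"] == "+", -counts["sel"])
        counts = counts.sort_values(
            keys + ["freq", "tiebreak"], ascending=[True] * len(keys) + [False, True]
        )
        first = counts.drop_duplicates(subset=keys, keep="first")
        chosen = {
            (r.chrom, r.strand, r.start5, r.barcode): int(r.sel)
            for r in first.itertuples()
        }

    out = []
    for r in agg.itertuples():
        dels: tuple = ()
        if r.keep_del:
            dels = (chosen[(r.chrom, r.strand, r.start5, r.barcode)],)
        out.append(
            MappedCdna(
                r.chrom, r.strand, int(r.start), int(r.end),
                r.barcode if use_barcode and r.barcode != "" else None, dels,
            )
        )
    n_merged = len(records) - len(out)
    if n_merged:
        logger.info("collapsed %d duplicate records into %d unique cDNAs",
                    len(records), len(out))
    return out


def collapse_barcoded(records: Sequence[MappedCdna]) -> List[MappedCdna]:
    """Collapse PCR duplicates of a barcoded (iCLIP) library.

    One record is kept per (barcode, chrom, strand, 5' start); within a group
    the retained deletion is the most frequent one, frequency ties resolved
    toward the read 5' end, and groups mixing deletion-free and
    deletion-bearing reads resolve by majority with ties going to
    deletion-free.
    """
    return _collapse(records, use_barcode=True)


def join_no_barcode(records: Sequence[MappedCdna]) -> List[MappedCdna]:
    """Join a barcode-free library (CLIP, mRNA-Seq) by starting position.

    Equivalent to allocating the same random barcode to every read: one unique
    cDNA per (chrom, strand, 5' start), deletions merged as in
    :func:`collapse_barcoded`.
    """
    return _collapse(records, use_barcode=False)


def collapse_auto(records: Sequence[MappedCdna]) -> List[MappedCdna]:
    """Collapse with barcodes when the library carries them, else join by
    position."""
    barcoded = any(r.barcode is not None for r in records)
    return _collapse(records, use_barcode=barcoded)


def require_min_library(records: Sequence[MappedCdna],
                        min_library_size: int = MIN_LIBRARY_SIZE) -> None:
    if len(records) < min_library_size:
        raise LibraryTooSmallError(
            f"library has {len(records)} unique cDNAs; "
            f"analyses require >= {min_library_size} (override min_library_size to force)"
        )


def deletion_proportion(records: Sequence[MappedCdna], window_nt: int = 25,
                        min_library_size: int = 0) -> Fraction:
    """Fraction of unique cDNAs with a deletion in the first ``window_nt`` nt.

    ``records`` should already be collapsed to unique cDNAs. Offsets are
    read-relative from the 5' end; a window larger than every read length
    reproduces the unwindowed deletion proportion. Returned as an exact
    :class:`fractions.Fraction`.
    """
    if window_nt <= 0:
        raise ValueError("window_nt must be positive")
    if min_library_size:
        require_min_library(records, min_library_size)
    if not records:
        raise ValueError("empty library")
    n_hit = sum(
        1 for r in records if any(o < window_nt for o in r.deletion_offsets())
    )
    return Fraction(n_hit, len(records))


def truncation_sites(records: Sequence[MappedCdna],
                     include_deleted: bool = False) -> List[CrossLinkSite]:
    """Aggregate truncation-derived cross-link sites with cDNA counts.

    By default only deletion-free cDNAs are used, since deletion-bearing
    cDNAs are predominantly read-through and their 3' ends do not mark
    cross-link sites. Records whose site falls off the chromosome are skipped
    (tallied in the log).
    """
    counts: dict = defaultdict(int)
    n_skipped = 0
    for r in records:
        if r.deletions and not include_deleted:
            continue
        site = derive_truncation_site(r)
        if site is None:
            n_skipped += 1
            continue
        counts[(r.chrom, r.strand, site.position)] += 1
    if n_skipped:
        logger.warning("skipped %d records with off-chromosome truncation sites",
                       n_skipped)
    return [
        CrossLinkSite(c, s, p, n, TRUNCATION)
        for (c, s, p), n in sorted(counts.items())
    ]


def deletion_sites(records: Sequence[MappedCdna]) -> List[CrossLinkSite]:
    """Aggregate deletion-derived cross-link sites (one selected deletion per cDNA)."""
    counts: dict = defaultdict(int)
    for r in records:
        if not r.deletions:
            continue
        counts[(r.chrom, r.strand, select_deletion(r))] += 1
    return [
        CrossLinkSite(c, s, p, n, DELETION) for (c, s, p), n in sorted(counts.items())
    ]


def unique_cdna_count(records: Iterable[MappedCdna]) -> int:
    """Number of distinct (chrom, strand, 5' start) keys."""
    return len({(r.chrom, r.strand, r.start5) for r in records})
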