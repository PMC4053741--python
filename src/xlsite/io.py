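"""Readers and writers for the pipeline's on-disk formats.

Formats
-------
* cDNA records: a tab-separated dialect with columns
  ``chrom  start  end  strand  barcode  deletions`` where ``barcode`` is ``.``
  for barcode-free libraries and ``deletions`` is a comma-separated list of
  genomic positions (``.`` if none). SAM is accepted as an alternative input;
  deletions are taken from CIGAR ``D`` operations.
* Cross-link sites: BED6 with the cDNA count in the score column and the
  source (truncation/deletion) in the name column.
* Segments: BED6 where the name column carries the segment type
  (e.g. genic/intergenic/3utr/intron).
* Genome: FASTA (read through pyfaidx).

All coordinates are 0-based half-open, matching BED conventions natively.
"""
from __future__ import annotations

import os
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from ._seq import revcomp
from .records import CrossLinkSite, MappedCdna

CDNA_COLUMNS = ["chrom", "start", "end", "strand", "barcode", "deletions"]


def write_cdna_tsv(records: Iterable[MappedCdna], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CDNA_COLUMNS) + "\n")
        for r in records:
            dels = ",".join(str(d) for d in r.deletions) if r.deletions else "."
            bc = r.barcode if r.barcode is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{bc}\t{dels}\n")


def read_cdna_tsv(path: str) -> List[MappedCdna]:
    df = pd.read_csv(
        path, sep="\t", comment=None, header=None, skiprows=1, names=CDNA_COLUMNS,
        dtype={"chrom": str, "barcode": str, "deletions": str},
    )
    records = []
    for row in df.itertuples():
        dels: tuple = ()
        if isinstance(row.deletions, str) and row.deletions not in (".", ""):
            dels = tuple(int(x) for x in row.deletions.split(","))
        bc = None if (not isinstance(row.barcode, str) or row.barcode == ".") else row.barcode
        records.append(
            MappedCdna(row.chrom, row.strand, int(row.start), int(row.end), bc, dels)
        )
    return records


def read_cdna_sam(
    path: str,
    barcode_tag: Optional[str] = "RX",
    barcode_from_name: bool = False,
) -> List[MappedCdna]:
    """Read mapped cDNAs from SAM/BAM.

    Deletion positions come from CIGAR ``D`` operations. The random barcode is
    taken from ``barcode_tag`` when present, or from the read-name suffix after
    the final ``:`` when ``barcode_from_name`` is set.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            dels = []
            ref = read.reference_start
            for op, ln in read.cigartuples or ():
                if op == 2:  # D
                    dels.extend(range(ref, ref + ln))
                if op in (0, 2, 3, 7, 8):  # consumes reference
                    ref += ln
            barcode = None
            if barcode_tag and read.has_tag(barcode_tag):
                barcode = str(read.get_tag(barcode_tag))
            elif barcode_from_name and ":" in read.query_name:
                barcode = read.query_name.rsplit(":", 1)[1]
            records.append(
                MappedCdna(
                    read.reference_name,
                    "-" if read.is_reverse else "+",
                    read.reference_start,
                    read.reference_end,
                    barcode,
                    tuple(dels),
                )
            )
    return records


def write_cdna_sam(records: Sequence[MappedCdna], genome, path: str) -> None:
    """Write cDNAs as SAM, reconstructing sequences from the genome.

    The aligned sequence skips deleted bases; minus-strand reads are stored
    reverse-complemented as SAM requires. Barcodes go to the ``RX`` tag.
    """
    import pysam

    from ._seq import as_genome

    genome = as_genome(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    chrom_index = {c: i for i, c in enumerate(genome)}
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for i, r in enumerate(records):
            a = pysam.AlignedSegment()
            a.query_name = f"cdna{i}"
            a.reference_id = chrom_index[r.chrom]
            a.reference_start = r.start
            a.is_reverse = r.strand == "-"
            a.mapping_quality = 255
            seq = genome[r.chrom][r.start : r.end]
            kept = "".join(
                b for p, b in zip(range(r.start, r.end), seq) if p not in r.deletions
            )
            a.query_sequence = kept if r.strand == "+" else revcomp(kept)
            cigar = []
            pos = r.start
            for d in r.deletions:
                if d > pos:
                    cigar.append((0, d - pos))
                cigar.append((2, 1))
                pos = d + 1
            if r.end > pos:
                cigar.append((0, r.end - pos))
            if r.strand == "-":
                # CIGAR stays in reference orientation for minus reads too.
                pass
            a.cigartuples = cigar
            if r.barcode is not None:
                a.set_tag("RX", r.barcode)
            fh.write(a)


def write_sites_bed(sites: Iterable[CrossLinkSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.position, s.strand)):
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.source}\t{s.count}\t{s.strand}\n"
            )


def read_sites_bed(path: str) -> List[CrossLinkSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, _end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            sites.append(CrossLinkSite(chrom, strand, int(start), int(score), name))
    return sites


SEGMENT_COLUMNS = ["chrom", "start", "end", "segment_type", "score", "strand"]


def write_segments_bed(segments: pd.DataFrame, path: str) -> None:
    df = segments.copy()
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_segments_bed(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=SEGMENT_COLUMNS, dtype={"chrom": str}
    )


def write_fasta(genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(chrom: str, start: int, values, path: str) -> None:
    """Write a per-position track as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        i = 0
        n = len(values)
        while i < n:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            fh.write(f"{chrom}\t{start + i}\t{start + j + 1}\t{values[i]:g}\n")
            i = j + 1


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
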