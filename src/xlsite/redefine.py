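"""Re-define deletion sites inside TTT homopolymer context.

Reverse-transcriptase slippage places one-base deletions preferentially in
homonucleotide runs, where the deleted base is ambiguous. Aligners resolve
the ambiguity systematically toward the highest genomic coordinate of the
run, which puts plus-strand deletions at the transcript 3' end of a uridine
tract and minus-strand deletions at its transcript 5' end, shifting the two
strands' motif profiles by two nucleotides relative to each other.

The correction searches a 3-nt window ending at the deletion site, expressed
in transcript orientation: offsets -2..0 for plus-strand cDNAs and 0..+2 for
minus-strand cDNAs, both of which denote the genomic window ``[d-2, d]``. If
that window reads TTT on the transcript (genomic TTT on plus, genomic AAA on
minus), the site is re-centred to the middle of the motif, ``d - 1``.
Re-defined sites that collide with existing sites are merged with summed
counts.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import List, Sequence, Union

from ._seq import Genome, as_genome
from .records import DELETION, CrossLinkSite, RedefinedSite

logger = logging.getLogger(__name__)


def redefine_deletion(site: CrossLinkSite, genome: Union[str, Genome]) -> RedefinedSite:
    """Re-centre one deletion site if it sits at the edge of a sense TTT motif.

    ``genome`` may be a FASTA path or a ``{chrom: sequence}`` mapping. Sites
    whose window extends past the chromosome boundary are returned unchanged
    (logged).
    """
    if site.source != DELETION:
        raise ValueError("only deletion-derived sites are re-defined")
    genome = as_genome(genome)
    seq = genome[site.chrom]
    d = site.position
    if d - 2 < 0 or d >= len(seq):
        logger.warning("re-definition window off chromosome for %s:%d", site.chrom, d)
        return RedefinedSite(site.chrom, site.strand, d, site.count, d, False)
    window = seq[d - 2 : d + 1]
    target = "TTT" if site.strand == "+" else "AAA"
    if window == target:
        return RedefinedSite(site.chrom, site.strand, d - 1, site.count, d, True)
    return RedefinedSite(site.chrom, site.strand, d, site.count, d, False)


def merge_redefined(sites: Sequence[RedefinedSite]) -> List[CrossLinkSite]:
    """Merge re-defined sites sharing a position, summing deletion counts."""
    counts: dict = defaultdict(int)
    for s in sites:
        counts[(s.chrom, s.strand, s.position)] += s.count
    return [
        CrossLinkSite(c, st, p, n, DELETION)
        for (c, st, p), n in sorted(counts.items())
    ]


def redefine_sites(sites: Sequence[CrossLinkSite],
                   genome: Union[str, Genome]) -> List[CrossLinkSite]:
    """Re-define every deletion site and merge colliding positions."""
    genome = as_genome(genome)
    redefined = [redefine_deletion(s, genome) for s in sites]
    n_moved = sum(1 for s in redefined if s.redefined)
    if n_moved:
        logger.info("re-defined %d/%d deletion sites into TTT centres",
                    n_moved, len(redefined))
    return merge_redefined(redefined)
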