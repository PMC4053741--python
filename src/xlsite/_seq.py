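"""Sequence utilities: complementing, IUPAC motif matching, homopolymer runs.

Motif matching counts overlapping occurrences (YCAY instances can overlap by
one nucleotide), so all scanners use a zero-width lookahead regex.
"""
from __future__ import annotations

import re
from functools import lru_cache
from typing import Dict, Mapping, Tuple, Union

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes. N is expanded to ACGT (it never matches padding).
IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(motif: str) -> str:
    """Reverse complement of an IUPAC motif (YCAY -> RTGR)."""
    return motif.upper().translate(_IUPAC_COMPLEMENT)[::-1]


@lru_cache(maxsize=64)
def iupac_regex(motif: str) -> "re.Pattern[str]":
    """Compile an overlap-aware regex for an IUPAC motif."""
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"motif {motif!r} contains non-IUPAC codes {sorted(bad)}")
    body = "".join(f"[{IUPAC[c]}]" for c in motif)
    return re.compile(f"(?=({body}))")


def motif_starts(seq: str, motif: str) -> np.ndarray:
    """Boolean array over ``seq``: True where a motif instance starts."""
    out = np.zeros(len(seq), dtype=bool)
    pat = iupac_regex(motif)
    for m in pat.finditer(seq.upper()):
        out[m.start()] = True
    return out


def sense_indicators(seq: str, motif: str) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position motif-start indicators for both transcript senses.

    Returns ``(plus, minus)``. ``plus[q]`` is True when a motif instance starts
    at genomic position ``q`` read on the plus strand. ``minus[q]`` is True
    when an instance of the motif in minus-strand transcript orientation has
    its 5' (transcript-start) base at genomic position ``q``; i.e. the reverse
    complement of ``seq[q - L + 1 : q + 1]`` matches the motif.
    """
    plus = motif_starts(seq, motif)
    # A match at index i of the reverse complement starts (in transcript
    # orientation) at genomic position len(seq) - 1 - i.
    minus = motif_starts(revcomp(seq), motif)[::-1]
    return plus, minus


def random_bases(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    idx = rng.integers(0, len(alphabet), n)
    return "".join(alphabet[i] for i in idx)


def homopolymer_runs(seq: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run decomposition of ``seq``.

    Returns ``(run_start_at, run_end_at, run_len_at)`` arrays indexed by
    position: the first index, last index (inclusive) and length of the
    maximal same-base run containing each position.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    if n == 0:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty, empty
    change = np.concatenate(([True], arr[1:] != arr[:-1]))
    run_id = np.cumsum(change) - 1
    starts = np.flatnonzero(change)
    lens = np.diff(np.concatenate((starts, [n])))
    run_start_at = starts[run_id]
    run_len_at = lens[run_id]
    run_end_at = run_start_at + run_len_at - 1
    return run_start_at, run_end_at, run_len_at


Genome = Mapping[str, str]


def as_genome(genome: Union[str, Genome]) -> Dict[str, str]:
    """Normalise a genome argument to ``{chrom: uppercase sequence}``.

    Accepts an in-memory mapping or a FASTA path (read through pyfaidx).
    """
    if isinstance(genome, (str, bytes)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    return {chrom: str(seq).upper() for chrom, seq in genome.items()}
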