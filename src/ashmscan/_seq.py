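"""Small sequence helpers shared across modules.

A "genome" anywhere in this package is any mapping from chromosome name to
a sliceable sequence: a plain ``dict[str, str]`` (synthetic data) or a
``pyfaidx.Fasta`` opened on an indexed FASTA both work.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC degenerate classes used by the AID motif rules
W = frozenset("AT")
R = frozenset("AG")
Y = frozenset("CT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] (0-based half-open), clipped at edges.

    Returns an upper-case string; shorter than requested when the window
    runs over a contig edge (callers check the length).
    """
    if start < 0:
        start = 0
    if start >= end:
        return ""
    return str(genome[chrom][start:end]).upper()
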