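"""Sequence-context classification of substitutions as AID-compatible.

Activation-induced cytidine deaminase (AID) preferentially deaminates
cytosines inside the WRCY hotspot motif (W=A/T, R=A/G, Y=C/T), yielding
C>T and C>G changes — the *classical* AID (c-AID) pattern.  Error-prone
repair downstream of AID lesions additionally mutates adenines inside WA
dinucleotides to C or G — *non-classical* AID (nc-AID).  Both patterns are
strand symmetric, so each variant is tested on the plus strand first and
then on the reverse complement; contexts are read from the reference
(pre-mutation) sequence, since that is the template AID acted on.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd

from ._seq import R, W, Y, fetch, revcomp
from .io_core import VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContextCall:
    variant: VariantRecord
    label: str  # "c-AID" | "nc-AID" | "none"
    strand: str  # "+" | "-" | "."
    context: str  # 4-mer (c-AID) / 2-mer (nc-AID) read on the matching strand


def classify_aid(variant: VariantRecord, genome) -> ContextCall:
    """Classify one substitution's reference context.

    Rules on the strand carrying the mutated pyrimidine/adenine:

    * c-AID: C>T or C>G with the C at position 3 of a WRCY 4-mer;
    * nc-AID: A>C or A>G with the A at position 2 of a WA 2-mer.

    On the plus strand the minus-strand c-AID rule reads G>A/C inside RGYW
    (G at position 2), the minus-strand nc-AID rule T>G/C followed by W.
    c-AID takes precedence over nc-AID; within one label the plus strand is
    tested first.  Positions too close to a contig edge return "none" with
    a logged warning.
    """
    pos0 = variant.pos - 1
    seq = fetch(genome, variant.chrom, pos0 - 3, pos0 + 4)
    if pos0 - 3 < 0 or len(seq) < 7:
        logger.warning(
            "%s:%d too close to the contig edge for context classification",
            variant.chrom,
            variant.pos,
        )
        return ContextCall(variant, "none", ".", "")
    # seq indices: 0..6 with the variant base at index 3
    ref, alt = variant.ref, variant.alt

    # c-AID, plus strand: W R C Y with the C mutated
    if ref == "C" and alt in "TG":
        if seq[1] in W and seq[2] in R and seq[4] in Y:
            return ContextCall(variant, "c-AID", "+", seq[1:5])
    # c-AID, minus strand: plus-strand R G Y W with the G mutated (G>A/C)
    if ref == "G" and alt in "AC":
        if seq[2] in R and seq[4] in Y and seq[5] in W:
            return ContextCall(variant, "c-AID", "-", revcomp(seq[2:6]))
    # nc-AID, plus strand: W A with the A mutated (A>C/G)
    if ref == "A" and alt in "CG":
        if seq[2] in W:
            return ContextCall(variant, "nc-AID", "+", seq[2:4])
    # nc-AID, minus strand: plus-strand T W with the T mutated (T>G/C)
    if ref == "T" and alt in "GC":
        if seq[4] in W:
            return ContextCall(variant, "nc-AID", "-", revcomp(seq[3:5]))
    return ContextCall(variant, "none", ".", "")


def summarize_contexts(
    calls: Iterable[ContextCall],
    group_key: Callable[[ContextCall], str] | None = None,
) -> pd.DataFrame:
    """Fractions of c-AID / nc-AID / unclassified calls, optionally by group.

    Fractions sum to 1 within each group; empty groups are simply absent.
    """
    calls = list(calls)
    if group_key is None:
        group_key = lambda c: "all"  # noqa: E731
    counts: dict[str, Counter] = {}
    for c in calls:
        counts.setdefault(group_key(c), Counter())[c.label] += 1
    rows = []
    for group in sorted(counts):
        total = sum(counts[group].values())
        rows.append(
            {
                "group": group,
                "n": total,
                "c_aid": counts[group]["c-AID"] / total,
                "nc_aid": counts[group]["nc-AID"] / total,
                "none": counts[group]["none"] / total,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "c_aid", "nc_aid", "none"])


def calls_to_frame(calls: Iterable[ContextCall]) -> pd.DataFrame:
    """Variant table with appended aid_label / aid_strand / aid_context columns."""
    return pd.DataFrame(
        [
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "sample_id": c.variant.sample_id,
                "aid_label": c.label,
                "aid_strand": c.strand,
                "aid_context": c.context,
            }
            for c in calls
        ]
    )
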