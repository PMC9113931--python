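"""PWM scanning and constructive/destructive mutation calls at binding sites.

A variant inside (or near) a transcription-factor binding site can weaken
the match to the factor's position weight matrix — a *destructive*
mutation — or improve it / create a new site — a *constructive* mutation.
Each variant is scored by the best log2-odds PWM match over a window of
``pad`` bases either side of the mutated position (both strands), once on
the reference sequence and once with the alternate base substituted; the
sign of the score difference classifies the variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import fetch, revcomp
from .io_core import GenomicInterval, VariantRecord

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
DEFAULT_PSEUDOCOUNT = 0.8  # split by background, the JASPAR convention


@dataclass
class PWM:
    """Position weight matrix with lazily derived log-odds scores."""

    motif_id: str
    counts: np.ndarray  # 4 x L, rows A, C, G, T
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: counts must be 4 x L")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.motif_id}: negative counts")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Column-stochastic probabilities after pseudocount regularization."""
        pc = self.pseudocount * self.background[:, None]
        reg = self.counts + pc
        return reg / reg.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background) per base and column."""
        return np.log2(self.probabilities / self.background[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probabilities.argmax(axis=0))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (relative to background)."""
        p = self.probabilities
        return (p * np.log2(p / self.background[:, None])).sum(axis=0)


def parse_jaspar(path) -> list[PWM]:
    """Parse PWMs from a JASPAR PFM file (``>ID NAME`` plus four count rows)."""
    from Bio import motifs as bio_motifs

    pwms: list[PWM] = []
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # biopython raises bare ValueError/KeyError
            raise ValueError(f"{path}: malformed JASPAR PFM file ({exc})") from exc
        for m in parsed:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            if counts.ndim != 2 or 0 in counts.shape:
                raise ValueError(f"{path}: motif {m.matrix_id or m.name}: bad count rows")
            pwms.append(PWM(motif_id=m.matrix_id or m.name, counts=counts))
    return pwms


def write_jaspar(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for base in "ACGT":
                row = " ".join(f"{int(c):6d}" for c in pwm.counts[_BASE_INDEX[base]])
                fh.write(f"{base}  [{row} ]\n")


def _strand_scores(pwm: PWM, seq: str) -> np.ndarray:
    """Log-odds score at every offset of one strand; N bases contribute 0."""
    L = pwm.length
    lo = pwm.log_odds
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    n_off = len(seq) - L + 1
    windows = idx[np.arange(n_off)[:, None] + np.arange(L)[None, :]]
    contrib = np.where(windows >= 0, lo[np.clip(windows, 0, 3), np.arange(L)[None, :]], 0.0)
    return contrib.sum(axis=1)


def best_score(pwm: PWM, sequence: str) -> tuple[float, int, str]:
    """Best log2-odds match over all offsets and both strands.

    Returns ``(score, offset, strand)`` with the offset in the coordinates
    of the given sequence.  Ties break to the smallest offset, plus strand
    before minus.
    """
    seq = sequence.upper()
    if len(seq) < pwm.length:
        raise ValueError(f"sequence ({len(seq)} bp) shorter than motif {pwm.motif_id} ({pwm.length} bp)")
    fwd = _strand_scores(pwm, seq)
    rev = _strand_scores(pwm, revcomp(seq))
    best_f = int(np.argmax(fwd))
    best_r = int(np.argmax(rev))
    score_f, score_r = float(fwd[best_f]), float(rev[best_r])
    if score_r > score_f:
        # map the reverse-complement offset back to original coordinates
        return score_r, len(seq) - pwm.length - best_r, "-"
    return score_f, best_f, "+"


@dataclass(frozen=True)
class ImpactCall:
    variant: VariantRecord
    motif_id: str
    wt_score: float
    mut_score: float
    delta: float
    impact: str  # constructive | destructive | neutral


def classify_impact(
    variant: VariantRecord,
    genome,
    pwms: Sequence[PWM],
    pad: int = 15,
    delta_min: float = 0.0,
) -> list[ImpactCall]:
    """Score the variant's window against every PWM, wild-type vs mutated.

    The window is ``2 * pad + 1`` bases centered on the variant (shorter at
    contig edges, logged).  A call is constructive when the best match score
    rises by more than ``delta_min``, destructive when it falls by more than
    ``delta_min``, neutral otherwise.
    """
    pos0 = variant.pos - 1
    start = pos0 - pad
    window = fetch(genome, variant.chrom, start, pos0 + pad + 1)
    center = pos0 - max(start, 0)
    if len(window) < 2 * pad + 1:
        logger.warning("window at %s:%d clipped to %d bp", variant.chrom, variant.pos, len(window))
    if window[center] != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {window[center]}, record says {variant.ref}"
        )
    mutated = window[:center] + variant.alt + window[center + 1 :]
    calls = []
    for pwm in pwms:
        wt, _, _ = best_score(pwm, window)
        mut, _, _ = best_score(pwm, mutated)
        delta = mut - wt
        if delta > delta_min:
            impact = "constructive"
        elif delta < -delta_min:
            impact = "destructive"
        else:
            impact = "neutral"
        calls.append(ImpactCall(variant, pwm.motif_id, wt, mut, delta, impact))
    return calls


def mutated_cluster_sequences(
    cluster: GenomicInterval,
    variants: Sequence[VariantRecord],
    genome,
    mode: str = "single",
) -> list[tuple[str, str]]:
    """Build labeled wild-type and mutated sequences for a variant cluster.

    ``mode="single"`` applies one variant per sequence; ``mode="all"``
    additionally emits sequences with every variant applied, enumerating
    conflicting alternate alleles at a shared position separately.  The
    wild-type sequence is always first, labeled ``wt``.
    """
    wt = fetch(genome, cluster.chrom, cluster.start, cluster.end)
    for v in variants:
        if not (cluster.chrom == v.chrom and cluster.start <= v.pos - 1 < cluster.end):
            raise ValueError(f"variant {v.chrom}:{v.pos} outside cluster {cluster}")
    out = [("wt", wt)]

    def apply(seq: str, v: VariantRecord, alt: str) -> str:
        off = v.pos - 1 - cluster.start
        return seq[:off] + alt + seq[off + 1 :]

    for v in variants:
        out.append((f"{v.chrom}:{v.pos}{v.ref}>{v.alt}", apply(wt, v, v.alt)))
    if mode == "all" and variants:
        by_pos: dict[int, list[VariantRecord]] = {}
        for v in variants:
            by_pos.setdefault(v.pos, []).append(v)
        positions = sorted(by_pos)
        for combo in product(*(by_pos[p] for p in positions)):
            seq = wt
            for v in combo:
                seq = apply(seq, v, v.alt)
            label = "all:" + ",".join(f"{v.pos}{v.ref}>{v.alt}" for v in combo)
            out.append((label, seq))
    elif mode not in ("single", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    return out


@dataclass(frozen=True)
class MotifSummary:
    motif_id: str
    n_constructive: int
    n_destructive: int
    n_neutral: int
    majority: str  # ties resolve to neutral
    best_score: float


def cluster_motif_summary(calls: Iterable[ImpactCall]) -> list[MotifSummary]:
    """Per-motif majority impact class over a cluster's variant calls.

    The best-matching motif is the one with the highest max(wt, mut) score;
    summaries are returned best match first.
    """
    per_motif: dict[str, list[ImpactCall]] = {}
    for c in calls:
        per_motif.setdefault(c.motif_id, []).append(c)
    out = []
    for motif_id, group in per_motif.items():
        n_c = sum(c.impact == "constructive" for c in group)
        n_d = sum(c.impact == "destructive" for c in group)
        n_n = sum(c.impact == "neutral" for c in group)
        if n_c > max(n_d, n_n):
            majority = "constructive"
        elif n_d > max(n_c, n_n):
            majority = "destructive"
        else:
            majority = "neutral"
        best = max(max(c.wt_score, c.mut_score) for c in group)
        out.append(MotifSummary(motif_id, n_c, n_d, n_n, majority, best))
    out.sort(key=lambda s: -s.best_score)
    return out


def impact_calls_to_frame(calls: Iterable[ImpactCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "sample_id": c.variant.sample_id,
                "motif_id": c.motif_id,
                "wt_score": c.wt_score,
                "mut_score": c.mut_score,
                "delta": c.delta,
                "class": c.impact,
            }
            for c in calls
        ]
    )
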