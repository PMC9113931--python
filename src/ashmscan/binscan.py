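"""Multi-resolution genomic binning and per-base maximum-score profiles.

Bins tile a *territory* (an ordered list of half-open intervals) at a fixed
size, anchored at each interval's start; the last bin of an interval is
truncated.  Variant assignment produces the bin-by-sample count matrix whose
marginals are the degrees of the bipartite sample-bin graph used by
:mod:`ashmscan.enrich`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_core import GenomicInterval, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinGrid:
    territory: tuple[GenomicInterval, ...]
    bin_size: int
    bins: tuple[GenomicInterval, ...]
    # index of the first bin of each territory interval (parallel to territory)
    offsets: tuple[int, ...] = field(repr=False, default=())

    @property
    def territory_length(self) -> int:
        return sum(len(iv) for iv in self.territory)


def make_bins(territory: Sequence[GenomicInterval], bin_size: int) -> BinGrid:
    """Tile each territory interval with ``bin_size`` bp bins (last truncated)."""
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    bins: list[GenomicInterval] = []
    offsets: list[int] = []
    for iv in territory:
        offsets.append(len(bins))
        for start in range(iv.start, iv.end, bin_size):
            bins.append(GenomicInterval(iv.chrom, start, min(start + bin_size, iv.end)))
    return BinGrid(tuple(territory), bin_size, tuple(bins), tuple(offsets))


@dataclass
class AssignmentMatrix:
    """Bin-by-sample variant counts with cached bipartite-graph marginals."""

    grid: BinGrid
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_bins, n_samples), int
    n_skipped: int = 0  # records outside the territory

    @property
    def bin_degrees(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def sample_degrees(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total_edges(self) -> int:
        return int(self.counts.sum())

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def assign(
    records: Iterable[VariantRecord],
    grid: BinGrid,
    sample_ids: Sequence[str] | None = None,
) -> AssignmentMatrix:
    """Count each in-territory record into exactly one bin.

    ``sample_ids`` fixes the column order (and includes zero-variant
    samples); by default columns are the sorted distinct sample ids seen.
    Records outside the territory are skipped with a logged count.
    """
    records = list(records)
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in records})
    sample_ids = tuple(sample_ids)
    col = {s: j for j, s in enumerate(sample_ids)}

    # per-chromosome lookup of (start, end, first-bin index) blocks
    blocks: dict[str, list[tuple[int, int, int]]] = {}
    for iv, off in zip(grid.territory, grid.offsets):
        blocks.setdefault(iv.chrom, []).append((iv.start, iv.end, off))

    counts = np.zeros((len(grid.bins), len(sample_ids)), dtype=np.int64)
    n_skipped = 0
    for r in records:
        if r.sample_id not in col:
            raise ValueError(f"sample {r.sample_id!r} not in sample_ids")
        pos0 = r.pos - 1
        placed = False
        for start, end, off in blocks.get(r.chrom, ()):
            if start <= pos0 < end:
                counts[off + (pos0 - start) // grid.bin_size, col[r.sample_id]] += 1
                placed = True
                break
        if not placed:
            n_skipped += 1
    if n_skipped:
        logger.info("assign: skipped %d record(s) outside territory", n_skipped)
    return AssignmentMatrix(grid, sample_ids, counts, n_skipped)


def write_bedgraph(profiles: Sequence[np.ndarray], territory: Sequence[GenomicInterval], path) -> None:
    """Write per-base profiles as bedGraph (runs of equal value merged)."""
    with open(path, "w") as fh:
        for iv, prof in zip(territory, profiles):
            start = 0
            for i in range(1, len(prof) + 1):
                boundary = i == len(prof) or not (
                    prof[i] == prof[start] or (np.isnan(prof[i]) and np.isnan(prof[start]))
                )
                if boundary:
                    if not np.isnan(prof[start]):
                        fh.write(f"{iv.chrom}\t{iv.start + start}\t{iv.start + i}\t{prof[start]:g}\n")
                    start = i


def bin_table(grid: BinGrid, assignment: "AssignmentMatrix") -> "pd.DataFrame":
    """Per-bin TSV payload: coordinates, bin size and bin degree."""
    import pandas as pd

    d_b = assignment.bin_degrees
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in grid.bins],
            "start": [b.start for b in grid.bins],
            "end": [b.end for b in grid.bins],
            "bin_size": grid.bin_size,
            "d_b": d_b,
        }
    )


def per_base_max_z(
    scores: Sequence[np.ndarray], grids: Sequence[BinGrid]
) -> list[np.ndarray]:
    """Per-base maximum score over bins of several grids on one territory.

    ``scores[i]`` holds one score per bin of ``grids[i]`` (NaN = unscored
    bin).  Returns one array per territory interval, parallel to the
    territory, with NaN where no scored bin covers the base.
    """
    territory = grids[0].territory
    for g in grids[1:]:
        if g.territory != territory:
            raise ValueError("all grids must cover the same territory")
    profiles = [np.full(len(iv), np.nan) for iv in territory]
    for score_vec, grid in zip(scores, grids):
        score_vec = np.asarray(score_vec, dtype=float)
        if score_vec.size != len(grid.bins):
            raise ValueError("score vector length does not match grid bins")
        for t_idx, (iv, off) in enumerate(zip(grid.territory, grid.offsets)):
            n_bins = -(-len(iv) // grid.bin_size)
            prof = profiles[t_idx]
            for b in range(n_bins):
                s = score_vec[off + b]
                if np.isnan(s):
                    continue
                lo = b * grid.bin_size
                hi = min(lo + grid.bin_size, len(iv))
                seg = prof[lo:hi]
                np.fmax(seg, s, out=seg)
    return profiles
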