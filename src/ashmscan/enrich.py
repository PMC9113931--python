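"""Bipartite sample-bin enrichment: the core hotspot statistic.

Model
-----
Variants define a bipartite graph with samples on one side and genomic bins
on the other; a bin's degree is the number of variants falling in it, a
sample's degree its number of variants in the scanned territory.  Under the
randomization null, each of sample *s*'s ``d_s`` variants lands in bin *b*
independently with probability ``q_b``:

* configuration null: ``q_b = d_b / E`` — conditions on the observed bin
  activity, so the test asks whether the *focal cohort's* share of a bin's
  activity is excessive (relative enrichment across cohorts);
* uniform null: ``q_b = L_b / L_tot`` — absolute hotspot mode, expected
  hits proportional to bin length.

The per-cohort statistic per bin is the number of cohort samples hitting the
bin at least once.  Sample *s* hits bin *b* with probability
``p_sb = 1 - (1 - q_b)^{d_s}``, so the cohort count is Poisson-binomial and
its upper tail (exact DP for cohorts up to ``exact_max_n`` samples,
bi-binomial beyond) gives the enrichment P value; Z-scores use the exact
moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from . import pbstats
from .binscan import AssignmentMatrix, BinGrid, assign, make_bins, per_base_max_z
from .io_core import GenomicInterval, SampleMeta, VariantRecord

HIGHLY_SIGNIFICANT = 10.0  # -log10 P flag threshold for genome-wide scans


@dataclass(frozen=True)
class BipartiteModel:
    sample_ids: tuple[str, ...]
    sample_degrees: np.ndarray
    bin_degrees: np.ndarray
    total_edges: int
    bin_lengths: np.ndarray
    territory_length: int
    null_kind: str  # "configuration" | "uniform"

    def bin_prob(self, bin_idx) -> np.ndarray | float:
        """Null per-variant probability q_b of landing in the bin."""
        if self.null_kind == "configuration":
            return self.bin_degrees[bin_idx] / self.total_edges
        return self.bin_lengths[bin_idx] / self.territory_length


def build_model(
    assignment: AssignmentMatrix, null_kind: str = "configuration"
) -> BipartiteModel:
    if null_kind not in ("configuration", "uniform"):
        raise ValueError(f"unknown null_kind {null_kind!r}")
    E = assignment.total_edges
    if E == 0:
        raise ValueError("no edges: nothing to model")
    return BipartiteModel(
        sample_ids=assignment.sample_ids,
        sample_degrees=assignment.sample_degrees.copy(),
        bin_degrees=assignment.bin_degrees.copy(),
        total_edges=E,
        bin_lengths=np.array([len(b) for b in assignment.grid.bins]),
        territory_length=assignment.grid.territory_length,
        null_kind=null_kind,
    )


def edge_prob(model: BipartiteModel, sample_id: str, bin_idx: int) -> float:
    """Probability that the sample hits the bin at least once under the null."""
    d_s = model.sample_degrees[model.sample_ids.index(sample_id)]
    q_b = model.bin_prob(bin_idx)
    return float(1.0 - (1.0 - q_b) ** d_s)


@dataclass(frozen=True)
class EnrichmentResult:
    bin_idx: int
    interval: GenomicInterval
    cohort: str
    k_obs: int
    k_raw: int  # raw variant multiplicity in the bin, for transparency
    tail: pbstats.TailResult

    @property
    def z(self) -> float:
        return self.tail.z

    @property
    def neglog10p(self) -> float:
        return self.tail.neglog10p


def cohort_enrichment(
    model: BipartiteModel,
    assignment: AssignmentMatrix,
    cohort_samples: Iterable[str],
    exact_max_n: int = 200,
) -> list[EnrichmentResult]:
    """Per-bin enrichment of a cohort's sample hits against the null.

    Bins with zero total variants are skipped (their null is degenerate at
    zero).  Exact DP tails for cohorts of at most ``exact_max_n`` samples,
    bi-binomial approximation beyond.
    """
    cohort = list(cohort_samples)
    if not cohort:
        raise ValueError("empty cohort")
    idx = [model.sample_ids.index(s) for s in cohort]
    d_s = model.sample_degrees[idx].astype(float)
    hits = assignment.counts[:, idx] >= 1
    raw = assignment.counts[:, idx].sum(axis=1)

    results = []
    for b in np.nonzero(model.bin_degrees > 0)[0]:
        q_b = model.bin_prob(int(b))
        p_vec = 1.0 - (1.0 - q_b) ** d_s
        k_obs = int(hits[b].sum())
        tail = pbstats.pb_tail(p_vec, k_obs, exact_max_n=exact_max_n)
        results.append(
            EnrichmentResult(
                bin_idx=int(b),
                interval=assignment.grid.bins[b],
                cohort="",
                k_obs=k_obs,
                k_raw=int(raw[b]),
                tail=tail,
            )
        )
    return results


def _results_to_frame(results: Sequence[EnrichmentResult], cohort: str, bin_size: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in results],
            "start": [r.interval.start for r in results],
            "end": [r.interval.end for r in results],
            "bin_size": bin_size,
            "cohort": cohort,
            "k_obs": [r.k_obs for r in results],
            "k_raw": [r.k_raw for r in results],
            "mean": [r.tail.mean for r in results],
            "sd": [r.tail.sd for r in results],
            "z": [r.tail.z for r in results],
            "p_upper": [r.tail.p_upper for r in results],
            "neglog10p": [r.neglog10p for r in results],
            "method": [r.tail.method for r in results],
        }
    )


def genome_scan(
    records: Sequence[VariantRecord],
    meta: Sequence[SampleMeta],
    territory: Sequence[GenomicInterval],
    bin_sizes: Sequence[int],
    focal_cohort: str,
    null_kind: str = "configuration",
    exact_max_n: int = 200,
) -> pd.DataFrame:
    """Multi-size enrichment scan of the focal cohort versus all other samples.

    Returns one row per (bin size, cohort side, non-empty bin), ranked by the
    focal cohort's -log10 P, with a ``highly_significant`` flag at
    -log10 P >= 10.
    """
    cohorts = {m.cohort for m in meta}
    if focal_cohort not in cohorts or len(cohorts) < 2:
        raise ValueError("need the focal cohort plus at least one other cohort")
    sample_ids = [m.sample_id for m in meta]
    focal = [m.sample_id for m in meta if m.cohort == focal_cohort]
    rest = [m.sample_id for m in meta if m.cohort != focal_cohort]

    frames = []
    for size in bin_sizes:
        grid = make_bins(territory, size)
        assignment = assign(records, grid, sample_ids=sample_ids)
        model = build_model(assignment, null_kind)
        for label, members in ((focal_cohort, focal), ("rest", rest)):
            res = cohort_enrichment(model, assignment, members, exact_max_n=exact_max_n)
            frames.append(_results_to_frame(res, label, size))
    table = pd.concat(frames, ignore_index=True)
    # Benjamini-Hochberg per cohort side and bin size; advisory, never a filter
    table["q_bh"] = np.nan
    for (_, _), idx in table.groupby(["cohort", "bin_size"]).groups.items():
        table.loc[idx, "q_bh"] = false_discovery_control(
            table.loc[idx, "p_upper"].clip(0, 1), method="bh"
        )
    table["highly_significant"] = (table["neglog10p"] >= HIGHLY_SIGNIFICANT) & (
        table["cohort"] == focal_cohort
    )
    focal_rank = table[table["cohort"] == focal_cohort].sort_values(
        "neglog10p", ascending=False
    )
    rest_rows = table[table["cohort"] != focal_cohort]
    return pd.concat([focal_rank, rest_rows], ignore_index=True)


@dataclass(frozen=True)
class ClusterCall:
    interval: GenomicInterval
    z_focal: float
    z_background: float
    specificity: str  # focal-specific | shared | background


def _runs_above(profile: np.ndarray, threshold: float, merge_gap: int) -> list[tuple[int, int]]:
    """Half-open runs of bases with profile >= threshold, gaps <= merge_gap merged."""
    above = np.where(np.nan_to_num(profile, nan=-np.inf) >= threshold)[0]
    if above.size == 0:
        return []
    runs = []
    start = prev = int(above[0])
    for i in above[1:]:
        i = int(i)
        if i - prev - 1 <= merge_gap:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def call_specific_clusters(
    focal_scores: Sequence[np.ndarray],
    background_scores: Sequence[np.ndarray],
    grids: Sequence[BinGrid],
    z_hi: float = 3.0,
    z_lo: float = 2.0,
    merge_gap: int = 2,
) -> list[ClusterCall]:
    """Threshold per-base max-Z profiles into cohort-specificity cluster calls.

    ``focal_scores[i]`` / ``background_scores[i]`` are per-bin Z vectors on
    ``grids[i]``.  Contiguous bases with focal max-Z >= ``z_hi`` (gaps up to
    ``merge_gap`` bp merged) become clusters; a cluster is *focal-specific*
    when the background max-Z stays below ``z_lo`` over it, else *shared*.
    Background-only clusters (background >= ``z_hi``, focal < ``z_hi``) are
    reported with class *background*.
    """
    focal_prof = per_base_max_z(focal_scores, grids)
    bg_prof = per_base_max_z(background_scores, grids)
    calls: list[ClusterCall] = []
    for iv, fp, bp in zip(grids[0].territory, focal_prof, bg_prof):
        focal_runs = _runs_above(fp, z_hi, merge_gap)
        for lo, hi in focal_runs:
            z_f = float(np.nanmax(fp[lo:hi]))
            z_b = float(np.nanmax(bp[lo:hi])) if np.any(~np.isnan(bp[lo:hi])) else -math.inf
            cls = "focal-specific" if z_b < z_lo else "shared"
            calls.append(ClusterCall(GenomicInterval(iv.chrom, iv.start + lo, iv.start + hi), z_f, z_b, cls))
        for lo, hi in _runs_above(bp, z_hi, merge_gap):
            if any(not (hi <= flo or lo >= fhi) for flo, fhi in focal_runs):
                continue  # overlaps a focal cluster, already reported
            z_f = float(np.nanmax(fp[lo:hi])) if np.any(~np.isnan(fp[lo:hi])) else -math.inf
            z_b = float(np.nanmax(bp[lo:hi]))
            calls.append(ClusterCall(GenomicInterval(iv.chrom, iv.start + lo, iv.start + hi), z_f, z_b, "background"))
    return calls


def fine_scan_z(
    records: Sequence[VariantRecord],
    meta: Sequence[SampleMeta],
    territory: Sequence[GenomicInterval],
    bin_sizes: Sequence[int],
    focal_cohort: str,
    null_kind: str = "configuration",
    exact_max_n: int = 200,
) -> tuple[list[np.ndarray], list[np.ndarray], list[BinGrid]]:
    """Per-bin Z vectors (focal, background) across several bin sizes.

    Convenience used by cluster calling; bins with zero variants carry NaN.
    """
    sample_ids = [m.sample_id for m in meta]
    focal = [m.sample_id for m in meta if m.cohort == focal_cohort]
    rest = [m.sample_id for m in meta if m.cohort != focal_cohort]
    grids, z_focal, z_rest = [], [], []
    for size in bin_sizes:
        grid = make_bins(territory, size)
        assignment = assign(records, grid, sample_ids=sample_ids)
        model = build_model(assignment, null_kind)
        zf = np.full(len(grid.bins), np.nan)
        zb = np.full(len(grid.bins), np.nan)
        for res in cohort_enrichment(model, assignment, focal, exact_max_n=exact_max_n):
            zf[res.bin_idx] = res.z
        for res in cohort_enrichment(model, assignment, rest, exact_max_n=exact_max_n):
            zb[res.bin_idx] = res.z
        grids.append(grid)
        z_focal.append(zf)
        z_rest.append(zb)
    return z_focal, z_rest, grids
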