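"""Probability kernels for hotspot enrichment and the classical tests around it.

The central object is the Poisson-binomial distribution: the number of
successes among independent Bernoulli trials with unequal probabilities.
In the enrichment model (see :mod:`ashmscan.enrich`) the trials are
"sample *s* hits bin *b* at least once" under the null, so cohort counts
per bin are Poisson-binomial and their tails give the enrichment P values.

Two tail engines are provided:

* an exact O(n^2) dynamic-programming convolution (``pb_pmf_exact``), and
* a bi-binomial approximation (``bibinomial_tail``): the trial
  probabilities are split into two groups by one-dimensional two-means
  and each group is replaced by a binomial with the group's mean
  probability; the tail of the convolution of the two binomials
  approximates the Poisson-binomial tail.  Moments (and hence Z-scores)
  are always computed exactly from the p_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TailResult",
    "pb_pmf_exact",
    "pb_moments",
    "pb_tail_exact",
    "two_means_split",
    "bibinomial_tail",
    "fisher_exact_2x2",
    "hypergeom_enrichment",
    "synonymous_enrichment",
]


@dataclass(frozen=True)
class TailResult:
    """Observed count with Poisson-binomial mean/SD/Z and upper-tail P."""

    k_obs: int
    mean: float
    sd: float
    z: float
    p_upper: float
    method: str

    @property
    def neglog10p(self) -> float:
        return -math.log10(max(self.p_upper, 1e-300))


def _as_prob_vector(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a non-empty 1-D vector of probabilities")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def pb_pmf_exact(p) -> np.ndarray:
    """Exact Poisson-binomial PMF over counts 0..n by DP convolution.

    O(n^2) time, numerically stable for n well beyond 10^4 because every
    operation is a convex combination of non-negative terms.
    """
    p = _as_prob_vector(p)
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for pi in p:
        # new[k] = old[k] * (1 - pi) + old[k-1] * pi
        pmf[1:] = pmf[1:] * (1.0 - pi) + pmf[:-1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def pb_moments(p) -> tuple[float, float]:
    """Exact mean and standard deviation of the Poisson-binomial."""
    p = _as_prob_vector(p)
    return float(p.sum()), float(np.sqrt((p * (1.0 - p)).sum()))


def _zscore(k_obs: int, mean: float, sd: float) -> float:
    if sd > 0.0:
        return (k_obs - mean) / sd
    # degenerate null: all p_i in {0,1}
    if k_obs == mean:
        return 0.0
    return math.inf if k_obs > mean else -math.inf


def pb_tail_exact(p, k_obs: int) -> TailResult:
    """Exact upper-tail Pr(K >= k_obs) via the DP kernel."""
    p = _as_prob_vector(p)
    if not 0 <= k_obs <= p.size:
        raise ValueError(f"k_obs={k_obs} outside 0..{p.size}")
    pmf = pb_pmf_exact(p)
    p_upper = 1.0 if k_obs == 0 else float(min(1.0, max(0.0, pmf[k_obs:].sum())))
    mean, sd = pb_moments(p)
    return TailResult(k_obs, mean, sd, _zscore(k_obs, mean, sd), p_upper, "exact_dp")


def two_means_split(p) -> np.ndarray:
    """Deterministic 1-D two-means: boolean mask of the high-probability group.

    Centroids start at min(p) and max(p); assignment/update iterated to
    convergence.  All-equal input yields an empty high group (a single
    binomial downstream).
    """
    p = _as_prob_vector(p)
    lo, hi = float(p.min()), float(p.max())
    if lo == hi:
        return np.zeros(p.size, dtype=bool)
    c_lo, c_hi = lo, hi
    mask = np.zeros(p.size, dtype=bool)
    for _ in range(100):
        new_mask = np.abs(p - c_hi) < np.abs(p - c_lo)  # ties -> low group
        if new_mask.any():
            c_hi = float(p[new_mask].mean())
        if (~new_mask).any():
            c_lo = float(p[~new_mask].mean())
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return mask


def bibinomial_tail(p, k_obs: int) -> TailResult:
    """Bi-binomial approximation of the Poisson-binomial upper tail.

    Exact when all p_i are equal (single binomial); mean/sd/z are always
    the exact Poisson-binomial moments.
    """
    p = _as_prob_vector(p)
    if not 0 <= k_obs <= p.size:
        raise ValueError(f"k_obs={k_obs} outside 0..{p.size}")
    mask = two_means_split(p)
    groups = [p[mask], p[~mask]]
    pmfs = []
    for g in groups:
        if g.size == 0:
            continue
        n_g, p_g = g.size, float(g.mean())
        pmfs.append(stats.binom.pmf(np.arange(n_g + 1), n_g, p_g))
    conv = pmfs[0]
    for extra in pmfs[1:]:
        conv = np.convolve(conv, extra)
    p_upper = 1.0 if k_obs == 0 else float(min(1.0, max(0.0, conv[k_obs:].sum())))
    mean, sd = pb_moments(p)
    return TailResult(k_obs, mean, sd, _zscore(k_obs, mean, sd), p_upper, "bibinomial")


def pb_tail(p, k_obs: int, exact_max_n: int = 200) -> TailResult:
    """Exact tail for short vectors, bi-binomial beyond ``exact_max_n`` trials."""
    p = _as_prob_vector(p)
    if p.size <= exact_max_n:
        return pb_tail_exact(p, k_obs)
    return bibinomial_tail(p, k_obs)


# ---------------------------------------------------------------------------
# Classical tests


def fisher_exact_2x2(table, sided: str = "two") -> float:
    """Fisher's exact test on a 2x2 contingency table.

    ``sided``: ``two`` (default; sum of hypergeometric probabilities of
    tables at most as probable as the observed one), ``greater`` or ``less``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    return float(stats.fisher_exact(t, alternative=alternative)[1])


@dataclass(frozen=True)
class EnrichmentStat:
    neglog10: float
    significant: bool  # statistic > 2


def hypergeom_enrichment(N: int, K: int, n: int, k_obs: int) -> EnrichmentStat:
    """Upper-tail hypergeometric enrichment as -log10 Pr(X >= k_obs).

    Drawing ``n`` items without replacement from a population of ``N``
    containing ``K`` successes, this is the negative decadic logarithm of
    the cumulative upper tail at the observed success count.  Values above
    2 (P below 0.01) are flagged significant.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k_obs <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric parameters N={N} K={K} n={n} k={k_obs}")
    logsf = stats.hypergeom.logsf(k_obs - 1, N, K, n)  # Pr(X >= k_obs)
    neglog10 = float(-logsf / math.log(10.0))
    return EnrichmentStat(neglog10=neglog10, significant=neglog10 > 2.0)


def synonymous_enrichment(groups: dict[str, tuple[int, int]]) -> dict[str, EnrichmentStat]:
    """Per-group enrichment of synonymous mutations among pooled coding calls.

    ``groups`` maps a group label to ``(n_total, n_synonymous)`` counted over
    the same exon.  The population is the pool of all groups' mutations, the
    successes are the pooled synonymous ones, and each group's mutations are
    the draws.
    """
    N = sum(t for t, _ in groups.values())
    K = sum(s for _, s in groups.values())
    out = {}
    for label, (n_total, n_syn) in groups.items():
        if n_syn > n_total:
            raise ValueError(f"group {label}: more synonymous than total")
        out[label] = hypergeom_enrichment(N, K, n_total, n_syn)
    return out
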