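"""Poisson-binomial kernels, bi-binomial tails and the classical tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ashmscan import pbstats


def brute_force_pmf(p):
    """Enumeration over all 2^n outcomes — the independent oracle."""
    n = len(p)
    pmf = np.zeros(n + 1)
    for outcome in itertools.product([0, 1], repeat=n):
        prob = 1.0
        for pi, x in zip(p, outcome):
            prob *= pi if x else 1.0 - pi
        pmf[sum(outcome)] += prob
    return pmf


class TestExactKernel:
    def test_symmetric_pair(self):
        assert np.allclose(pbstats.pb_pmf_exact([0.5, 0.5]), [0.25, 0.5, 0.25])

    def test_all_zero_probabilities(self):
        pmf = pbstats.pb_pmf_exact([0.0, 0.0, 0.0])
        assert pmf[0] == 1.0 and pmf[1:].sum() == 0.0

    def test_enumerated_tail(self):
        # Pr(K >= 2) for p = (0.1, 0.2, 0.7), frozen from the 2^3 enumeration
        pmf = pbstats.pb_pmf_exact([0.1, 0.2, 0.7])
        assert pmf[2:].sum() == pytest.approx(0.202, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force_enumeration(self, p):
        assert np.allclose(pbstats.pb_pmf_exact(p), brute_force_pmf(p), atol=1e-12)

    @pytest.mark.parametrize("n,prob", [(10, 0.3), (137, 0.05), (500, 0.6)])
    def test_constant_p_is_binomial(self, n, prob):
        from scipy import stats

        pmf = pbstats.pb_pmf_exact([prob] * n)
        assert np.allclose(pmf, stats.binom.pmf(np.arange(n + 1), n, prob), atol=1e-12)

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            pbstats.pb_pmf_exact([0.5, 1.2])
        with pytest.raises(ValueError):
            pbstats.pb_pmf_exact([])

    def test_tail_z_zero_iff_k_equals_mean(self):
        res = pbstats.pb_tail_exact([0.5] * 10, 5)
        assert res.z == 0.0
        assert pbstats.pb_tail_exact([0.5] * 10, 7).z > 0

    def test_degenerate_sd_zero(self):
        res = pbstats.pb_tail_exact([1.0, 1.0, 0.0], 3)
        assert res.sd == 0.0 and math.isinf(res.z) and res.z > 0
        assert pbstats.pb_tail_exact([1.0, 1.0, 0.0], 2).z == 0.0


class TestBiBinomial:
    def test_exact_for_constant_p(self):
        from scipy import stats

        res = pbstats.bibinomial_tail([0.3] * 10, 5)
        assert res.p_upper == pytest.approx(stats.binom.sf(4, 10, 0.3), abs=1e-12)
        assert res.method == "bibinomial"

    def test_k_zero_tail_is_one(self):
        assert pbstats.bibinomial_tail(np.random.default_rng(0).uniform(0, 1, 50), 0).p_upper == 1.0

    def test_two_component_mixture_close_to_exact(self):
        p = np.array([0.01] * 50 + [0.5] * 50)
        mean, sd = pbstats.pb_moments(p)
        k = int(np.ceil(mean + 3 * sd))
        exact = pbstats.pb_tail_exact(p, k).p_upper
        approx = pbstats.bibinomial_tail(p, k).p_upper
        assert abs(math.log10(approx) - math.log10(exact)) <= 0.3

    def test_moments_are_exact_not_approximated(self):
        p = np.random.default_rng(1).uniform(0, 1, 300)
        mean, sd = pbstats.pb_moments(p)
        res = pbstats.bibinomial_tail(p, 150)
        assert res.mean == pytest.approx(mean) and res.sd == pytest.approx(sd)

    def test_fidelity_over_random_vectors(self):
        """|log10 approx - log10 exact| <= 0.5 wherever the exact tail >= 1e-10,
        over the trial-count range where the approximation is dispatched
        (the exact kernel handles vectors of up to 200 trials)."""
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = int(rng.integers(201, 501))
            p = rng.beta(0.5, 2.0, n) if rng.random() < 0.5 else rng.uniform(0, 1, n)
            mean, sd = pbstats.pb_moments(p)
            k = min(n, int(np.ceil(mean + rng.uniform(0, 4) * max(sd, 1e-9))))
            exact = pbstats.pb_tail_exact(p, k).p_upper
            if exact < 1e-10:
                continue
            approx = pbstats.bibinomial_tail(p, k).p_upper
            assert abs(math.log10(max(approx, 1e-300)) - math.log10(exact)) <= 0.5


def test_zscore_calibration():
    """Upper-tail Z threshold calibrates to the normal quantile at large n."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.3, 0.7, 300)
    pmf = pbstats.pb_pmf_exact(p)
    mean, sd = pbstats.pb_moments(p)
    draws = rng.choice(len(pmf), size=2000, p=pmf)
    z = (draws - mean) / sd
    frac = (z >= 1.96).mean()
    mc_se = math.sqrt(0.025 * 0.975 / 2000)
    assert abs(frac - 0.025) <= 3 * mc_se + 0.005  # lattice/skew allowance at n=300


class TestFisher:
    def test_perfectly_exclusive_two_by_two(self):
        # enumeration over all tables with margins (2,2;2,2)
        assert pbstats.fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_balanced_table_is_one(self):
        assert pbstats.fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_one_sided_five_by_five(self):
        # C(5,5) * C(5,0) / C(10,5) = 1/252
        assert pbstats.fisher_exact_2x2([[5, 0], [0, 5]], sided="greater") == pytest.approx(1 / 252)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=4, max_size=4))
    def test_transposition_invariance(self, cells):
        a, b, c, d = cells
        p1 = pbstats.fisher_exact_2x2([[a, b], [c, d]])
        p2 = pbstats.fisher_exact_2x2([[a, c], [b, d]])
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_rejects_negative_cells(self):
        with pytest.raises(ValueError):
            pbstats.fisher_exact_2x2([[1, -1], [0, 2]])


class TestHypergeom:
    def test_single_term_example(self):
        res = pbstats.hypergeom_enrichment(10, 5, 5, 5)
        assert res.neglog10 == pytest.approx(-math.log10(1 / 252), abs=1e-9)
        assert res.significant

    def test_zero_draws_statistic_zero(self):
        res = pbstats.hypergeom_enrichment(10, 5, 5, 0)
        assert res.neglog10 == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_significance_threshold_is_two(self):
        # P = 0.01 exactly maps to a statistic of 2, flagged only when above
        assert not pbstats.hypergeom_enrichment(100, 1, 1, 0).significant

    def test_inconsistent_parameters(self):
        with pytest.raises(ValueError):
            pbstats.hypergeom_enrichment(10, 12, 5, 3)

    def test_group_wrapper_pools_population(self):
        stats_by_group = pbstats.synonymous_enrichment({"A": (5, 5), "B": (5, 0)})
        assert stats_by_group["A"].neglog10 == pytest.approx(-math.log10(1 / 252), abs=1e-9)
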