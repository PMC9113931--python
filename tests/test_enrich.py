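"""Bipartite sample-bin enrichment model, null calibration, cluster calls."""

import numpy as np
import pytest

from ashmscan import enrich
from ashmscan.binscan import assign, make_bins
from ashmscan.io_core import GenomicInterval, SampleMeta, VariantRecord


def _setup(positions_by_sample, territory_len=40, bin_size=10):
    territory = [GenomicInterval("chr1", 0, territory_len)]
    grid = make_bins(territory, bin_size)
    recs = [
        VariantRecord("chr1", pos, "A", "C", s)
        for s, positions in positions_by_sample.items()
        for pos in positions
    ]
    am = assign(recs, grid, sample_ids=sorted(positions_by_sample))
    return grid, am


class TestModel:
    def test_degree_conservation(self):
        _, am = _setup({"s1": [1, 12], "s2": [3, 25], "s3": [5, 33]})
        model = enrich.build_model(am)
        assert model.total_edges == 6
        assert model.bin_degrees.sum() == 6 and model.sample_degrees.sum() == 6

    def test_uniform_null_uses_lengths(self):
        _, am = _setup({"s1": [1, 1, 1, 2]})  # all variants in bin 0
        model = enrich.build_model(am, "uniform")
        assert model.bin_prob(0) == pytest.approx(10 / 40)
        assert model.bin_prob(3) == pytest.approx(10 / 40)

    def test_configuration_null_uses_degrees(self):
        _, am = _setup({"s1": [1, 2, 3, 15]})
        model = enrich.build_model(am, "configuration")
        assert model.bin_prob(0) == pytest.approx(3 / 4)
        assert model.bin_prob(1) == pytest.approx(1 / 4)

    def test_empty_graph_rejected(self):
        _, am = _setup({"s1": []})
        with pytest.raises(ValueError):
            enrich.build_model(am)


class TestEdgeProb:
    def test_zero_degree_sample(self):
        _, am = _setup({"s1": [1], "s2": []})
        model = enrich.build_model(am)
        assert enrich.edge_prob(model, "s2", 0) == 0.0

    def test_closed_form(self):
        # d_s = 3, q_b = 0.1 -> 1 - 0.9^3
        model = enrich.BipartiteModel(
            sample_ids=("s1",),
            sample_degrees=np.array([3]),
            bin_degrees=np.array([1, 9]),
            total_edges=10,
            bin_lengths=np.array([10, 90]),
            territory_length=100,
            null_kind="configuration",
        )
        assert enrich.edge_prob(model, "s1", 0) == pytest.approx(0.271)

    def test_monte_carlo_cross_check(self, rng):
        d_s, q_b, n_mc = 5, 0.22, 200_000
        hits = (rng.random((n_mc, d_s)) < q_b).any(axis=1).mean()
        closed_form = 1 - (1 - q_b) ** d_s
        assert hits == pytest.approx(closed_form, abs=3 * np.sqrt(closed_form / n_mc))


class TestCohortEnrichment:
    def test_planted_bin_sign(self):
        # every focal sample hits bin 0; background samples hit other bins
        positions = {f"f{i}": [1, 11 + 2 * i] for i in range(5)}
        positions.update({f"b{i}": [21, 31] for i in range(5)})
        _, am = _setup(positions)
        model = enrich.build_model(am)
        focal = [s for s in am.sample_ids if s.startswith("f")]
        rest = [s for s in am.sample_ids if s.startswith("b")]
        z_f = {r.bin_idx: r.z for r in enrich.cohort_enrichment(model, am, focal)}
        z_b = {r.bin_idx: r.z for r in enrich.cohort_enrichment(model, am, rest)}
        assert z_f[0] > 0 > z_b[0]

    def test_empty_cohort_rejected(self):
        _, am = _setup({"s1": [1]})
        model = enrich.build_model(am)
        with pytest.raises(ValueError):
            enrich.cohort_enrichment(model, am, [])

    def test_exchangeability_within_cohort(self):
        positions = {"a": [1, 15], "b": [2, 22], "c": [35]}
        _, am = _setup(positions)
        model = enrich.build_model(am)
        r1 = enrich.cohort_enrichment(model, am, ["a", "b"])
        r2 = enrich.cohort_enrichment(model, am, ["b", "a"])
        assert [(r.bin_idx, r.k_obs, r.tail.p_upper) for r in r1] == [
            (r.bin_idx, r.k_obs, r.tail.p_upper) for r in r2
        ]

    def test_permutation_cross_check(self, rng):
        """Empirical tail frequency from independent re-placements matches p_upper."""
        from ashmscan.synthdata import SimConfig, simulate

        bundle = simulate(SimConfig(seed=9, cohorts=(("A", 30), ("B", 60)), genome_length=2000))
        grid = make_bins(bundle.territory, 100)
        am = assign(bundle.records, grid, sample_ids=[m.sample_id for m in bundle.meta])
        model = enrich.build_model(am)
        focal = [m.sample_id for m in bundle.meta if m.cohort == "A"]
        results = enrich.cohort_enrichment(model, am, focal)
        idx = [model.sample_ids.index(s) for s in focal]
        d_s = model.sample_degrees[idx]
        n_mc = 10_000
        for res in results[:5]:
            q = model.bin_prob(res.bin_idx)
            p_vec = 1 - (1 - q) ** d_s.astype(float)
            k_mc = (rng.random((n_mc, len(p_vec))) < p_vec).sum(axis=1)
            emp = (k_mc >= res.k_obs).mean()
            se = np.sqrt(max(res.tail.p_upper * (1 - res.tail.p_upper), 1e-6) / n_mc)
            assert abs(emp - res.tail.p_upper) <= 3 * se + 1e-3

    def test_specificity_monotone_in_multiplier(self):
        """Below carrier saturation (k_obs < cohort size) a stronger planted
        multiplier never weakens the hotspot's focal z; the carrier count is
        monotone throughout."""
        from ashmscan.synthdata import PlantedCluster, SimConfig, simulate

        z_at_hotspot, k_at_hotspot = [], []
        for mult in (1.0, 2.0, 4.0, 6.0, 10.0):
            cfg = SimConfig(
                seed=11,
                planted_clusters=(PlantedCluster(2000, 2100, "MCL", mult),),
            )
            b = simulate(cfg)
            scan = enrich.genome_scan(b.records, b.meta, b.territory, [100], "MCL")
            row = scan[(scan.cohort == "MCL") & (scan.start == 2000)]
            z_at_hotspot.append(float(row.z.iloc[0]))
            k_at_hotspot.append(int(row.k_obs.iloc[0]))
        assert all(b >= a - 0.5 for a, b in zip(z_at_hotspot, z_at_hotspot[1:]))
        assert z_at_hotspot[-1] > z_at_hotspot[0] + 2
        assert all(b >= a for a, b in zip(k_at_hotspot, k_at_hotspot[1:]))


class TestGenomeScan:
    def test_planted_hotspot_ranks_first(self):
        from ashmscan.synthdata import PlantedCluster, SimConfig, simulate

        b = simulate(SimConfig(seed=5, planted_clusters=(PlantedCluster(2000, 2100, "MCL", 10.0),)))
        scan = enrich.genome_scan(b.records, b.meta, b.territory, [100], "MCL")
        top = scan[scan.cohort == "MCL"].iloc[0]
        assert (top.start, top.end) == (2000, 2100)

    def test_needs_two_cohorts(self):
        meta = [SampleMeta("s1", "A"), SampleMeta("s2", "A")]
        with pytest.raises(ValueError):
            enrich.genome_scan([], meta, [GenomicInterval("chr1", 0, 10)], [10], "A")


class TestClusterCalls:
    def _grids(self):
        return [make_bins([GenomicInterval("chr1", 0, 30)], 10)]

    def test_focal_specific(self):
        grids = self._grids()
        calls = enrich.call_specific_clusters(
            [np.array([0.0, 4.0, 0.0])], [np.array([0.0, 0.5, 0.0])], grids
        )
        assert len(calls) == 1
        c = calls[0]
        assert (c.interval.start, c.interval.end, c.specificity) == (10, 20, "focal-specific")

    def test_shared_cluster(self):
        grids = self._grids()
        calls = enrich.call_specific_clusters(
            [np.array([0.0, 4.0, 0.0])], [np.array([0.0, 4.0, 0.0])], grids
        )
        assert calls[0].specificity == "shared"

    def test_background_only_cluster(self):
        grids = self._grids()
        calls = enrich.call_specific_clusters(
            [np.array([0.0, 0.0, 0.0])], [np.array([0.0, 4.0, 0.0])], grids
        )
        assert calls[0].specificity == "background"

    def test_gap_merging(self):
        grids = [make_bins([GenomicInterval("chr1", 0, 30)], 2)]
        z = np.array([4.0, 0.0, 4.0] + [0.0] * 12)  # 2 bp gap between hot bins
        calls = enrich.call_specific_clusters([z], [np.zeros(15)], grids, merge_gap=2)
        assert len(calls) == 1 and (calls[0].interval.start, calls[0].interval.end) == (0, 6)
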