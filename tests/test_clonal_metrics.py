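import itertools

import numpy as np
import pytest

from clonaldyn import clonal_metrics as cm
from clonaldyn import evolution_sim as es


def brute_force_kmeans_ss(values, weights, k):
    """Exhaustive minimal weighted within-cluster SS over all assignments of
    distinct values to k clusters (independent of the DP implementation)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    n = len(values)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        ss = 0.0
        for c in range(k):
            mask = np.array([l == c for l in labels])
            w = weights[mask]
            v = values[mask]
            mu = np.average(v, weights=w)
            ss += float(np.sum(w * (v - mu) ** 2))
        best = min(best, ss)
    return best


def fake_result(burden_counts: dict[int, int]) -> es.SimulationResult:
    """A SimulationResult with prescribed burden -> cell-count composition."""
    clones = []
    for i, (burden, count) in enumerate(sorted(burden_counts.items())):
        clones.append(
            es.CloneRecord(
                clone_id=i,
                parent_id=None,
                driver_mutations=frozenset(),
                neutral_mutations=frozenset(f"mut{burden}_{j}" for j in range(burden)),
                k_neutral=burden,
                s=0.0,
                count=count,
            )
        )
    params = es.SimulationParams(capacity=1e7, n0=1e5)
    return es.SimulationResult(
        params=params,
        trajectory=np.array([sum(burden_counts.values())]),
        final_clones=clones,
        mutation_registry={},
    )


class TestKmeans1D:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_on_random_sets(self, k):
        rng = np.random.default_rng(k)
        for _ in range(5):
            vals = rng.choice(np.arange(10), size=6, replace=False).astype(float)
            wts = rng.integers(1, 50, size=6).astype(float)
            labels, cents = cm.kmeans_1d(vals, wts, k)
            ss = 0.0
            for c in range(k):
                mask = labels == c
                mu = np.average(vals[mask], weights=wts[mask])
                ss += float(np.sum(wts[mask] * (vals[mask] - mu) ** 2))
            assert ss == pytest.approx(brute_force_kmeans_ss(vals, wts, k), abs=1e-9)

    def test_centroids_sorted(self):
        labels, cents = cm.kmeans_1d([5.0, 0.0, 9.0, 1.0], [1, 1, 1, 1], 2)
        assert list(cents) == sorted(cents)
        assert labels[np.argmin([5.0, 0.0, 9.0, 1.0])] == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            cm.kmeans_1d([], [], 2)
        with pytest.raises(ValueError):
            cm.kmeans_1d([1.0], [1.0], 0)


class TestClusterByBurden:
    def test_uniform_population_single_cluster(self):
        res = fake_result({0: 500})
        out = cm.cluster_by_burden(res)
        assert out.mrca_fraction == pytest.approx(100.0)
        assert len(out.centroids) == 1

    def test_two_mode_population(self):
        # 70 ancestral cells vs 30 cells carrying 5 mutations
        res = fake_result({0: 70, 5: 30})
        out = cm.cluster_by_burden(res)
        assert out.mrca_fraction == pytest.approx(70.0)
        assert out.centroids[out.mrca_cluster] == pytest.approx(0.0)
        assert cm.mrca_fraction(res) == pytest.approx(70.0)

    def test_three_mode_population_low_burden_cluster(self):
        res = fake_result({0: 50, 1: 10, 8: 40})
        out = cm.cluster_by_burden(res)
        # the MRCA cluster contains the low-burden mode; fraction is
        # cell-weighted (50 or 60 depending on whether burden-1 joins)
        members = [
            cid for cid, lab in out.cluster_assignments.items()
            if lab == out.mrca_cluster
        ]
        assert 0 in members
        assert out.mrca_fraction in (pytest.approx(50.0), pytest.approx(60.0))
        # burden-8 cells never join the ancestral cluster
        assert out.cluster_assignments[2] != out.mrca_cluster

    def test_weighted_equals_exploded_per_cell(self):
        comp = {0: 350, 1: 60, 2: 12, 6: 78}
        res = fake_result(comp)
        out = cm.cluster_by_burden(res)
        exploded = np.repeat(
            [b for b in sorted(comp)], [comp[b] for b in sorted(comp)]
        ).astype(float)
        k = len(out.centroids)
        labels, cents = cm.kmeans_1d(exploded, np.ones_like(exploded), k)
        mrca_frac = 100.0 * np.mean(labels == int(np.argmin(cents)))
        assert out.mrca_fraction == pytest.approx(mrca_frac)

    def test_empty_population_errors(self):
        res = fake_result({0: 1})
        res.final_clones = []
        with pytest.raises(ValueError):
            cm.cluster_by_burden(res)


class TestDistinctMutations:
    def test_no_mutations(self):
        assert cm.distinct_mutations(fake_result({0: 100})) == 0

    def test_counts_only_surviving(self):
        res = fake_result({0: 10, 3: 5})
        # registry may contain extinct mutations; only carried IDs count
        res.mutation_registry = {f"x{i}": None for i in range(7)}
        assert cm.distinct_mutations(res) == 3

    def test_monotone_in_mutation_rate_seed_paired(self, sim_catalog):
        lo, hi = [], []
        for seed in range(8):
            for m, acc in ((0.01, lo), (0.04, hi)):
                p = es.SimulationParams(
                    m=m, p=0.01, r=2.0, capacity=5e3, n0=100,
                    generations=20, seed=seed,
                )
                acc.append(cm.distinct_mutations(es.run_simulation(p, sim_catalog)))
        assert np.mean(hi) > np.mean(lo)


class TestSummarizeScan:
    def test_grey_section_mean(self):
        out = cm.summarize_scan({2.0: {"mrca_fraction": [90, 92, 94]}})
        rows = out.to_frame()
        assert rows.section.unique().tolist() == ["grey"]
        assert rows.value.iloc[0] == pytest.approx(92.0)
        assert rows.replicate_index.isna().all()

    def test_black_section_cluster_centroids(self):
        vals = [80.0] * 10 + [40.0] * 10
        out = cm.summarize_scan({3.2: {"mrca_fraction": vals}})
        rows = out.to_frame()
        assert set(rows.section) == {"black"}
        assert sorted(rows.value) == [pytest.approx(40.0), pytest.approx(80.0)]

    def test_red_section_keeps_replicates(self):
        vals = [10.0, 20.0, 30.0]
        out = cm.summarize_scan({3.8: {"mrca_fraction": vals}})
        rows = out.to_frame()
        assert rows.value.tolist() == vals
        assert rows.replicate_index.tolist() == [0, 1, 2]

    def test_boundary_convention(self):
        assert cm.summarize_scan({3.0: {"x": [1.0]}}).section(3.0) == "black"
        assert cm.summarize_scan({3.5: {"x": [1.0]}}).section(3.5) == "black"
        assert cm.summarize_scan({2.999: {"x": [1.0]}}).section(2.999) == "grey"
        assert cm.summarize_scan({3.501: {"x": [1.0]}}).section(3.501) == "red"

    def test_sections_partition_grid(self):
        grid = np.round(np.arange(2.0, 4.0, 0.1), 2)
        out = cm.summarize_scan({float(r): {"x": [1.0, 2.0]} for r in grid})
        df = out.to_frame()
        for r, sub in df.groupby("r"):
            assert sub.section.nunique() == 1

    def test_missing_replicates_error(self):
        with pytest.raises(ValueError):
            cm.summarize_scan({2.0: {"x": []}})
        with pytest.raises(ValueError):
            cm.summarize_scan({})
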