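"""End-state clonal-landscape metrics.

All the cells at the end of a run are clustered by their mutational burden
(total acquired mutation count); the least-mutated cluster is taken to
represent the most recent common ancestors (MRCA), and the percentage of
cells in it is the MRCA fraction.  Clustering is exact 1-D k-means via
dynamic programming on the distinct burden values weighted by cell counts
(deterministic and optimal in one dimension, unlike Lloyd's algorithm), with
the number of clusters chosen in 1..max_k by the cell-weighted mean
silhouette (ties toward fewer clusters).

A growth-rate scan is summarized with three display conventions mirroring
how the bifurcation structure is usually drawn: below the first
period-doubling (r < 3) replicate values collapse to their mean ("grey"),
in the period-doubling window (3 <= r <= 3.5) they are reduced to 1-D
cluster centroids ("black", one branch per centroid), and beyond ("red")
every replicate value is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .evolution_sim import SimulationResult

__all__ = [
    "ClusteringResult",
    "BifurcationSummary",
    "kmeans_1d",
    "choose_k_silhouette",
    "cluster_by_burden",
    "mrca_fraction",
    "distinct_mutations",
    "summarize_scan",
]

GREY_BLACK_BOUNDARY = 3.0
BLACK_RED_BOUNDARY = 3.5


@dataclass(frozen=True)
class ClusteringResult:
    """1-D clustering of cell-weighted burden values.

    ``mrca_cluster`` is the label (index) of the cluster with the smallest
    centroid; ``mrca_fraction`` is the percentage (0-100) of cells in it.
    """

    cluster_assignments: dict[int, int]  # clone_id -> cluster label
    centroids: tuple[float, ...]
    mrca_cluster: int
    mrca_fraction: float


def _weighted_ss_prefix(values: np.ndarray, weights: np.ndarray):
    """Prefix sums enabling O(1) within-segment weighted SS queries."""
    w = np.concatenate([[0.0], np.cumsum(weights)])
    wv = np.concatenate([[0.0], np.cumsum(weights * values)])
    wv2 = np.concatenate([[0.0], np.cumsum(weights * values * values)])

    def cost(i: int, j: int) -> float:
        # weighted SS of values[i..j] inclusive
        W = w[j + 1] - w[i]
        if W <= 0:
            return 0.0
        S = wv[j + 1] - wv[i]
        S2 = wv2[j + 1] - wv2[i]
        return max(S2 - S * S / W, 0.0)

    return cost


def kmeans_1d(
    values: Sequence[float], weights: Sequence[float], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal weighted k-means in one dimension by dynamic programming.

    ``values`` need not be sorted or unique.  Returns ``(labels, centroids)``
    where labels[i] is the cluster of values[i] and centroids are in
    increasing order (cluster 0 has the smallest centroid).  Exact: minimizes
    the weighted within-cluster sum of squares over all contiguous partitions
    of the sorted values, which in 1-D contains the global optimum.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("cannot cluster an empty set")
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    if k < 1:
        raise ValueError("k must be >= 1")

    # collapse to distinct sorted values
    uniq, inv = np.unique(v, return_inverse=True)
    uw = np.zeros_like(uniq)
    np.add.at(uw, inv, w)
    n = uniq.size
    k = min(k, n)

    cost = _weighted_ss_prefix(uniq, uw)
    INF = math.inf
    # dp[c][j] = optimal cost of clustering uniq[0..j] into c+1 clusters
    dp = np.full((k, n), INF)
    back = np.zeros((k, n), dtype=int)
    for j in range(n):
        dp[0][j] = cost(0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, arg = INF, c
            for i in range(c, j + 1):
                val = dp[c - 1][i - 1] + cost(i, j)
                if val < best:
                    best, arg = val, i
            dp[c][j] = best
            back[c][j] = arg

    # recover boundaries
    bounds = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = back[c][j]
        bounds.append(i)
        j = i - 1
    bounds = sorted(bounds)

    labels_uniq = np.zeros(n, dtype=int)
    for b in bounds:
        labels_uniq[b:] += 1
    centroids = np.array(
        [
            np.average(uniq[labels_uniq == c], weights=uw[labels_uniq == c])
            for c in range(k)
        ]
    )
    return labels_uniq[inv], centroids


def _mean_silhouette(
    uniq: np.ndarray, uw: np.ndarray, labels: np.ndarray, k: int
) -> float:
    """Cell-weighted mean silhouette for a clustering of distinct values with
    multiplicities.  Weights act as cell counts: distances between co-located
    cells are zero and the usual (n_A - 1) self-exclusion applies."""
    tot_w = np.array([uw[labels == c].sum() for c in range(k)])
    s_sum = 0.0
    for i, v in enumerate(uniq):
        c = labels[i]
        same = labels == c
        if tot_w[c] <= 1:
            continue  # singleton cell: silhouette 0 by convention
        a = np.sum(uw[same] * np.abs(uniq[same] - v)) / (tot_w[c] - 1)
        b = math.inf
        for other in range(k):
            if other == c or tot_w[other] == 0:
                continue
            mask = labels == other
            b = min(b, np.sum(uw[mask] * np.abs(uniq[mask] - v)) / tot_w[other])
        denom = max(a, b)
        if denom > 0:
            s_sum += uw[i] * (b - a) / denom
    return s_sum / uw.sum()


def choose_k_silhouette(
    values: Sequence[float], weights: Sequence[float], max_k: int = 6
) -> int:
    """Number of clusters in 1..max_k maximizing the weighted silhouette.

    Single-valued populations give k = 1 (silhouette undefined otherwise);
    ties break toward the smaller k.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    uniq, inv = np.unique(v, return_inverse=True)
    uw = np.zeros_like(uniq)
    np.add.at(uw, inv, w)
    n_distinct = uniq.size
    if n_distinct == 1:
        return 1
    best_k, best_s = 2, -math.inf
    for k in range(2, min(max_k, n_distinct) + 1):
        labels, _ = kmeans_1d(uniq, uw, k)
        s = _mean_silhouette(uniq, uw, labels, k)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


def cluster_by_burden(
    result: SimulationResult, max_k: int = 6
) -> ClusteringResult:
    """Cluster end-state cells by mutational burden (cell-count weighted)."""
    clones = [c for c in result.final_clones if c.count > 0]
    if not clones:
        raise ValueError("empty population: nothing to cluster")
    burdens = np.array([c.burden for c in clones], dtype=float)
    weights = np.array([c.count for c in clones], dtype=float)
    k = choose_k_silhouette(burdens, weights, max_k=max_k)
    labels, centroids = kmeans_1d(burdens, weights, k)
    mrca = int(np.argmin(centroids))
    frac = 100.0 * weights[labels == mrca].sum() / weights.sum()
    return ClusteringResult(
        cluster_assignments={c.clone_id: int(l) for c, l in zip(clones, labels)},
        centroids=tuple(float(c) for c in centroids),
        mrca_cluster=mrca,
        mrca_fraction=float(frac),
    )


def mrca_fraction(result: SimulationResult, max_k: int = 6) -> float:
    """Percentage of end-state cells in the least-mutated burden cluster."""
    return cluster_by_burden(result, max_k=max_k).mrca_fraction


def distinct_mutations(result: SimulationResult) -> int:
    """Number of distinct mutation IDs carried by at least one surviving
    cell at the end of the run."""
    return len(result.surviving_mutation_ids())


@dataclass(frozen=True)
class BifurcationSummary:
    """Scan summary with the grey/black/red section convention.

    ``rows`` is a list of (r, section, statistic_name, value,
    replicate_index) tuples; aggregated sections carry ``None`` for the
    replicate index.  Boundary convention: r = 3.0 and r = 3.5 both belong to
    the black section.
    """

    r_grid: tuple[float, ...]
    rows: tuple[tuple[float, str, str, float, int | None], ...]

    def section(self, r: float) -> str:
        return _section(r)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows,
            columns=["r", "section", "statistic_name", "value", "replicate_index"],
        )


def _section(r: float) -> str:
    if r < GREY_BLACK_BOUNDARY:
        return "grey"
    if r <= BLACK_RED_BOUNDARY:
        return "black"
    return "red"


def summarize_scan(
    per_r_metrics: Mapping[float, Mapping[str, Sequence[float]]],
    max_k: int = 6,
) -> BifurcationSummary:
    """Reduce replicate metrics over a growth-rate grid to the three-section
    display convention: mean (grey, r < 3), 1-D cluster centroids (black,
    3 <= r <= 3.5), all replicate values (red, r > 3.5)."""
    if not per_r_metrics:
        raise ValueError("no scan metrics supplied")
    rows: list[tuple[float, str, str, float, int | None]] = []
    for r in sorted(per_r_metrics):
        metrics = per_r_metrics[r]
        sec = _section(r)
        for name, vals in metrics.items():
            vals = np.asarray(list(vals), dtype=float)
            if vals.size == 0:
                raise ValueError(f"no replicates for r={r}, metric {name!r}")
            if sec == "grey":
                rows.append((r, sec, name, float(vals.mean()), None))
            elif sec == "black":
                k = choose_k_silhouette(vals, np.ones_like(vals), max_k=max_k)
                _, cents = kmeans_1d(vals, np.ones_like(vals), k)
                for c in cents:
                    rows.append((r, sec, name, float(c), None))
            else:
                for i, v in enumerate(vals):
                    rows.append((r, sec, name, float(v), i))
    return BifurcationSummary(
        r_grid=tuple(sorted(per_r_metrics)), rows=tuple(rows)
    )
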