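import numpy as np
import pandas as pd
import pytest

from comodmap import (
    ExpressionMatrix,
    SimExpressionParams,
    simulate_expression,
    simulate_ortholog_table,
)


@pytest.fixture(scope="session")
def small_matrix() -> ExpressionMatrix:
    """Deterministic 10 genes x 20 cells count matrix with 3 cell types."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(5.0, size=(10, 20)).astype(float)
    return ExpressionMatrix(
        counts,
        [f"g{i}" for i in range(10)],
        [f"c{i}" for i in range(20)],
        [("glia", "neuron_a", "neuron_b")[i % 3] for i in range(20)],
    )


@pytest.fixture(scope="session")
def planted_sim():
    """One seeded 200x2000 simulation with a 26-gene planted module."""
    return simulate_expression(SimExpressionParams(seed=7))


@pytest.fixture(scope="session")
def composition_table():
    """Ortholog table realizing the published mapping composition."""
    return simulate_ortholog_table(163, (37, 17), (31, 107), min_score=3, seed=11)


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Naive rank-then-Pearson Spearman, independent of the implementation.

    Average ranks computed by explicit tie grouping; Pearson by the textbook
    moment formula.
    """
    def avg_ranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def linkage_oracle(dist: np.ndarray, method: str = "complete") -> list[float]:
    """Brute-force O(n^3) agglomeration; returns sorted merge heights."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                pair_d = [dist[i, j] for i in clusters[a] for j in clusters[b]]
                if method == "complete":
                    d = max(pair_d)
                elif method == "average":
                    d = sum(pair_d) / len(pair_d)
                else:
                    d = min(pair_d)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) by integer combinatorics (independent of scipy)."""
    from math import comb

    total = comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return acc / total
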