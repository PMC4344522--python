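"""Independent oracles used by the test suite.

Everything here is deliberately brute-force (enumeration, exhaustive tail
sums, explicit min-over-tail) and independent of the library code paths it
checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.optimize import nnls


# ---------------------------------------------------------------------------
# unrooted binary topologies and least-squares branch fitting
# ---------------------------------------------------------------------------

def enumerate_topologies(n_taxa: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies over taxa 0..n-1 as edge lists.

    Built by sequential insertion: each new taxon subdivides every existing
    edge.  Internal node ids start at n_taxa.  (1, 3, 15, 105, ... trees.)
    """
    if n_taxa < 3:
        raise ValueError("need >=3 taxa")
    base = [[(n_taxa, 0), (n_taxa, 1), (n_taxa, 2)]]
    next_internal = n_taxa + 1
    trees = base
    for taxon in range(3, n_taxa):
        grown = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                new_edges = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, taxon)]
                grown.append(new_edges)
        next_internal += 1
        trees = grown
    return trees


def topology_bipartitions(edges: list[tuple[int, int]], n_taxa: int) -> set[frozenset]:
    """Canonical internal-edge leaf splits (side not containing taxon 0)."""
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def leaves_beyond(u: int, v: int) -> frozenset:
        # leaves reachable from v without crossing edge (u, v)
        seen, stack, out = {u, v}, [v], []
        while stack:
            node = stack.pop()
            if node < n_taxa:
                out.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    all_leaves = frozenset(range(n_taxa))
    splits = set()
    for u, v in edges:
        if u >= n_taxa and v >= n_taxa:
            side = leaves_beyond(u, v)
            if 0 in side:
                side = all_leaves - side
            if 2 <= len(side) <= n_taxa - 2:
                splits.add(side)
    return splits


def path_edge_matrix(edges: list[tuple[int, int]], n_taxa: int) -> np.ndarray:
    """Rows = taxon pairs (i<j), columns = edges; 1 where the edge lies on
    the path between the pair."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for e_idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, e_idx))
        adj.setdefault(v, []).append((u, e_idx))

    def path_edges(src: int, dst: int) -> list[int]:
        prev = {src: (None, None)}
        stack = [src]
        while stack:
            node = stack.pop()
            if node == dst:
                break
            for nb, e_idx in adj[node]:
                if nb not in prev:
                    prev[nb] = (node, e_idx)
                    stack.append(nb)
        out, node = [], dst
        while prev[node][0] is not None:
            out.append(prev[node][1])
            node = prev[node][0]
        return out

    pairs = list(itertools.combinations(range(n_taxa), 2))
    mat = np.zeros((len(pairs), len(edges)))
    for row, (i, j) in enumerate(pairs):
        for e_idx in path_edges(i, j):
            mat[row, e_idx] = 1.0
    return mat


def best_ls_topology(d: np.ndarray) -> tuple[int, list[list[tuple[int, int]]]]:
    """Exhaustive minimum least-squares topology search (non-negative branch
    lengths) over all unrooted binary topologies.  Returns the argmin index
    and the topology list searched."""
    n = d.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    dvec = np.array([d[i, j] for i, j in pairs])
    topologies = enumerate_topologies(n)
    residuals = []
    for edges in topologies:
        mat = path_edge_matrix(edges, n)
        _, res = nnls(mat, dvec)
        residuals.append(res)
    return int(np.argmin(residuals)), topologies


def additive_matrix_from_topology(
    edges: list[tuple[int, int]], n_taxa: int, rng: np.random.Generator,
    low: float = 0.05, high: float = 1.0,
) -> np.ndarray:
    """Pairwise path distances from random positive branch lengths."""
    lengths = rng.uniform(low, high, size=len(edges))
    mat = path_edge_matrix(edges, n_taxa)
    dvec = mat @ lengths
    d = np.zeros((n_taxa, n_taxa))
    for (i, j), val in zip(itertools.combinations(range(n_taxa), 2), dvec):
        d[i, j] = d[j, i] = val
    return d


# ---------------------------------------------------------------------------
# step-up FDR, explicit min-over-tail
# ---------------------------------------------------------------------------

def bh_bruteforce(pvals: np.ndarray) -> np.ndarray:
    """q_i = min over {j : p_j >= p_i} of m p_j / rank(p_j), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.empty(m)
    for pos in range(m):
        tail = [m * ranked[j] / (j + 1) for j in range(pos, m)]
        q[pos] = min(1.0, min(tail))
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# exact binomial two-sided p by exhaustive tail sum
# ---------------------------------------------------------------------------

def binom_two_sided_bruteforce(k: int, n: int, p: float = 0.5) -> float:
    """Sum of P(X = j) over all j whose probability does not exceed P(X = k)."""
    pmf = [comb(n, j) * p ** j * (1 - p) ** (n - j) for j in range(n + 1)]
    threshold = pmf[k] * (1 + 1e-12)
    return float(min(1.0, sum(q for q in pmf if q <= threshold)))
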