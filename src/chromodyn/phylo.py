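"""Distance-based phylogenetics for linker-histone globular domains.

Pipeline: uncorrected p-distances from a pre-aligned amino-acid alignment,
neighbor-joining (Saitou-Nei) tree construction, bootstrap support from
column resampling, and outgroup rooting (by convention on the
*Dictyostelium discoideum* H1 globular domain, the most basal H1-like
sequence available).

Trees are ``dendropy.Tree`` objects; bootstrap supports are mapped onto the
internal branches of the full-data NJ tree (the display convention of the
common distance-phylogenetics packages), not onto a consensus tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "SupportTree",
    "p_distance",
    "nj_tree",
    "bootstrap_support",
    "root_tree",
    "tree_bipartitions",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned amino-acid sequences (gap character '-')."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        if len(self.rows) == 0:
            raise ValueError("empty alignment")
        length = len(self.rows[0])
        for name, row in zip(self.taxa, self.rows):
            if len(row) != length:
                raise ValueError(f"ragged alignment: row {name!r} has length {len(row)}")
            bad = set(row.upper()) - _AA - {_GAP}
            if bad:
                raise ValueError(f"row {name!r}: invalid characters {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, columns: Iterable[int]) -> "Alignment":
        cols = list(columns)
        rows = tuple("".join(row[c] for c in cols) for row in self.rows)
        return Alignment(taxa=self.taxa, rows=rows)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distances with a zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape must match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("diagonal must be zero")


@dataclass(frozen=True)
class SupportTree:
    """An NJ tree with bootstrap supports on its internal branches."""

    tree: dendropy.Tree
    supports: dict          # canonical bipartition (frozenset) -> % support
    n_reps: int
    n_discarded: int = 0


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance(aln: Alignment, gap_policy: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites between each pair of aligned rows.

    ``pairwise`` deletion (default) compares, for each pair, only the
    columns where both rows are non-gap; ``complete`` deletion first drops
    every column containing a gap in any row.  A pair with no comparable
    site is an error naming the pair.
    """
    if aln.n_taxa < 2:
        raise ValueError("need >=2 taxa")
    if gap_policy not in ("pairwise", "complete"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    rows = np.array([list(r.upper()) for r in aln.rows])
    if gap_policy == "complete":
        keep = ~(rows == _GAP).any(axis=0)
        rows = rows[:, keep]
    nongap = rows != _GAP
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            diff = int((rows[i, both] != rows[j, both]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(taxa=aln.taxa, d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Standard Q-criterion agglomeration; ties on Q are broken by the lowest
    (i, j) index pair.  A negative pendant branch length is clipped to zero
    with the deficit transferred to its sister so their sum stays d(i,j).
    Returns an unrooted tree (trifurcating at the seed node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >=3 taxa")
    tns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes = []
    for name in dm.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
    d = dm.d.copy()
    active = list(range(n))  # indices into the (growing) distance matrix
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    def D(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))]

    next_idx = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D(i, j) - li
        li, lj = _clip_pair(li, lj)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(next_idx, k), max(next_idx, k))] = 0.5 * (D(i, k) + D(j, k) - D(i, j))
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    a, b, c = active
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    tree = dendropy.Tree(taxon_namespace=tns)
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = max(length, 0.0)
        tree.seed_node.add_child(nodes[idx])
    tree.is_rooted = False
    return tree


def _clip_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical internal-branch leaf bipartitions of a tree.

    Each internal edge splits the leaves in two; the split is represented
    by the side not containing the alphabetically first taxon, so the
    representation is invariant to rooting and taxon order.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else leaves - below
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    gap_policy: str = "pairwise",
) -> SupportTree:
    """Bootstrap supports mapped onto the full-data NJ tree.

    Columns are resampled with replacement for each replicate (the random
    stream is keyed to the replicate index, so supports do not depend on
    taxon input order); NJ is run on each resample and the support of each
    internal branch of the full-data tree is the percentage of replicate
    trees containing the same leaf bipartition.  Replicates in which some
    pair has no comparable site under pairwise deletion are discarded and
    counted; a warning is raised if more than 1% are discarded.
    """
    if n_reps < 1:
        raise ValueError("need >=1 replicate")
    full = nj_tree(p_distance(aln, gap_policy=gap_policy))
    target = tree_bipartitions(full)
    counts = {bp: 0 for bp in target}
    discarded = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        resampled = aln.resample_columns(cols)
        try:
            rep_tree = nj_tree(p_distance(resampled, gap_policy=gap_policy))
        except ValueError:
            discarded += 1
            continue
        rep_splits = tree_bipartitions(rep_tree)
        for bp in target:
            if bp in rep_splits:
                counts[bp] += 1
    valid = n_reps - discarded
    if valid == 0:
        raise ValueError("all bootstrap replicates were discarded")
    if discarded > 0.01 * n_reps:
        warnings.warn(f"{discarded}/{n_reps} bootstrap replicates discarded")
    supports = {bp: 100.0 * c / valid for bp, c in counts.items()}
    _annotate_supports(full, supports)
    return SupportTree(tree=full, supports=supports, n_reps=n_reps, n_discarded=discarded)


def _annotate_supports(tree: dendropy.Tree, supports: dict) -> None:
    """Write integer support percentages as internal node labels."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else leaves - below
        if side in supports:
            node.label = str(int(round(supports[side])))


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_tree(tree: dendropy.Tree, outgroup_taxon: str) -> dendropy.Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge.

    The unrooted leaf bipartitions are preserved; the outgroup leaf becomes
    one child of the new root.  The input tree is not modified.
    """
    rooted = tree.clone(depth=1)
    matches = [l for l in rooted.leaf_node_iter() if l.taxon.label == outgroup_taxon]
    if not matches:
        raise ValueError(f"unknown taxon {outgroup_taxon!r}")
    leaf = matches[0]
    length = leaf.edge.length if leaf.edge.length is not None else 0.0
    rooted.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted
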