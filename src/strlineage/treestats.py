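"""Support values and annotation statistics on lineage trees.

Three ingredients quantify confidence and biology on a reconstructed tree:

* **Bootstrap by locus resampling** — the reconstruction is repeated on
  panels drawn with replacement from the original loci (same panel size per
  replicate, so on average ``(1 - 1/L)^L`` of the distinct loci, roughly a
  third, are absent from each replicate).
* **Transfer bootstrap expectation (TBE)** — per internal branch,
  ``1 - mean(transfer index) / (p - 1)`` over replicates, where the transfer
  index is the minimum number of leaves whose reassignment turns some branch
  of the replicate into the reference branch, and ``p`` is the size of the
  branch's lighter side. Computed by exhaustive scan over replicate branches;
  exact at the tree sizes this package targets.
* **Hypergeometric clade enrichment** — for each internal node, the exact
  upper-tail probability that a clade of its size contains at least the
  observed number of leaves of a given annotation under uniform sampling
  from all leaves. Displayed as branch widths (wider = smaller p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UncomputableDistanceError
from .panel import STRPanel
from .trees import (
    ROOT_LEAF,
    _edges_to_newick,
    _mismatch_distance,
    leaf_depths,
    neighbor_joining,
    read_newick,
)


# ------------------------------------------------------------- bipartitions

@dataclass(frozen=True)
class Bipartition:
    """Leaf-set split induced by one tree edge, in canonical form.

    ``side`` is the lighter of the two sides (ties broken toward the
    lexicographically smaller side), ``leaves`` the full leaf set.
    """

    side: frozenset[str]
    leaves: frozenset[str]

    @classmethod
    def canonical(cls, side, leaves) -> "Bipartition":
        side, leaves = frozenset(side), frozenset(leaves)
        if not side or side == leaves:
            raise ConfigError("bipartition sides must both be non-empty")
        other = leaves - side
        if len(other) < len(side) or (
            len(other) == len(side) and sorted(other) < sorted(side)
        ):
            side = other
        return cls(side=side, leaves=leaves)

    @property
    def lighter_size(self) -> int:
        return len(self.side)


def tree_bipartitions(
    tree: dendropy.Tree, include_trivial: bool = False
) -> list[tuple[dendropy.Node, Bipartition]]:
    """Bipartitions of every edge (internal only unless ``include_trivial``).

    The root itself induces no bipartition and is skipped.
    """
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.is_leaf():
            if include_trivial:
                out.append(
                    (node, Bipartition.canonical({node.taxon.label}, all_leaves))
                )
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if clade == all_leaves:
            continue  # unifurcation above the full leaf set: not a split
        out.append((node, Bipartition.canonical(clade, all_leaves)))
    return out


def transfer_index(b: Bipartition, replicate: dendropy.Tree) -> int:
    """Minimum leaves to move so some replicate branch matches ``b``.

    Exhaustive scan over every replicate edge (trivial ones included), taking
    the Hamming distance between split indicator vectors minimized over
    complementation. Bounded above by ``p - 1`` for lighter-side size ``p``.
    """
    rep_leaves = frozenset(l.taxon.label for l in replicate.leaf_node_iter())
    if rep_leaves != b.leaves:
        raise ConfigError("replicate leaf set differs from the reference bipartition's")
    n = len(b.leaves)
    best = len(b.side)  # distance to the empty split
    for _, rb in tree_bipartitions(replicate, include_trivial=True):
        h = len(b.side.symmetric_difference(rb.side))
        best = min(best, h, n - h)
        if best == 0:
            break
    return best


# ----------------------------------------------------------------- bootstrap

def resample_locus_indices(n_loci: int, rng: np.random.Generator) -> np.ndarray:
    """Panel-size draw of locus indices with replacement (one bootstrap replicate)."""
    return rng.integers(0, n_loci, size=n_loci)


@dataclass
class BootstrapResult:
    trees: list[dendropy.Tree]
    skipped: list[int]  # replicate indices with an uncomputable distance pair
    dropped_locus_fraction: list[float]  # distinct-locus loss per usable replicate


def bootstrap_trees(
    matrix: pd.DataFrame,
    root_group,
    panel: STRPanel,
    B: int,
    seed: int,
) -> BootstrapResult:
    """Rebuild the tree on ``B`` locus-resampled replicates.

    Each replicate draws panel-size loci with replacement, recomputes
    distances and the root profile on the resampled columns, and reruns
    neighbor joining. Replicates with a cell pair sharing no genotyped locus
    are skipped and reported. Deterministic per (seed, replicate index).
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    labels = [str(i) for i in matrix.index]
    group = [str(g) for g in root_group]
    X = matrix[panel.ids].to_numpy(dtype=float)
    refs = np.array([l.ref_repeats for l in panel], dtype=float)
    group_rows = [labels.index(g) for g in group]
    L = len(panel)
    trees: list[dendropy.Tree] = []
    skipped: list[int] = []
    dropped: list[float] = []
    for rep in range(B):
        rng = np.random.default_rng([seed, rep])
        idx = resample_locus_indices(L, rng)
        Xb = X[:, idx]
        try:
            D = _mismatch_distance(Xb, labels)
        except UncomputableDistanceError:
            skipped.append(rep)
            continue
        dropped.append(1.0 - len(set(idx.tolist())) / L)
        # root profile on the resampled loci (reference fallback per column)
        sub = Xb[group_rows, :]
        called = (~np.isnan(sub)).sum(axis=0)
        sums = np.nansum(sub, axis=0)
        means = sums / np.maximum(called, 1)
        prof = np.where(called > 0, np.floor(means + 0.5), refs[idx])
        valid = ~np.isnan(Xb)
        diff = (Xb != prof[None, :]) & valid
        shared = valid.sum(axis=1)
        if (shared == 0).any():
            skipped.append(rep)
            continue
        d_root = diff.sum(axis=1) / shared
        aug = np.zeros((len(labels) + 1, len(labels) + 1))
        aug[:-1, :-1] = D
        aug[-1, :-1] = d_root
        aug[:-1, -1] = d_root
        dist = pd.DataFrame(aug, index=labels + [ROOT_LEAF], columns=labels + [ROOT_LEAF])
        edges = neighbor_joining(dist)
        neighbors = [a if b == ROOT_LEAF else b for a, b, _ in edges if ROOT_LEAF in (a, b)]
        newick = _edges_to_newick(
            edges, neighbors[0], drop={ROOT_LEAF}, leaf_names=set(labels)
        )
        trees.append(read_newick(newick))
    return BootstrapResult(trees=trees, skipped=skipped, dropped_locus_fraction=dropped)


def tbe_support(
    reference: dendropy.Tree, replicates: list[dendropy.Tree]
) -> dict[int, float]:
    """Attach transfer-bootstrap-expectation supports to the reference tree.

    For each internal branch with lighter-side size ``p >= 2``:
    ``TBE = 1 - mean(transfer index) / (p - 1)``, clamped to [0, 1], written
    onto the node label (so it serializes as a NEWICK internal-node label).
    Returns ``{node_id: support}`` keyed by internal-node preorder ids.
    """
    if not replicates:
        raise ConfigError("need at least one usable bootstrap replicate")
    supports: dict[int, float] = {}
    ids = internal_node_ids(reference)
    for node, b in tree_bipartitions(reference):
        p = b.lighter_size
        if p < 2:
            continue
        mean_idx = float(np.mean([transfer_index(b, rep) for rep in replicates]))
        tbe = 1.0 - mean_idx / (p - 1)
        tbe = min(max(tbe, 0.0), 1.0)
        node.label = f"{tbe:.3f}"
        supports[ids[id(node)]] = tbe
    return supports


# ---------------------------------------------------------------- enrichment

@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one annotation in one clade."""

    node_id: int
    category: str
    k: int  # annotated leaves in the clade
    n: int  # clade size
    K: int  # annotated leaves in the tree
    N: int  # leaves in the tree
    p_value: float
    width_score: float = 0.0
    leaves: frozenset[str] = field(default_factory=frozenset)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n); exact, 1.0 when k <= 0."""
    if k <= 0 or K == 0 or n == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def internal_node_ids(tree: dendropy.Tree) -> dict[int, int]:
    """Stable preorder ids for internal nodes, keyed by ``id(node)``."""
    ids: dict[int, int] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            ids[id(node)] = counter
            counter += 1
    return ids


def branch_enrichment(
    tree: dendropy.Tree,
    labels: dict[str, str],
    category: str,
    width_params: tuple[float, float, float] = (1.0, 1.0, 10.0),
) -> list[EnrichmentResult]:
    """Exact hypergeometric upper-tail enrichment of ``category`` per clade.

    ``labels`` maps every leaf to its annotation. Raw (uncorrected) p-values
    are returned, matching how per-branch clustering significance is usually
    displayed; apply :func:`benjamini_hochberg` separately if desired.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    unlabeled = [l for l in leaves if l not in labels]
    if unlabeled:
        raise ConfigError(f"unlabeled leaves: {unlabeled[:5]}")
    N = len(leaves)
    K = sum(1 for l in leaves if labels[l] == category)
    ids = internal_node_ids(tree)
    results = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = [l.taxon.label for l in node.leaf_iter()]
        n = len(clade)
        k = sum(1 for l in clade if labels[l] == category)
        p = hypergeom_upper_tail(k, n, K, N)
        results.append(
            EnrichmentResult(
                node_id=ids[id(node)],
                category=category,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=p,
                width_score=branch_width(p, *width_params),
                leaves=frozenset(clade),
            )
        )
    return results


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted q-values, same order as the input."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q.tolist()


def branch_width(
    p_value: float, w_min: float = 1.0, scale: float = 1.0, cap: float = 10.0
) -> float:
    """Display width for a branch: ``w_min + min(-log10(p), cap) * scale``."""
    if not (0.0 < p_value <= 1.0):
        raise ConfigError(f"p-value must be in (0, 1], got {p_value}")
    return w_min + min(-math.log10(p_value), cap) * scale


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.node_id, r.category, r.k, r.n, r.K, r.N, r.p_value, r.width_score)
            for r in results
        ],
        columns=["node_id", "category", "k", "n", "K", "N", "p_value", "width_score"],
    )


# ------------------------------------------------------------------- depths

@dataclass
class DepthComparison:
    depths_a: list[float]
    depths_b: list[float]
    statistic: float
    p_value: float
    mode: str
    method: str


def depth_comparison(
    tree: dendropy.Tree,
    group_a,
    group_b,
    mode: str = "edges",
) -> DepthComparison:
    """Two-sided Mann-Whitney U comparison of root-to-leaf depths.

    ``mode='edges'`` counts edges on the root path; ``mode='length'`` sums
    branch lengths. Exact enumeration is used for small tie-free samples,
    the tie-corrected normal approximation otherwise.
    """
    a, b = [str(x) for x in group_a], [str(x) for x in group_b]
    if not a or not b:
        raise ConfigError("both depth groups must be non-empty")
    overlap = set(a) & set(b)
    if overlap:
        raise ConfigError(f"depth groups overlap: {sorted(overlap)[:5]}")
    depths = leaf_depths(tree, mode=mode)
    missing = [x for x in a + b if x not in depths]
    if missing:
        raise ConfigError(f"group members absent from tree: {missing[:5]}")
    da = [depths[x] for x in a]
    db = [depths[x] for x in b]
    pooled = da + db
    has_ties = len(set(pooled)) < len(pooled)
    small = max(len(da), len(db)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(da, db, alternative="two-sided", method=method)
    return DepthComparison(
        depths_a=da,
        depths_b=db,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        mode=mode,
        method=method,
    )
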