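"""Lineage-tree reconstruction from STR genotype matrices.

Genotypes are translated to characters and concatenated in fixed panel order
into sequence-like strings (exportable as FASTA for external tree tools).
The native reconstruction path computes pairwise mismatch-fraction distances
with pairwise deletion of missing entries and runs an exact neighbor-joining,
rooting the result at a pseudo-leaf placed at the average genotype of a
designated root group of cells (the HSC-MPP compartment in the intended
application: the least-diverged cells anchor the founder).
"""

from __future__ import annotations

import math
import string
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DegenerateTreeError,
    NewickParseError,
    UncomputableDistanceError,
)
from .panel import STRPanel

#: fixed encoding alphabet; per locus, repeat count r maps to
#: ALPHABET[r - min_repeats]
ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits
MISSING_CHAR = "-"
ROOT_LEAF = "rootprofile"  # pseudo-leaf used to root NJ trees


# ------------------------------------------------------------------ encoding

def encode_genotypes(matrix: pd.DataFrame, panel: STRPanel) -> dict[str, str]:
    """Translate a genotype matrix into per-cell character strings.

    The mapping is an explicit per-locus bijection: repeat count ``r`` becomes
    the alphabet character at offset ``r - min_repeats``; missing entries
    become ``-``. Strings follow panel column order.
    """
    for locus in panel:
        width = locus.max_repeats - locus.min_repeats + 1
        if width > len(ALPHABET):
            raise ConfigError(
                f"locus {locus.locus_id} spans {width} repeat counts; "
                f"alphabet holds only {len(ALPHABET)}"
            )
    out: dict[str, str] = {}
    for cell_id, row in matrix[panel.ids].iterrows():
        chars = []
        for locus, value in zip(panel, row):
            if pd.isna(value):
                chars.append(MISSING_CHAR)
            else:
                r = int(value)
                if not (locus.min_repeats <= r <= locus.max_repeats):
                    raise ConfigError(
                        f"cell {cell_id}, locus {locus.locus_id}: repeat {r} "
                        f"outside [{locus.min_repeats}, {locus.max_repeats}]"
                    )
                chars.append(ALPHABET[r - locus.min_repeats])
        out[str(cell_id)] = "".join(chars)
    return out


def decode_genotypes(alignment: Mapping[str, str], panel: STRPanel) -> pd.DataFrame:
    """Inverse of :func:`encode_genotypes` (missing characters become NaN)."""
    rows = {}
    for cell_id, seq in alignment.items():
        if len(seq) != len(panel):
            raise ConfigError(f"cell {cell_id}: string length {len(seq)} != panel size")
        vals = []
        for locus, ch in zip(panel, seq):
            if ch == MISSING_CHAR:
                vals.append(np.nan)
            else:
                vals.append(locus.min_repeats + ALPHABET.index(ch))
        rows[cell_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=panel.ids)


def write_fasta(alignment: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")


# ----------------------------------------------------------------- distances

def _mismatch_distance(X: np.ndarray, labels: list[str]) -> np.ndarray:
    """Mismatch fraction over co-genotyped loci; NaN marks missing entries."""
    valid = ~np.isnan(X)
    both = valid[:, None, :] & valid[None, :, :]
    shared = both.sum(axis=2)
    with np.errstate(invalid="ignore"):
        diff = (X[:, None, :] != X[None, :, :]) & both
    n = len(labels)
    bad = np.argwhere((shared == 0) & ~np.eye(n, dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise UncomputableDistanceError((labels[i], labels[j]))
    D = diff.sum(axis=2) / np.maximum(shared, 1)
    np.fill_diagonal(D, 0.0)
    return D


def pairwise_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric cells x cells mismatch-fraction distance matrix.

    ``d(a, b)`` = (# co-genotyped loci with different repeat counts) /
    (# co-genotyped loci). Pairs sharing no genotyped locus raise
    :class:`~strlineage.errors.UncomputableDistanceError`.
    """
    if len(matrix) < 2:
        raise DegenerateTreeError("need at least 2 cells for distances")
    labels = [str(i) for i in matrix.index]
    D = _mismatch_distance(matrix.to_numpy(dtype=float), labels)
    return pd.DataFrame(D, index=labels, columns=labels)


# -------------------------------------------------------------- root profile

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_root_profile(
    matrix: pd.DataFrame, root_group: Iterable[str], panel: STRPanel
) -> np.ndarray:
    """Average genotype of the designated root group, rounded half-up.

    Loci with no call anywhere in the group fall back to the panel reference
    repeat count, then the profile is clamped into each locus range.
    """
    group = [str(g) for g in root_group]
    if not group:
        raise ConfigError("root group is empty")
    missing = [g for g in group if g not in matrix.index]
    if missing:
        raise ConfigError(f"root group cells absent from matrix: {missing}")
    sub = matrix.loc[group, panel.ids].to_numpy(dtype=float)
    profile = np.empty(len(panel), dtype=int)
    for j, locus in enumerate(panel):
        col = sub[:, j]
        col = col[~np.isnan(col)]
        value = _round_half_up(float(col.mean())) if col.size else locus.ref_repeats
        profile[j] = min(max(value, locus.min_repeats), locus.max_repeats)
    return profile


# ------------------------------------------------------------ neighbor joining

def neighbor_joining(dist: pd.DataFrame) -> list[tuple[str, str, float]]:
    """Exact neighbor-joining; returns the unrooted tree as an edge list.

    Deterministic: ties in the Q criterion are broken by lexicographic order
    of the joined node ids. Negative branch-length estimates are clamped to
    zero. Internal nodes are named ``nj#``.
    """
    ids = [str(i) for i in dist.index]
    if len(ids) < 3:
        raise DegenerateTreeError("neighbor joining needs at least 3 taxa")
    D = dist.to_numpy(dtype=float).copy()
    edges: list[tuple[str, str, float]] = []
    counter = 0
    while len(ids) > 2:
        n = len(ids)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            ((i, j) for i, j in cand if i < j),
            key=lambda ij: tuple(sorted((ids[ij[0]], ids[ij[1]]))),
        )
        i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_id = f"nj{counter}"
        counter += 1
        edges.append((new_id, ids[i], li))
        edges.append((new_id, ids[j], lj))
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        dnew = np.maximum(dnew, 0.0)
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        ids = [ids[k] for k in keep] + [new_id]
    edges.append((ids[0], ids[1], max(D[0, 1], 0.0)))
    return edges


def _edges_to_newick(
    edges: list[tuple[str, str, float]], root: str, drop: set[str], leaf_names: set[str]
) -> str:
    adj: dict[str, list[tuple[str, float]]] = {}
    for a, b, ln in edges:
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    def rec(node: str, parent: str | None, edge_len: float | None) -> str:
        children = [(c, ln) for c, ln in adj[node] if c != parent and c not in drop]
        if not children:
            body = node if node in leaf_names else ""
        else:
            inner = ",".join(rec(c, node, ln) for c, ln in sorted(children))
            label = node if node in leaf_names else ""
            body = f"({inner}){label}"
        return body if edge_len is None else f"{body}:{edge_len:.10g}"

    return rec(root, None, None) + ";"


def build_tree(
    dist: pd.DataFrame,
    root_profile: np.ndarray,
    matrix: pd.DataFrame,
    panel: STRPanel,
) -> dendropy.Tree:
    """Neighbor-joining tree rooted at the root-group average profile.

    The profile is appended as a pseudo-leaf (mismatch distance to every
    cell over that cell's called loci), NJ runs on the augmented matrix, the
    tree is rooted at the pseudo-leaf's attachment node, and the pseudo-leaf
    is removed.
    """
    labels = [str(i) for i in dist.index]
    if len(labels) < 3:
        raise DegenerateTreeError("need at least 3 cells to build a tree")
    if ROOT_LEAF in labels:
        raise ConfigError(f"cell id {ROOT_LEAF!r} is reserved")
    X = matrix.loc[labels, panel.ids].to_numpy(dtype=float)
    prof = np.asarray(root_profile, dtype=float)
    valid = ~np.isnan(X)
    with np.errstate(invalid="ignore"):
        diff = (X != prof[None, :]) & valid
    shared = valid.sum(axis=1)
    if (shared == 0).any():
        idx = int(np.argwhere(shared == 0)[0])
        raise UncomputableDistanceError((labels[idx], ROOT_LEAF))
    d_root = diff.sum(axis=1) / shared

    aug = pd.DataFrame(
        np.zeros((len(labels) + 1, len(labels) + 1)),
        index=labels + [ROOT_LEAF],
        columns=labels + [ROOT_LEAF],
    )
    aug.iloc[: len(labels), : len(labels)] = dist.to_numpy(dtype=float)
    aug.loc[ROOT_LEAF, labels] = d_root
    aug.loc[labels, ROOT_LEAF] = d_root

    edges = neighbor_joining(aug)
    # the pseudo-leaf's single neighbor becomes the root
    neighbors = [a if b == ROOT_LEAF else b for a, b, _ in edges if ROOT_LEAF in (a, b)]
    root_node = neighbors[0]
    newick = _edges_to_newick(edges, root_node, drop={ROOT_LEAF}, leaf_names=set(labels))
    return read_newick(newick)


# ------------------------------------------------------------------- NEWICK

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree; internal-node labels (supports) are preserved."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def read_newick(
    text: str, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Parse a rooted NEWICK tree; malformed input raises NewickParseError."""
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            taxon_namespace=taxon_namespace,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed NEWICK: {exc}") from exc


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition difference)."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=write_newick(tree_a),
        schema="newick",
        taxon_namespace=tns,
        rooting="force-unrooted",
        preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=write_newick(tree_b),
        schema="newick",
        taxon_namespace=tns,
        rooting="force-unrooted",
        preserve_underscores=True,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def leaf_depths(tree: dendropy.Tree, mode: str = "edges") -> dict[str, float]:
    """Root-to-leaf depth per leaf: edge count or summed branch length."""
    if mode not in ("edges", "length"):
        raise ConfigError(f"mode must be 'edges' or 'length', got {mode!r}")
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += 1 if mode == "edges" else (node.edge.length or 0.0)
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths
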