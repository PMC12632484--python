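"""Balanced minimum-evolution trees over copy-number profiles.

Pairwise Manhattan (L1) distances are computed on CN vectors per cell
(1 Mb bins) or per subcluster (mean 20 kb bins). The tree topology is
the neighbor-joining agglomeration (the greedy search for the balanced
minimum-evolution criterion); branch lengths are re-estimated by
weighted least squares under Pauplin's balanced weighting
(w_ij = 2^(1 - topological distance)), and nearest-neighbor-interchange
moves are accepted while they reduce the balanced tree length.
Negative branch lengths are clamped to zero with the deficit moved to
the adjacent edges. Trees are rooted on the edge subtending a diploid
outgroup and serialise to Newick via scikit-bio.
"""

from __future__ import annotations

import io
import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .containers import CellCNMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances


def cn_distance_matrix(vectors: pd.DataFrame) -> DistanceMatrix:
    """Pairwise L1 distance between CN vectors (rows = labels).

    Bins missing (NaN) in either member of a pair are excluded for that
    pair, with rescaling to the full bin count so distances remain
    comparable across pairs. A pair with no shared bins is an error.
    """
    labels = [str(l) for l in vectors.index]
    x = vectors.to_numpy(dtype=float)
    n, m = x.shape
    out = np.zeros((n, n))
    finite = np.isfinite(x)
    for i in range(n):
        for j in range(i + 1, n):
            ok = finite[i] & finite[j]
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(f"no shared bins for pair "
                                 f"({labels[i]}, {labels[j]})")
            d = float(np.abs(x[i, ok] - x[j, ok]).sum()) * m / n_ok
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=labels)


def cell_vectors(matrix: CellCNMatrix, bins_per_window: int = 50
                 ) -> pd.DataFrame:
    """Per-cell mean CN in 1 Mb windows (50 x 20 kb bins)."""
    from .clustering import aggregate_bins
    agg = aggregate_bins(matrix, bins_per_window=bins_per_window)
    return pd.DataFrame(agg.values, index=agg.barcodes)


def subcluster_vectors(matrix: CellCNMatrix, labels: pd.Series
                       ) -> pd.DataFrame:
    """Per-subcluster mean CN at full 20 kb resolution.

    ``labels`` maps barcode -> dotted subcluster label; masked calls are
    excluded from the means.
    """
    rows = {}
    cn = matrix.cn.astype(float)
    ok = ~matrix.mask
    for lab in sorted(labels.unique()):
        idx = matrix.barcodes.get_indexer(labels.index[labels == lab])
        cnt = ok[idx].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0,
                            (cn[idx] * ok[idx]).sum(axis=0)
                            / np.maximum(cnt, 1), np.nan)
        rows[str(lab)] = mean
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# balanced minimum evolution


def _tip_edge_counts(tree: TreeNode) -> Tuple[list, np.ndarray]:
    """Topological (edge-count) distances between all tips."""
    unit = tree.copy()
    for node in unit.traverse(include_self=False):
        node.length = 1.0
    dm = unit.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data)


def bme_length(tree: TreeNode, dm: DistanceMatrix) -> float:
    """Pauplin's balanced tree length: sum of 2^(1-t_ij) * d_ij."""
    ids, t = _tip_edge_counts(tree)
    order = [ids.index(i) for i in dm.ids]
    t = t[np.ix_(order, order)]
    d = np.asarray(dm.data)
    iu = np.triu_indices(len(ids), 1)
    return float((2.0 ** (1.0 - t[iu]) * d[iu]).sum())


def _edges(tree: TreeNode) -> list:
    """All (child) nodes carrying an edge to their parent."""
    return [n for n in tree.traverse(include_self=False)]


def _internal_edges(tree: TreeNode) -> list:
    return [n for n in _edges(tree)
            if not n.is_tip() and n.parent is not None
            and not (n.parent.is_root() and len(n.parent.children) < 3
                     and n.parent.parent is None and False)]


def _nni_neighbours(tree: TreeNode) -> list:
    """Trees one NNI move away (around each internal edge)."""
    out = []
    base = tree.copy()
    internal = [id(n) for n in base.traverse(include_self=False)
                if not n.is_tip()]
    for rank, _ in enumerate(internal):
        for variant in (0, 1):
            t = tree.copy()
            nodes = [n for n in t.traverse(include_self=False)
                     if not n.is_tip()]
            v = nodes[rank]
            u = v.parent
            if u is None or len(v.children) < 2:
                continue
            siblings = [c for c in u.children if c is not v]
            if not siblings:
                continue
            a = v.children[variant % len(v.children)]
            c = siblings[0]
            # swap subtree a (under v) with subtree c (under u)
            v.remove(a)
            u.remove(c)
            v.append(c)
            u.append(a)
            out.append(t)
    return out


def _balanced_branch_lengths(tree: TreeNode, dm: DistanceMatrix) -> int:
    """Fit branch lengths by WLS with balanced (2^-t) weights, in place.

    Returns the number of negative estimates clamped to zero; the
    clamped deficit is pushed to the child edges so path lengths change
    as little as possible.
    """
    tips = list(tree.tips())
    tip_names = [t.name for t in tips]
    edges = _edges(tree)
    e_index = {id(n): k for k, n in enumerate(edges)}
    n_pairs = len(tips) * (len(tips) - 1) // 2
    X = np.zeros((n_pairs, len(edges)))
    y = np.zeros(n_pairs)
    w = np.zeros(n_pairs)
    ids, t_counts = _tip_edge_counts(tree)
    tpos = {name: k for k, name in enumerate(ids)}
    row = 0
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            path = _edge_path(tips[i], tips[j])
            for node in path:
                X[row, e_index[id(node)]] = 1.0
            y[row] = dm[tip_names[i], tip_names[j]]
            w[row] = 2.0 ** (-t_counts[tpos[tip_names[i]],
                                       tpos[tip_names[j]]])
            row += 1
    sw = np.sqrt(w)[:, None]
    sol, *_ = np.linalg.lstsq(X * sw, y * sw.ravel(), rcond=None)
    clamped = 0
    for k, node in enumerate(edges):
        node.length = float(sol[k])
    for node in tree.preorder(include_self=False):
        if node.length is not None and node.length < 0:
            deficit = node.length
            node.length = 0.0
            clamped += 1
            for child in node.children:
                if child.length is not None:
                    child.length = max(child.length + deficit, 0.0)
    return clamped


def _edge_path(a: TreeNode, b: TreeNode) -> list:
    """Edge nodes on the path between two tips."""
    anc_a = [a] + list(a.ancestors())
    seen = {id(n): k for k, n in enumerate(anc_a)}
    path_b = []
    node = b
    while id(node) not in seen:
        path_b.append(node)
        node = node.parent
    lca_idx = seen[id(node)]
    return anc_a[:lca_idx] + path_b


def build_me_tree(dm: DistanceMatrix, nni: bool = True,
                  max_rounds: int = 20) -> TreeNode:
    """NJ topology + balanced branch lengths + BME-improving NNI moves."""
    if len(dm.ids) < 3:
        logger.warning("fewer than 3 labels; returning trivial tree")
        tree = TreeNode(name=None)
        for name in dm.ids:
            tree.append(TreeNode(name=str(name),
                                 length=float(dm.data.max()) / 2))
        return tree
    tree = nj(dm)
    if nni:
        best_len = bme_length(tree, dm)
        for _ in range(max_rounds):
            improved = False
            for cand in _nni_neighbours(tree):
                l = bme_length(cand, dm)
                if l < best_len - 1e-12:
                    tree, best_len = cand, l
                    improved = True
                    break
            if not improved:
                break
    clamped = _balanced_branch_lengths(tree, dm)
    if clamped:
        logger.info("clamped %d negative branch lengths", clamped)
    return tree


def root_at_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the edge subtending the outgroup tip (at its midpoint).

    All leaf-to-leaf path lengths are preserved; every non-outgroup
    leaf descends from the root's other child.
    """
    t = tree.copy()
    try:
        tip = t.find(str(outgroup))
    except Exception as exc:
        raise KeyError(f"outgroup {outgroup!r} not found") from exc
    if not tip.is_tip():
        raise KeyError(f"outgroup {outgroup!r} is not a leaf")
    half = (tip.length or 0.0) / 2.0
    rooted = t.root_at(tip.parent)
    tip = rooted.find(str(outgroup))
    parent = tip.parent
    parent.remove(tip)
    new_root = TreeNode(name=None)
    tip.length = half
    inner = parent
    inner.length = half
    new_root.append(tip)
    new_root.append(inner)
    return new_root


def path_length_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    return tree.tip_tip_distances()


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def from_newick(source: str) -> TreeNode:
    return TreeNode.read(io.StringIO(source), format="newick")


def write_newick(tree: TreeNode, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree))
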