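"""Recursive significance-gated bisection clustering on departures.

At each node the two-way baseline is refit on the node's cells alone (genes
all-zero within the node are dropped), the departure matrix is recomputed,
cells are bisected by Ward/Euclidean hierarchical clustering, and the split
is kept only if a SigClust-style Monte-Carlo test finds it significant.
Recursion stops when (1) the split is not significant, (2) the maximum
depth J is reached, or (3) the node is too small for both children to reach
the minimum size S.

The split test simulates the null of a single multivariate Gaussian with
diagonal covariance taken from per-gene variances (floored at their median
to guard degenerate coordinates); the statistic is the 2-cluster index
CI = within-split SS / total SS, and p = (1 + #{null CI <= observed}) /
(1 + n_mc).  No correction is applied across the tree's many split tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .counts_io import CountMatrix
from .departure import DepartureMatrix, dipd
from .twoway import fit_twoway

STOP_SIGNIFICANT = "significant_split"
STOP_NOT_SIGNIFICANT = "not_significant"
STOP_MAX_DEPTH = "max_depth"
STOP_MIN_SIZE = "min_size"


@dataclass(eq=False)
class ClusterNode:
    cell_indices: list[int]
    depth: int
    name: str                      # binary path from the root ("" = root)
    stop_reason: str | None = None
    p_value: float | None = None
    degenerate_split: bool = False
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "depth": self.depth,
            "n_cells": len(self.cell_indices),
            "cell_indices": list(map(int, self.cell_indices)),
            "stop_reason": self.stop_reason,
            "p_value": self.p_value,
            "degenerate_split": self.degenerate_split,
        }
        if self.children is not None:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass(eq=False)
class ClusterTree:
    root: ClusterNode
    cell_ids: list[str]
    alpha: float
    J: int
    S: int
    n_mc: int
    seed: int

    @property
    def max_leaves(self) -> int:
        return 2 ** self.J

    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def labels(self) -> pd.Series:
        """Leaf name per cell, indexed by cell id (root name '0' if unsplit)."""
        lab = np.empty(len(self.cell_ids), dtype=object)
        for leaf in self.leaves():
            name = leaf.name if leaf.name else "0"
            for i in leaf.cell_indices:
                lab[i] = name
        return pd.Series(lab, index=self.cell_ids, name="cluster")

    def to_json(self, **kwargs) -> str:
        payload = {
            "alpha": self.alpha, "J": self.J, "S": self.S,
            "n_mc": self.n_mc, "seed": self.seed,
            "cell_ids": self.cell_ids,
            "root": self.root.to_dict(),
        }
        kwargs.setdefault("sort_keys", True)
        return json.dumps(payload, **kwargs)


def split_once(D_values: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Bisect cells (columns) by Ward/Euclidean agglomeration, cut at k=2.

    Returns (labels in {0,1} with cell 0 labeled 0, merge height of the top
    join, degenerate flag).  If all cell vectors are identical the split is
    arbitrary but deterministic (first half vs second half) and flagged.
    """
    X = np.asarray(D_values, dtype=float).T  # cells as points
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    if np.allclose(X, X[0], atol=0.0):
        labels = np.zeros(n, dtype=int)
        labels[n // 2:] = 1
        return labels, 0.0, True
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, 2, criterion="maxclust") - 1
    if labels[0] != 0:
        labels = 1 - labels
    return labels.astype(int), float(Z[-1, 2]), False


def _cluster_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-split SS over total SS for points X (rows) under a 2-partition."""
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total <= 0:
        return 1.0
    within = 0.0
    for k in (0, 1):
        pts = X[labels == k]
        if len(pts):
            within += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return within / total


def split_significance(D_values: np.ndarray, labels: np.ndarray,
                       n_mc: int = 100, seed: int = 0) -> float:
    """Monte-Carlo p-value for a 2-way split of departure columns.

    Null: a single multivariate Gaussian whose covariance spectrum is the
    sample covariance's eigenvalues (at most n_cells - 1 are nonzero), each
    soft-floored at the median per-gene variance.  The cluster index is
    rotation invariant, so null draws are simulated on independent
    coordinates with those eigen-variances.  Each null draw is split by the
    same Ward k=2 procedure; a small observed cluster index (tight split)
    is evidence against homogeneity.

    Matching the spectrum — rather than per-coordinate variances — matters:
    the leading principal directions of even a homogeneous sample exceed
    any axis-aligned variance, and a null that ignores them rejects far too
    often on sparse discrete departures.
    """
    if n_mc < 19:
        raise ValueError("n_mc < 19 cannot resolve alpha = 0.05")
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 1 or len(np.unique(labels)) < 2:
        raise ValueError("labels must be a binary partition with both groups non-empty")
    D = np.asarray(D_values, dtype=float)
    X = D.T
    n_genes, n_cells = D.shape
    obs_ci = _cluster_index(X, labels)
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    eig = np.zeros(n_genes)
    k = min(len(sv), n_genes)
    eig[:k] = sv[:k] ** 2 / max(n_cells - 1, 1)
    floor = float(np.median(D.var(axis=1, ddof=1)))
    sd = np.sqrt(np.maximum(eig, floor))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        null = rng.standard_normal((n_genes, n_cells)) * sd[:, None]
        null_labels, _, degen = split_once(null)
        if degen:
            continue
        if _cluster_index(null.T, null_labels) <= obs_ci:
            hits += 1
    return (1 + hits) / (1 + n_mc)


def _node_departures(m: CountMatrix, cells: np.ndarray) -> np.ndarray:
    """Departure matrix for a cell subset, refit locally; all-zero genes dropped."""
    sub = m.subset(cell_idx=cells)
    keep = np.flatnonzero(sub.gene_totals > 0)
    sub = sub.subset(gene_idx=keep)
    return dipd(sub, fit_twoway(sub)).values


def hclust_departure(m: CountMatrix, alpha: float = 0.05, J: int = 10,
                     S: int = 10, n_mc: int = 100, seed: int = 0) -> ClusterTree:
    """Recursive significance-gated clustering of cells (*Hclust-Departure*).

    Parameters
    ----------
    m
        Filtered count matrix (no all-zero rows/columns).
    alpha
        Split significance level; the one substantive tunable.
    J
        Maximum depth, capping the tree at 2^J leaves.
    S
        Minimum cluster size: a node with fewer than 2*S cells is never
        split (neither child could reach S), and a child below S becomes a
        leaf.
    n_mc
        Monte-Carlo draws per split test.
    seed
        Drives every stochastic component; identical inputs and seed give a
        byte-identical JSON tree.
    """
    if np.any(m.gene_totals <= 0) or np.any(m.cell_totals <= 0):
        raise ValueError("apply filter_counts before clustering")
    root_ss = np.random.SeedSequence(seed)

    def build(cells: np.ndarray, depth: int, name: str,
              ss: np.random.SeedSequence) -> ClusterNode:
        node = ClusterNode(cell_indices=[int(i) for i in cells], depth=depth, name=name)
        if depth >= J:
            node.stop_reason = STOP_MAX_DEPTH
            return node
        if len(cells) < 2 * S:
            node.stop_reason = STOP_MIN_SIZE
            return node
        D = _node_departures(m, cells)
        labels, _, degen = split_once(D)
        sig_ss, left_ss, right_ss = ss.spawn(3)
        p = split_significance(D, labels, n_mc=n_mc,
                               seed=sig_ss.generate_state(1)[0] % (2**31))
        node.p_value = float(p)
        node.degenerate_split = degen
        if p >= alpha:
            node.stop_reason = STOP_NOT_SIGNIFICANT
            return node
        node.stop_reason = STOP_SIGNIFICANT
        left = cells[labels == 0]
        right = cells[labels == 1]
        node.children = (
            build(left, depth + 1, name + "0", left_ss),
            build(right, depth + 1, name + "1", right_ss),
        )
        return node

    root = build(np.arange(m.n_cells), 0, "", root_ss)
    return ClusterTree(root, list(m.cell_ids), alpha, J, S, n_mc, seed)


CATEGORY_RED = "red"        # significant and large effect
CATEGORY_ORANGE = "orange"  # significant, small effect
CATEGORY_BLACK = "black"    # not significant

MEAN_DIFF_THRESHOLD = 4.0
MIN_CELLS_FOR_TTEST = 30


def departure_markers(D: DepartureMatrix, group_a, group_b,
                      fdr_alpha: float = 0.05,
                      mean_diff_threshold: float = MEAN_DIFF_THRESHOLD) -> pd.DataFrame:
    """Per-gene differential departure between two cell groups.

    Uses the two-sample t-test when both groups have >= 30 cells and the
    Wilcoxon rank-sum test otherwise, then Benjamini-Hochberg adjustment
    across genes.  Genes are 'red' (adjusted p < 0.05 and |mean departure
    difference| > 4), 'orange' (significant but small shift) or 'black'.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells")
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint")
    Da, Db = D.values[:, a], D.values[:, b]
    use_t = min(len(a), len(b)) >= MIN_CELLS_FOR_TTEST
    diffs = Da.mean(axis=1) - Db.mean(axis=1)
    pvals = np.ones(D.values.shape[0])
    flagged = np.zeros(D.values.shape[0], dtype=bool)
    for g in range(D.values.shape[0]):
        xa, xb = Da[g], Db[g]
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            # no variance in either group: the statistic is undefined; record
            # p = 1 and flag rather than guessing
            flagged[g] = True
            pvals[g] = 1.0
            continue
        if use_t:
            pvals[g] = stats.ttest_ind(xa, xb).pvalue
        else:
            pvals[g] = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    category = np.where(
        p_adj < fdr_alpha,
        np.where(np.abs(diffs) > mean_diff_threshold, CATEGORY_RED, CATEGORY_ORANGE),
        CATEGORY_BLACK,
    )
    return pd.DataFrame({
        "gene_id": D.gene_ids,
        "mean_diff": diffs,
        "p_value": pvals,
        "p_adjusted": p_adj,
        "category": category,
        "test": "t" if use_t else "wilcoxon",
        "degenerate": flagged,
    }).set_index("gene_id")
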