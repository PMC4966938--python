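"""Hierarchical clustering of deposits with multiscale-bootstrap support.

Deposits are clustered by complete linkage on Euclidean distances over
variance-filtered atomic segments. Cluster uncertainty is assessed by
multiscale bootstrap resampling of the atoms: at each scale r the atoms are
resampled with replacement to round(m*r) columns, the tree is rebuilt, and
the fraction of replicates recovering each original node's member set gives
a per-scale bootstrap probability (BP). The approximately unbiased (AU)
support extrapolates these across scales by fitting
Phi^-1(1 - BP_r) = v*sqrt(r) + c/sqrt(r) by weighted least squares and
reporting AU = 1 - Phi(v - c). BP is reported at scale r = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .core import AtomicSegmentMatrix, CohortTable
from .heterogeneity import variance_filter

logger = logging.getLogger("methet")

DEFAULT_SCALES: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass(eq=False)
class ClusterNode:
    members: frozenset  # leaf indices
    height: float
    left: Optional["ClusterNode"] = None
    right: Optional["ClusterNode"] = None
    bp: Optional[float] = None
    au: Optional[float] = None
    never_recovered: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass(eq=False)
class ClusterTree:
    root: ClusterNode
    labels: list[str]

    def internal_nodes(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                return
            out.append(node)
            walk(node.left)
            walk(node.right)

        walk(self.root)
        out.sort(key=lambda n: (n.height, min(n.members)))
        return out

    def member_id_sets(self) -> list[frozenset]:
        return [
            frozenset(self.labels[i] for i in node.members)
            for node in self.internal_nodes()
        ]

    def to_newick(self, annotate: str = "both") -> str:
        def fmt(node: ClusterNode) -> str:
            if node.is_leaf:
                return self.labels[next(iter(node.members))]
            label = ""
            if annotate in ("au", "both") and node.au is not None:
                label += f"au={node.au:.3f}"
            if annotate in ("bp", "both") and node.bp is not None:
                label += ("|" if label else "") + f"bp={node.bp:.3f}"
            return f"({fmt(node.left)},{fmt(node.right)}){label}:{node.height:.6g}"

        return fmt(self.root) + ";"


def _complete_linkage(dist: np.ndarray, labels: Sequence[str]) -> ClusterTree:
    """Deterministic complete-linkage agglomeration.

    Tied merge distances are broken toward the pair containing the smallest
    original sample index (then the smallest index of the partner cluster).
    """
    n = dist.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two samples")
    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(frozenset([i]), 0.0) for i in range(n)
    }
    min_idx = {i: i for i in range(n)}
    pair_d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        (a, b), d = min(
            pair_d.items(),
            key=lambda kv: (kv[1], *sorted((min_idx[kv[0][0]], min_idx[kv[0][1]]))),
        )
        new = ClusterNode(
            nodes[a].members | nodes[b].members, d, nodes[a], nodes[b]
        )
        del pair_d[(a, b)]
        for k in list(nodes):
            if k in (a, b):
                continue
            da = pair_d.pop((min(a, k), max(a, k)))
            db = pair_d.pop((min(b, k), max(b, k)))
            pair_d[(min(next_id, k), max(next_id, k))] = max(da, db)
        del nodes[a], nodes[b]
        nodes[next_id] = new
        min_idx[next_id] = min(min_idx[a], min_idx[b])
        next_id += 1
    return ClusterTree(root=next(iter(nodes.values())), labels=list(labels))


def cluster_samples(
    matrix: AtomicSegmentMatrix, variance_cutoff: Optional[float] = 0.03
) -> ClusterTree:
    """Complete-linkage tree over Euclidean distances on filtered atoms."""
    if matrix.estimates.shape[0] < 2:
        raise ValueError("clustering needs at least two samples")
    filtered = variance_filter(matrix, variance_cutoff)
    dist = squareform(pdist(filtered.estimates, metric="euclidean"))
    return _complete_linkage(dist, matrix.samples)


def _replicate_member_sets(features: np.ndarray) -> set[frozenset]:
    """Internal-node member sets of a complete-linkage tree (fast path)."""
    n = features.shape[0]
    Z = _scipy_linkage(features, method="complete", metric="euclidean")
    members: list[frozenset] = [frozenset([i]) for i in range(n)]
    out: set[frozenset] = set()
    for row in Z:
        merged = members[int(row[0])] | members[int(row[1])]
        members.append(merged)
        out.add(merged)
    return out


def multiscale_bootstrap(
    matrix: AtomicSegmentMatrix,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int = 0,
    variance_cutoff: Optional[float] = 0.03,
) -> ClusterTree:
    """Cluster samples and attach AU/BP supports to every internal node.

    Resampling unit is the atomic segment (feature columns). Per-scale BPs
    of 0 or 1 are continuity-corrected to 1/(2*n_boot) from the boundary
    before the AU fit; a node recovered in every replicate at every scale is
    reported AU = BP = 1, and one never recovered gets AU = 0 with a flag.
    Seeded runs are bit-reproducible.
    """
    tree = cluster_samples(matrix, variance_cutoff)
    filtered = variance_filter(matrix, variance_cutoff)
    est = filtered.estimates
    m = est.shape[1]
    if m == 0:
        raise ValueError("no atoms to resample")
    nodes = tree.internal_nodes()
    node_sets = [node.members for node in nodes]
    rng = np.random.default_rng(seed)

    scales = [float(r) for r in scales]
    counts = np.zeros((len(nodes), len(scales)), dtype=np.int64)
    for si, r in enumerate(scales):
        m_r = max(1, round(m * r))
        for _ in range(n_boot):
            cols = rng.integers(0, m, m_r)
            found = _replicate_member_sets(est[:, cols])
            for ni, s in enumerate(node_sets):
                if s in found:
                    counts[ni, si] += 1

    r_arr = np.asarray(scales)
    one_idx = int(np.argmin(np.abs(r_arr - 1.0)))
    for ni, node in enumerate(nodes):
        raw_bp = counts[ni] / n_boot
        node.bp = float(raw_bp[one_idx])
        if np.all(counts[ni] == n_boot):
            node.au = 1.0
            continue
        if np.all(counts[ni] == 0):
            node.au = 0.0
            node.never_recovered = True
            continue
        bp = np.clip(raw_bp, 1.0 / (2 * n_boot), 1.0 - 1.0 / (2 * n_boot))
        z = norm.ppf(1.0 - bp)
        X = np.column_stack([np.sqrt(r_arr), 1.0 / np.sqrt(r_arr)])
        w = n_boot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
        W = X * w[:, None]
        beta = np.linalg.solve(X.T @ W, W.T @ z)
        v, c = beta
        node.au = float(1.0 - norm.cdf(v - c))
    return tree


def patient_cluster_purity(tree: ClusterTree, cohort: CohortTable) -> dict[str, str]:
    """Per patient: 'monophyletic' if some node's members equal the patient's
    deposits in the tree, 'split' otherwise, 'not_assessable' for solitary
    deposits."""
    leaf_ids = set(tree.labels)
    node_sets = set(tree.member_id_sets())
    out: dict[str, str] = {}
    for pid in cohort.patient_ids:
        samples = frozenset(
            s for s in cohort.samples_of(pid, resection=1) if s in leaf_ids
        )
        if len(samples) == 0:
            continue
        if len(samples) == 1:
            out[pid] = "not_assessable"
        elif samples in node_sets:
            out[pid] = "monophyletic"
        else:
            out[pid] = "split"
    return out
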