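"""Brownian-motion correlation structure from a rooted plant phylogeny.

Under Brownian trait evolution on a rooted tree, the covariance between
two tips equals the path length shared from the root down to their most
recent common ancestor, and the variance of a tip is its root-to-tip
depth.  Standardizing the covariance matrix gives the tip-tip correlation
used as the fixed working correlation of the phylogenetic GEE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .data import PlantSpecies, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PhyloCorrelation:
    """Unit-diagonal, symmetric, PSD tip correlation matrix."""

    tip_order: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.tip_order), len(self.tip_order)):
            raise ValidationError("correlation shape does not match tip order")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("correlation matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValidationError("correlation diagonal must be 1")
        eigmin = float(np.linalg.eigvalsh(m).min())
        if eigmin < -1e-10:
            raise ValidationError(
                f"correlation matrix not PSD (min eigenvalue {eigmin:.3e})"
            )
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.tip_order, columns=self.tip_order)

    def scaled(self, lam: float) -> "PhyloCorrelation":
        """Pagel-style sensitivity knob: shrink off-diagonals by ``lam``.

        ``lam=1`` (the default everywhere) leaves the plain Brownian
        structure untouched; ``lam=0`` gives independence.
        """
        m = lam * self.matrix + (1.0 - lam) * np.eye(len(self.tip_order))
        return PhyloCorrelation(tip_order=list(self.tip_order), matrix=m)


def brownian_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Shared-path covariance matrix of the tips of a rooted tree.

    Polytomies need no resolution: the entry for two tips is simply the
    depth of their most recent common ancestor.
    """
    # node depths from the root (root edge length, if any, ignored)
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValidationError("tree has missing branch lengths")
        depth[node] = depth[node.parent_node] + float(node.edge.length)

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    idx = {lf: i for i, lf in enumerate(leaves)}
    vcv = np.zeros((n, n))
    for lf in leaves:
        vcv[idx[lf], idx[lf]] = depth[lf]

    # postorder sweep: at each internal node, tips of distinct child
    # subtrees share exactly this node's depth
    tips_below: dict[dendropy.Node, list[dendropy.Node]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [node]
            continue
        children = node.child_nodes()
        groups = [tips_below[c] for c in children]
        d = depth[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for ta in groups[a]:
                    for tb in groups[b]:
                        vcv[idx[ta], idx[tb]] = d
                        vcv[idx[tb], idx[ta]] = d
        tips_below[node] = [t for g in groups for t in g]
    return labels, vcv


def to_correlation(labels: list[str], vcv: np.ndarray) -> PhyloCorrelation:
    """Standardize a covariance matrix: C(a,b) = V(a,b)/sqrt(V(a,a)V(b,b))."""
    d = np.diag(vcv).astype(float)
    if np.any(d <= 0):
        bad = [labels[i] for i in np.flatnonzero(d <= 0)]
        raise ValidationError(f"zero root-to-tip depth for tips {bad}")
    s = 1.0 / np.sqrt(d)
    corr = vcv * np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return PhyloCorrelation(tip_order=list(labels), matrix=corr)


def correlation_from_tree(tree: dendropy.Tree) -> PhyloCorrelation:
    labels, vcv = brownian_vcv(tree)
    return to_correlation(labels, vcv)


def align_to_registry(
    corr: PhyloCorrelation, plants: list[PlantSpecies]
) -> PhyloCorrelation:
    """Reorder rows/columns to registry order; drop tips with no plant.

    Every retained plant must map to exactly one tree tip (via
    ``tree_tip_label`` or, failing that, its ``plant_id``).
    """
    pos = {label: i for i, label in enumerate(corr.tip_order)}
    if len(pos) != len(corr.tip_order):
        raise ValidationError("duplicate tip labels in correlation")
    order: list[int] = []
    labels: list[str] = []
    for p in plants:
        if p.tip_label not in pos:
            raise ValidationError(
                f"plant {p.plant_id!r} (tip {p.tip_label!r}) missing from tree"
            )
        order.append(pos[p.tip_label])
        labels.append(p.plant_id)
    dropped = set(corr.tip_order) - {p.tip_label for p in plants}
    if dropped:
        logger.info("dropping %d unmatched tree tips: %s", len(dropped), sorted(dropped))
    m = corr.matrix[np.ix_(order, order)]
    return PhyloCorrelation(tip_order=labels, matrix=m)
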