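"""Average-linkage hierarchical clustering with correlation distance.

Probes are mean-centered, items (probes or samples) get the distance
d(i, j) = 1 - r(i, j) with r the Pearson correlation, and trees are built
by unweighted average linkage (UPGMA).  Cutting the sample tree into
branches and testing each branch's phenotype prevalence reproduces the
dendrogram-level view of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import association
from .io_core import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterTree",
    "center_genes",
    "pearson_distance",
    "average_linkage",
    "cut_tree",
    "branch_enrichment",
]


@dataclass
class ClusterTree:
    """A hierarchical tree in scipy linkage form plus its leaf identities."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    ids: list[str]
    axis: str  # "probes" or "samples"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n_leaves - 1 merges")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("average-linkage heights must be non-decreasing")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.ids[i] for i in order]


def center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe's mean across samples (rows end up mean 0)."""
    centered = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, matrix.detection_p)


def pearson_distance(
    matrix: ExpressionMatrix, axis: str = "samples"
) -> tuple[np.ndarray, list[str]]:
    """Symmetric 1 - Pearson-r distance over probes or samples.

    Zero-variance items have no defined correlation and are dropped with
    a warning; the returned id list names the retained items.
    """
    if axis == "probes":
        data = matrix.values.to_numpy(dtype=float)
        ids = matrix.probe_ids
    elif axis == "samples":
        data = matrix.values.to_numpy(dtype=float).T
        ids = matrix.sample_ids
    else:
        raise ValueError("axis must be 'probes' or 'samples'")
    sd = data.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [i for i, k in zip(ids, keep) if not k]
        logger.warning("dropping %d zero-variance item(s): %s",
                       len(dropped), dropped[:10])
        data = data[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items with positive variance")
    r = np.corrcoef(data)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # enforce exact symmetry
    return dist, list(ids)


def average_linkage(dist: np.ndarray, ids=None, axis: str = "samples") -> ClusterTree:
    """UPGMA tree from a square distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dist must be a square matrix")
    if ids is None:
        ids = [str(i) for i in range(dist.shape[0])]
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return ClusterTree(linkage=Z, ids=list(ids), axis=axis)


def cut_tree(tree: ClusterTree, n_branches: int) -> pd.Series:
    """Branch labels (1..n_branches) at the cut producing that many branches.

    Labels are renumbered in leaf order (branch 1 is leftmost in the
    dendrogram) and returned indexed by the tree's original ids.
    """
    n = len(tree.ids)
    if not (1 <= n_branches <= n):
        raise ValueError("n_branches must lie in [1, n_leaves]")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=n_branches).ravel()
    # renumber so labels follow dendrogram leaf order
    order = hierarchy.leaves_list(tree.linkage)
    seen: dict[int, int] = {}
    for leaf in order:
        if raw[leaf] not in seen:
            seen[raw[leaf]] = len(seen) + 1
    labels = np.array([seen[c] for c in raw])
    return pd.Series(labels, index=tree.ids, name="branch")


def branch_enrichment(
    branch_labels: pd.Series, phenotype
) -> tuple[pd.DataFrame, association.AssociationResult | None]:
    """Per-branch phenotype prevalence plus an overall chi-square test.

    For two branches the test delegates to the 2x2 chi-square; for more
    branches a b x 2 Pearson chi-square is used.  Branches with no
    members are excluded (cannot arise from :func:`cut_tree`).
    """
    y = np.asarray(phenotype, dtype=int)
    b = np.asarray(branch_labels)
    if len(y) != len(b):
        raise ValueError("branch labels and phenotype must align")
    rows = []
    for br in sorted(pd.unique(b)):
        mask = b == br
        rows.append({
            "branch": br,
            "n": int(mask.sum()),
            "cases": int(y[mask].sum()),
            "rate": float(y[mask].mean()),
        })
    summary = pd.DataFrame(rows).set_index("branch")
    branches = summary.index.to_numpy()
    if len(branches) < 2 or y.sum() in (0, len(y)):
        return summary, None
    if len(branches) == 2:
        m = b == branches[0]
        table = association.ContingencyTable(
            tp=int(y[m].sum()), fp=int((1 - y[m]).sum()),
            fn=int(y[~m].sum()), tn=int((1 - y[~m]).sum()),
        )
        result = association.chi_square(table)
    else:
        counts = np.array([
            [summary.loc[br, "cases"], summary.loc[br, "n"] - summary.loc[br, "cases"]]
            for br in branches
        ])
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        result = association.AssociationResult(
            odds_ratio=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p_value=float(p), sensitivity=None, specificity=None,
            method="chi2", statistic=float(chi2),
        )
    return summary, result
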