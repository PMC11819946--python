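"""Descriptor orthogonality: variable clustering, VIF, admissible predictor sets.

MLR predictors must be mutually near-orthogonal.  Similarity between
descriptors is measured as 100*|r| (Pearson, across compounds), i.e. the
clustering distance is d = 1 - |r|, agglomerated with average linkage.
Typical phenoxyacetic-acid panels split into an "electronic" cluster
{TPSA, HBD+HBA} and a "structural" cluster {MW, alpha, NRB}.  Admissible
predictor sets for the model search contain exactly one lipophilicity
descriptor (log k_BMC or log k_IAM) plus at most one member of each flat
cluster, enumerated exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import DomainError

__all__ = [
    "ClusterTree",
    "CollinearityReport",
    "variable_cluster",
    "vif",
    "admissible_sets",
]


def _frame(panel) -> pd.DataFrame:
    return panel.frame if hasattr(panel, "frame") else panel


@dataclass
class ClusterTree:
    """Agglomerative variable dendrogram on the 100*|r| similarity scale."""

    leaves: list[str]
    merges: list[tuple[int, int, float]]  # (node, node, similarity %) in merge order
    linkage_matrix: np.ndarray = field(repr=False)

    def flat_clusters(self, threshold: float) -> list[list[str]]:
        """Flat clusters whose internal merges all sit at >= threshold % similarity."""
        if not 0 < threshold < 100:
            raise DomainError(f"threshold must be in (0, 100), got {threshold}")
        labels = fcluster(self.linkage_matrix, t=1.0 - threshold / 100.0, criterion="distance")
        clusters: dict[int, list[str]] = {}
        for name, lab in zip(self.leaves, labels):
            clusters.setdefault(int(lab), []).append(name)
        return sorted((sorted(c) for c in clusters.values()), key=lambda c: c[0])

    def to_newick(self) -> str:
        """Newick string with branch lengths on the distance (1 - |r|) scale."""
        root = to_tree(self.linkage_matrix)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

        return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"

    def to_json_dict(self) -> dict:
        return {
            "leaves": self.leaves,
            "merges": [[a, b, s] for a, b, s in self.merges],
        }


def variable_cluster(
    panel,
    variables: Sequence[str],
    *,
    linkage_method: str = "average",
    absolute: bool = True,
) -> ClusterTree:
    """Cluster descriptors by correlation similarity across compounds.

    Distance d = 1 - |r| by default (1 - r with ``absolute=False``);
    similarity reported as 100*(1 - d).  Raises on constant variables.
    """
    frame = _frame(panel)
    variables = list(variables)
    if len(variables) < 2:
        raise DomainError("need at least two variables to cluster")
    data = frame.loc[:, variables].astype(float)
    constant = [v for v in variables if np.ptp(data[v].to_numpy()) == 0]
    if constant:
        raise DomainError(f"constant variable(s): {', '.join(constant)}")
    corr = data.corr().to_numpy()
    if absolute:
        corr = np.abs(corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=linkage_method)
    merges = [(int(a), int(b), 100.0 * (1.0 - d)) for a, b, d, _ in Z]
    return ClusterTree(leaves=variables, merges=merges, linkage_matrix=Z)


@dataclass
class CollinearityReport:
    """Per-descriptor variance inflation factors and the correlation matrix."""

    vif: dict[str, float]
    correlation: pd.DataFrame
    flagged: list[str]  # descriptors with (numerically) infinite VIF


def vif(panel, variables: Sequence[str]) -> CollinearityReport:
    """VIF_j = 1/(1 - R^2_j), R^2_j from regressing descriptor j on the rest.

    Perfectly collinear descriptors get an infinite VIF and are flagged
    rather than raising.
    """
    frame = _frame(panel)
    variables = list(variables)
    if len(frame) <= len(variables) + 1:
        raise DomainError(
            f"need more compounds ({len(frame)}) than variables + 1 ({len(variables) + 1})"
        )
    data = frame.loc[:, variables].astype(float)
    vifs: dict[str, float] = {}
    flagged: list[str] = []
    for v in variables:
        others = [w for w in variables if w != v]
        if not others:
            vifs[v] = 1.0
            continue
        # least-squares projection handles collinearity among the regressors
        design = np.column_stack([np.ones(len(data)), data[others].to_numpy()])
        y = data[v].to_numpy()
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / sst
        if 1.0 - r2 < 1e-12:
            vifs[v] = float("inf")
            flagged.append(v)
        else:
            vifs[v] = 1.0 / (1.0 - r2)
    return CollinearityReport(vif=vifs, correlation=data.corr(), flagged=flagged)


def admissible_sets(
    tree: ClusterTree,
    threshold: float,
    lipophilicity_options: Sequence[str],
    max_size: int,
) -> list[tuple[str, ...]]:
    """Exhaustively enumerate admissible predictor sets.

    Each set holds exactly one lipophilicity descriptor and at most one
    member per flat cluster formed at ``threshold`` % similarity, with total
    size <= max_size.  Output is deterministic: sorted by size, then
    lexicographically.
    """
    lipo = sorted(lipophilicity_options)
    if not lipo:
        raise DomainError("lipophilicity_options must not be empty")
    if max_size < 1:
        raise DomainError("max_size must be at least 1")
    clusters = tree.flat_clusters(threshold)
    sets: list[tuple[str, ...]] = []
    for L in lipo:
        for r in range(0, max_size):
            for combo in combinations(clusters, r):
                for members in product(*combo):
                    sets.append((L,) + tuple(sorted(members)))
    sets.sort(key=lambda s: (len(s), s))
    return sets
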