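"""Cross-omics integration: joint scaling, hierarchical clustering, activity calls.

Per-layer log2 fold changes are scaled to a common [-2, 2] range so no
layer dominates, treatments (or analytes) are clustered with Euclidean
distance and complete linkage, and each treatment is categorized as
active / passive / equivocal from its per-layer significance pattern:
active in >= 2 layers -> active overall, exactly 1 -> equivocal, none ->
passive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .preprocess import FoldChangeMatrix, count_significant

__all__ = [
    "IntegratedMatrix",
    "Dendrogram",
    "ActivityCall",
    "scale_to_symmetric_range",
    "hierarchical_cluster",
    "call_activity",
]


@dataclass
class IntegratedMatrix:
    """Analyte x treatment values scaled per layer to [-2, 2]."""

    values: pd.DataFrame
    layer_of: pd.Series


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over one axis of a matrix."""

    linkage: np.ndarray
    labels: list[str]
    axis: str

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class ActivityCall:
    """Per-layer and overall active/passive/equivocal categorization."""

    per_layer: pd.DataFrame  # treatment x layer, {active, passive}
    overall: pd.Series  # treatment -> {active, equivocal, passive}
    evidence: pd.DataFrame  # treatment x layer significant-analyte counts


def scale_to_symmetric_range(
    fc_layers: dict[str, FoldChangeMatrix] | dict[str, pd.DataFrame],
    lo: float = -2.0,
    hi: float = 2.0,
) -> IntegratedMatrix:
    """Scale each layer linearly so its global min/max hit [lo, hi].

    No rounding; a constant layer maps to all zeros. Layers are stacked
    over the shared treatment axis (mismatching treatment sets are an
    error).
    """
    if not fc_layers:
        raise ValueError("at least one layer required")
    frames = {
        name: (fc.log2fc if isinstance(fc, FoldChangeMatrix) else fc)
        for name, fc in fc_layers.items()
    }
    ref = None
    for name, frame in frames.items():
        if ref is None:
            ref = list(frame.columns)
        elif list(frame.columns) != ref:
            extra = set(frame.columns) ^ set(ref)
            raise ValueError(f"treatment mismatch across layers at {name!r}: {sorted(extra)}")
    blocks, layers = [], []
    for name, frame in frames.items():
        v = frame.to_numpy(float)
        vmin, vmax = np.nanmin(v), np.nanmax(v)
        if vmax == vmin:
            scaled = np.zeros(v.shape)
        else:
            scaled = (v - vmin) / (vmax - vmin) * (hi - lo) + lo
        blocks.append(pd.DataFrame(scaled, index=frame.index, columns=frame.columns))
        layers.append(pd.Series(name, index=frame.index))
    return IntegratedMatrix(values=pd.concat(blocks), layer_of=pd.concat(layers))


def _pairwise_complete_euclidean(x: np.ndarray) -> np.ndarray:
    """Euclidean distances over pairwise-complete coordinates, rescaled by
    the shared-coordinate fraction so distances stay comparable."""
    n, p = x.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(x[i]) | np.isnan(x[j]))
            m = int(mask.sum())
            if m == 0:
                raise ValueError(f"items {i} and {j} share no observed coordinates")
            diff = x[i, mask] - x[j, mask]
            d[i, j] = d[j, i] = np.sqrt(np.sum(diff**2) * (p / m))
    return d


def hierarchical_cluster(
    matrix: pd.DataFrame | IntegratedMatrix,
    axis: str = "columns",
    metric: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of rows or columns (default Euclidean +
    complete linkage, the usual convention for treatment heatmaps).

    Absent values fall back to pairwise-complete distances rescaled by the
    fraction of shared coordinates.
    """
    values = matrix.values if isinstance(matrix, IntegratedMatrix) else matrix
    x = values.to_numpy(float)
    if axis in ("columns", 1):
        x = x.T
        labels = [str(c) for c in values.columns]
    elif axis in ("rows", "index", 0):
        labels = [str(i) for i in values.index]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if x.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    if np.isnan(x).any():
        dist = squareform(_pairwise_complete_euclidean(x), checks=False)
    else:
        dist = pdist(x, metric=metric)
    z = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(linkage=z, labels=labels, axis="columns" if axis in ("columns", 1) else "rows")


def call_activity(
    fc_layers: dict[str, FoldChangeMatrix],
    alpha: float = 0.05,
    min_significant: int = 1,
    min_active_layers: int = 2,
    use_adjusted: bool = False,
) -> ActivityCall:
    """Categorize treatments as active / equivocal / passive.

    A treatment is active in a layer when >= ``min_significant`` analytes
    are significantly altered (p <= alpha) there. Overall: active when
    active in >= ``min_active_layers`` layers, equivocal when active in at
    least one layer but fewer than that, passive when active in none.
    Raising ``alpha`` can only move calls toward active.
    """
    counts = {}
    for name, fc in fc_layers.items():
        counts[name] = count_significant(fc, alpha=alpha, use_adjusted=use_adjusted)["total"]
    evidence = pd.DataFrame(counts)
    per_layer = evidence.ge(min_significant).map(lambda b: "active" if b else "passive")
    n_active = evidence.ge(min_significant).sum(axis=1)
    overall = pd.Series(
        np.where(n_active >= min_active_layers, "active",
                 np.where(n_active >= 1, "equivocal", "passive")),
        index=evidence.index,
        name="overall",
    )
    return ActivityCall(per_layer=per_layer, overall=overall, evidence=evidence)
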