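"""Weighted co-expression network construction and module detection.

The weighted gene correlation network analysis (WGCNA) core: analyte
profiles are scaled per layer to integers in [0, 100], pairwise Pearson
correlations are raised to a soft power beta (default 18) to form the
adjacency, the topological overlap matrix (TOM) combines direct adjacency
with shared-neighbor similarity, modules are cut out of an average-linkage
dendrogram of 1 - TOM, close modules are merged by eigengene correlation,
and each module is summarized by its eigengene — the first principal
component of its standardized expression.

Module labels follow the conventional size-ranked color sequence
(turquoise, blue, brown, ...) with ``grey`` reserved for unassigned
analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ScaledMatrix",
    "CoexpressionNetwork",
    "ModulePartition",
    "EigengeneMatrix",
    "MODULE_COLORS",
    "GREY",
    "scale_to_int_range",
    "adjacency",
    "scale_free_fit",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
]

GREY = "grey"

#: WGCNA's conventional color order for size-ranked module labels.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class ScaledMatrix:
    """Analyte x sample integer matrix in [0, 100] with a layer tag per analyte."""

    values: pd.DataFrame
    layer_of: pd.Series

    def __post_init__(self) -> None:
        self.layer_of = self.layer_of.reindex(self.values.index)
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("scaled matrix must be complete")
        if not np.array_equal(v, np.round(v)) or v.min() < 0 or v.max() > 100:
            raise ValueError("scaled matrix entries must be integers in [0, 100]")

    @property
    def analytes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class CoexpressionNetwork:
    """Soft-thresholded adjacency (and optionally TOM) over analytes."""

    beta: float
    adjacency: pd.DataFrame
    network_type: str = "unsigned"
    tom: pd.DataFrame | None = None

    @property
    def analytes(self) -> pd.Index:
        return self.adjacency.index

    def connectivity(self) -> pd.Series:
        a = self.adjacency.to_numpy()
        return pd.Series(a.sum(axis=1) - np.diag(a), index=self.analytes, name="k")


@dataclass
class ModulePartition:
    """Analyte -> module color labels; ``grey`` marks unassigned analytes."""

    module_of: pd.Series
    min_module_size: int = 25
    merge_cut_height: float = 0.1
    linkage: np.ndarray | None = field(default=None, repr=False)

    @property
    def modules(self) -> list[str]:
        sizes = self.module_of[self.module_of != GREY].value_counts()
        return list(sizes.index)

    def size_of(self) -> pd.Series:
        return self.module_of.value_counts()

    def members(self, module: str) -> pd.Index:
        return self.module_of.index[self.module_of == module]


@dataclass
class EigengeneMatrix:
    """Sample x module eigengene scores with per-module variance explained."""

    values: pd.DataFrame
    variance_explained: pd.Series

    @property
    def modules(self) -> pd.Index:
        return self.values.columns


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def scale_to_int_range(
    fc_layers: dict[str, pd.DataFrame], lo: int = 0, hi: int = 100
) -> ScaledMatrix:
    """Scale each layer's fold changes linearly to integers in [lo, hi].

    Per layer, the global minimum maps to ``lo`` and the global maximum to
    ``hi``; values are rounded half away from zero. A constant layer maps to
    the midpoint. Layers are stacked over a shared sample axis.
    """
    if not fc_layers:
        raise ValueError("at least one layer required")
    blocks, layers = [], []
    samples = None
    for name, frame in fc_layers.items():
        if frame.empty:
            raise ValueError(f"layer {name!r} is empty")
        if samples is None:
            samples = frame.columns
        elif list(frame.columns) != list(samples):
            raise ValueError(
                f"layer {name!r} samples {list(frame.columns)} differ from {list(samples)}"
            )
        v = frame.to_numpy(float)
        if not np.isfinite(v[~np.isnan(v)]).all():
            raise ValueError(f"layer {name!r} contains non-finite values")
        vmin, vmax = np.nanmin(v), np.nanmax(v)
        if vmax == vmin:
            scaled = np.full(v.shape, (lo + hi) / 2.0)
        else:
            scaled = (v - vmin) / (vmax - vmin) * (hi - lo) + lo
        scaled = _round_half_away(scaled)
        blocks.append(pd.DataFrame(scaled, index=frame.index, columns=samples))
        layers.append(pd.Series(name, index=frame.index))
    values = pd.concat(blocks, axis=0)
    layer_of = pd.concat(layers)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate analyte identifiers across layers: {dupes[:5]}")
    return ScaledMatrix(values=values, layer_of=layer_of)


def _pairwise_complete_corr(x: np.ndarray, min_shared: int = 3) -> np.ndarray:
    """Pearson correlation between rows; pairs with < min_shared complete
    samples (or zero variance) get correlation 0."""
    if not np.isnan(x).any():
        sd = x.std(axis=1)
        ok = sd > 0
        c = np.zeros((x.shape[0], x.shape[0]))
        if ok.any():
            c_ok = np.corrcoef(x[ok])
            c[np.ix_(ok, ok)] = np.nan_to_num(c_ok, nan=0.0)
        np.fill_diagonal(c, 1.0)
        return c
    c = pd.DataFrame(x.T).corr(min_periods=min_shared).to_numpy()
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return c


def adjacency(
    x: ScaledMatrix | pd.DataFrame,
    beta: float = 18,
    network_type: str = "unsigned",
    min_shared_samples: int = 3,
) -> CoexpressionNetwork:
    """Soft-thresholded co-expression adjacency.

    Unsigned: a_ij = |cor(x_i, x_j)|^beta; signed: a_ij = ((1+cor)/2)^beta.
    Correlations are Pearson over pairwise-complete samples; pairs sharing
    fewer than ``min_shared_samples`` samples are treated as uncorrelated.
    """
    values = x.values if isinstance(x, ScaledMatrix) else x
    if values.shape[1] < 3:
        raise ValueError("at least 3 samples required for a co-expression network")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if network_type not in ("unsigned", "signed"):
        raise ValueError(f"unknown network_type {network_type!r}")
    c = _pairwise_complete_corr(values.to_numpy(float), min_shared_samples)
    c = np.clip(c, -1.0, 1.0)
    if network_type == "unsigned":
        a = np.abs(c) ** beta
    else:
        a = ((1.0 + c) / 2.0) ** beta
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    adj = pd.DataFrame(a, index=values.index, columns=values.index)
    return CoexpressionNetwork(beta=beta, adjacency=adj, network_type=network_type)


def scale_free_fit(network: CoexpressionNetwork, n_bins: int = 10):
    """Scale-free topology fit: R^2 of log10(freq) vs log10(k) and slope.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are dropped. Returns ``(r_squared, slope)``; ``(nan, nan)`` when all
    connectivities coincide.
    """
    k = network.connectivity().to_numpy()
    if k.size < 2:
        raise ValueError("scale-free fit needs at least 2 analytes")
    if np.allclose(k, k[0]):
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = np.polyval([slope, intercept], xs)
    ss_res = float(np.sum((np.array(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.array(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return r2, float(slope)


def tom_similarity(network: CoexpressionNetwork) -> CoexpressionNetwork:
    """Topological overlap matrix of a weighted network.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij sums a_iu * a_uj over shared neighbors u and k_i is the
    connectivity of node i; TOM_ii = 1. The degenerate case a_ij = 1 with
    zero surrounding connectivity is defined as TOM_ij = 1.
    """
    a = network.adjacency.to_numpy(float)
    n = a.shape[0]
    off = a - np.diag(np.diag(a))
    k = off.sum(axis=1)
    l = off @ off
    num = l + off
    den = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 1.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    tom = pd.DataFrame(t, index=network.analytes, columns=network.analytes)
    return CoexpressionNetwork(
        beta=network.beta,
        adjacency=network.adjacency,
        network_type=network.network_type,
        tom=tom,
    )


def _gap_cut_height(heights: np.ndarray) -> float:
    """Largest-gap heuristic: midpoint of the widest gap between successive
    sorted merge heights above the median height."""
    hs = np.sort(heights)
    upper = hs[hs >= np.median(hs)]
    if upper.size < 2:
        return float(hs[-1]) * 0.5
    gaps = np.diff(upper)
    i = int(np.argmax(gaps))
    return float((upper[i] + upper[i + 1]) / 2.0)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (x - mu) / sd


def _first_pc(block: np.ndarray):
    """First principal component of standardized rows: (scores over samples,
    variance explained). Zero-variance rows are dropped."""
    z = _standardize_rows(block)
    z = z[~np.isnan(z).any(axis=1)]
    if z.shape[0] == 0:
        raise ValueError("module has no analytes with variance")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2)) if s.size else 1.0
    scores = scores - scores.mean()
    sd = scores.std(ddof=1)
    if sd > 0:
        scores = scores / sd
    mean_profile = z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    return scores, var_explained


def module_eigengenes(
    x: ScaledMatrix | pd.DataFrame,
    partition: ModulePartition,
    include_grey: bool = False,
) -> EigengeneMatrix:
    """Eigengene (first PC) of each non-grey module.

    Analyte profiles are standardized to mean 0 / sd 1 across samples; the
    eigengene is the standardized first-principal-component score vector
    over samples, signed so it correlates non-negatively with the module's
    mean standardized profile. ``variance_explained`` is the leading
    eigenvalue fraction.

    ``include_grey`` appends an eigengene for the grey pseudo-module (when
    it has >= 2 members) so its trait correlations can be inspected — grey
    stays excluded from merging and key-driver candidacy.
    """
    values = x.values if isinstance(x, ScaledMatrix) else x
    modules = _size_ranked_modules(partition.module_of)
    if include_grey and (partition.module_of == GREY).sum() >= 2:
        modules = modules + [GREY]
    cols, ves = {}, {}
    for module in modules:
        members = partition.members(module)
        if len(members) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 analytes")
        scores, ve = _first_pc(values.loc[members].to_numpy(float))
        cols[module] = scores
        ves[module] = ve
    me = pd.DataFrame(cols, index=values.columns)
    return EigengeneMatrix(values=me, variance_explained=pd.Series(ves, dtype=float))


def _size_ranked_modules(module_of: pd.Series) -> list[str]:
    sizes = module_of[module_of != GREY].value_counts()
    return list(sizes.index)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Map arbitrary module ids to the color sequence, largest first.

    Ties broken by first analyte position for determinism."""
    non_grey = labels[labels != GREY]
    order = {}
    first_pos = {}
    for pos, (_, lab) in enumerate(non_grey.items()):
        first_pos.setdefault(lab, pos)
    sizes = non_grey.value_counts()
    ranked = sorted(sizes.index, key=lambda m: (-sizes[m], first_pos[m]))
    for i, m in enumerate(ranked):
        order[m] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    return labels.map(lambda m: GREY if m == GREY else order[m])


def detect_modules(
    x: ScaledMatrix | pd.DataFrame,
    network: CoexpressionNetwork,
    min_module_size: int = 25,
    merge_cut_height: float = 0.1,
    cut_height: float | str = "auto",
    reassign_threshold: float = 0.7,
) -> ModulePartition:
    """Detect co-expression modules from the TOM dendrogram.

    Average-linkage hierarchical clustering of 1 - TOM is cut at
    ``cut_height`` ("auto" = midpoint of the largest gap between sorted
    merge heights above the median — a simplified, deterministic stand-in
    for adaptive tree cutting; a float or ``("quantile", q)`` are also
    accepted). Clusters below ``min_module_size`` are dissolved; their
    members are reassigned to the module whose eigengene they correlate
    with most strongly when that |correlation| reaches
    ``reassign_threshold``, otherwise they fall into grey. Modules whose
    eigengenes are closer than ``merge_cut_height`` (dissimilarity
    1 - cor) are merged iteratively. Labels are size-ranked colors.
    """
    if network.tom is None:
        raise ValueError("network has no TOM; call tom_similarity first")
    values = x.values if isinstance(x, ScaledMatrix) else x
    analytes = network.analytes
    values = values.loc[analytes]
    n = len(analytes)
    if n < 2:
        raise ValueError("module detection needs at least 2 analytes")

    dissim = 1.0 - network.tom.to_numpy(float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    z = hierarchy.linkage(condensed, method="average")

    if cut_height == "auto":
        h = _gap_cut_height(z[:, 2])
    elif isinstance(cut_height, tuple) and cut_height[0] == "quantile":
        h = float(np.quantile(z[:, 2], cut_height[1]))
    else:
        h = float(cut_height)
    raw = hierarchy.fcluster(z, t=h, criterion="distance")
    labels = pd.Series(raw, index=analytes).astype(object)

    sizes = labels.value_counts()
    big = set(sizes.index[sizes >= min_module_size])
    labels[~labels.isin(big)] = GREY
    if not big:
        return ModulePartition(
            module_of=_relabel_by_size(labels),
            min_module_size=min_module_size,
            merge_cut_height=merge_cut_height,
            linkage=z,
        )

    # PAM-like rescue: reassign dissolved-cluster members by eigengene correlation
    grey_mask = labels == GREY
    if grey_mask.any() and reassign_threshold is not None:
        part = ModulePartition(module_of=labels, min_module_size=min_module_size)
        me = module_eigengenes(values, part)
        prof = _standardize_rows(values.loc[grey_mask].to_numpy(float))
        mev = me.values.to_numpy(float)
        mev_std = (mev - mev.mean(axis=0)) / mev.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore"):
            cors = np.nan_to_num(prof @ mev_std / (values.shape[1] - 1), nan=0.0)
        best = np.argmax(np.abs(cors), axis=1)
        best_cor = np.abs(cors)[np.arange(cors.shape[0]), best]
        grey_idx = labels.index[grey_mask]
        assign = best_cor >= reassign_threshold
        labels.loc[grey_idx[assign]] = me.values.columns.to_numpy()[best[assign]]

    # merge modules with near-identical eigengenes
    while True:
        mods = _size_ranked_modules(labels)
        if len(mods) < 2:
            break
        me = module_eigengenes(values, ModulePartition(module_of=labels))
        cor = np.corrcoef(me.values.to_numpy(float).T)
        dis = 1.0 - cor
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_cut_height:
            break
        a, b = me.values.columns[i], me.values.columns[j]
        labels[labels == b] = a

    return ModulePartition(
        module_of=_relabel_by_size(labels),
        min_module_size=min_module_size,
        merge_cut_height=merge_cut_height,
        linkage=z,
    )
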