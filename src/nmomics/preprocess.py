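"""Replicate-level intensity tables and fold-change statistics.

This module turns per-replicate analyte intensity tables (one per omics
layer) into filtered, normalized log2 fold-change matrices with raw and
Benjamini–Hochberg adjusted p-values, following the standard workflow for
label-based proteomics and kit-based targeted metabolomics:

* protein quantification from the top-three peptide intensities,
* log2 transformation and per-sample median centering,
* cell-count normalization with below-LOD censoring for metabolite
  concentrations,
* a replicate filter (analyte quantified in >= ``min_present`` of the
  replicates in *every* treatment, control included),
* two-sample Student t-tests of each treatment against the control on the
  log2 scale, with BH adjustment per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReplicateIntensityTable",
    "FoldChangeMatrix",
    "protein_quant_top3",
    "normalize_log2_median",
    "normalize_cell_count",
    "replicate_filter",
    "fold_change_test",
    "per_replicate_fold_changes",
    "bh_adjust",
    "count_significant",
]


@dataclass
class ReplicateIntensityTable:
    """Analyte x (treatment, replicate) intensities for one omics layer.

    ``values`` has the analyte identifiers as index and a two-level column
    MultiIndex ``(treatment, replicate)``. Entries may be NaN (absent
    measurement). ``control_label`` names the control treatment among the
    columns. ``cell_counts`` (optional, metabolomics) maps each
    ``(treatment, replicate)`` column to a positive cell count. ``lod``
    (optional) gives a per-analyte limit of detection; values below it are
    censored by :func:`normalize_cell_count`. ``is_log2`` records whether
    values are already on the log2 scale.
    """

    layer_name: str
    values: pd.DataFrame
    control_label: str
    cell_counts: pd.Series | None = None
    lod: pd.Series | None = None
    is_log2: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex) or self.values.columns.nlevels != 2:
            raise ValueError("values must have (treatment, replicate) MultiIndex columns")
        if self.control_label not in self.treatments:
            raise ValueError(
                f"control_label {self.control_label!r} not among treatments {self.treatments}"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate analyte identifiers: {dupes}")
        counts = pd.Series(self.values.columns.get_level_values(0)).value_counts()
        if counts.nunique() > 1:
            raise ValueError("every treatment must declare the same number of replicate columns")

    @property
    def treatments(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def analytes(self) -> pd.Index:
        return self.values.index

    def treatment_block(self, treatment: str) -> pd.DataFrame:
        return self.values[treatment]


@dataclass
class FoldChangeMatrix:
    """Per-layer log2 fold changes vs control with t-test p-values.

    All four frames share the analyte index; columns are the non-control
    treatments. ``p_adj`` is Benjamini–Hochberg adjusted over the layer's
    full (analyte, treatment) family by default.
    """

    layer_name: str
    log2fc: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_quantified: pd.DataFrame
    adjust_family: str = "layer"

    @property
    def treatments(self) -> list[str]:
        return list(self.log2fc.columns)

    @property
    def analytes(self) -> pd.Index:
        return self.log2fc.index


def protein_quant_top3(
    peptide_table: pd.DataFrame,
    protein_of: pd.Series,
    *,
    layer_name: str = "proteomics",
    control_label: str = "control",
    min_peptides: int = 2,
) -> ReplicateIntensityTable:
    """Summarize peptide intensities into protein intensities (top-3 rule).

    Per protein and sample, the protein intensity is the mean of the three
    highest peptide intensities present in that sample (all of them when
    fewer than three are present; absent when none is). Proteins identified
    by fewer than ``min_peptides`` peptides overall are dropped, mirroring
    the two-peptide identification rule.
    """
    protein_of = protein_of.reindex(peptide_table.index)
    if protein_of.isna().any():
        missing = protein_of.index[protein_of.isna()].tolist()
        raise ValueError(f"peptides without a protein mapping: {missing[:5]}")

    keep = protein_of.groupby(protein_of).transform("size") >= min_peptides
    table = peptide_table.loc[keep.to_numpy()]
    groups = protein_of.loc[keep.to_numpy()]

    def _top3_mean(block: pd.DataFrame) -> pd.Series:
        out = {}
        for col in block.columns:
            vals = block[col].dropna().to_numpy()
            if vals.size == 0:
                out[col] = np.nan
            else:
                vals.sort()
                out[col] = float(vals[-3:].mean())
        return pd.Series(out)

    prot = table.groupby(groups.to_numpy(), sort=True).apply(_top3_mean)
    prot.columns = peptide_table.columns
    prot.index.name = "protein"
    return ReplicateIntensityTable(
        layer_name=layer_name, values=prot, control_label=control_label
    )


def normalize_log2_median(table: ReplicateIntensityTable) -> ReplicateIntensityTable:
    """log2-transform and median-center each sample column.

    Every present value becomes ``log2(value) - median(log2 column)``, the
    median taken over present entries of that (treatment, replicate) column,
    so the per-column median is exactly zero afterwards.
    """
    if table.is_log2:
        raise ValueError(f"layer {table.layer_name!r} is already on the log2 scale")
    vals = table.values
    bad = vals.le(0)
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive intensity for analyte {vals.index[r]!r} in sample "
            f"{vals.columns[c]}: {vals.iat[r, c]}"
        )
    logged = np.log2(vals)
    centered = logged - logged.median(axis=0, skipna=True)
    return replace(table, values=centered, is_log2=True)


def log2_transform(table: ReplicateIntensityTable) -> ReplicateIntensityTable:
    """Plain log2 transform without centering (for data already on a
    common scale, e.g. kit concentrations normalized externally)."""
    if table.is_log2:
        raise ValueError(f"layer {table.layer_name!r} is already on the log2 scale")
    bad = table.values.le(0)
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive intensity for analyte {table.values.index[r]!r} in "
            f"sample {table.values.columns[c]}: {table.values.iat[r, c]}"
        )
    return replace(table, values=np.log2(table.values), is_log2=True)


def normalize_cell_count(
    table: ReplicateIntensityTable, *, reference_count: float = 1e6
) -> ReplicateIntensityTable:
    """Normalize concentrations to cell numbers; censor values below LOD.

    Each value is divided by its sample's cell count and multiplied by
    ``reference_count`` (concentration per ``reference_count`` cells).
    Values below the analyte's limit of detection are set absent before
    normalization — they never enter downstream statistics.
    """
    if table.cell_counts is None:
        raise ValueError(f"layer {table.layer_name!r} has no cell counts")
    counts = table.cell_counts.reindex(table.values.columns)
    has_data = table.values.notna().any(axis=0)
    missing = counts.isna() & has_data
    if missing.any():
        raise ValueError(f"missing cell count for samples with data: {counts.index[missing].tolist()}")
    if (counts.dropna() <= 0).any():
        raise ValueError("cell counts must be positive")
    vals = table.values.copy()
    if table.lod is not None:
        lod = table.lod.reindex(vals.index)
        vals = vals.mask(vals.lt(lod, axis=0))
    normed = vals.div(counts, axis=1) * reference_count
    return replace(table, values=normed)


def replicate_filter(
    table: ReplicateIntensityTable, min_present: int = 3
) -> pd.Index:
    """Analytes quantified in >= ``min_present`` replicates of every treatment.

    The control counts as a treatment; an analyte missing the threshold in
    any single treatment is dropped. Returns the retained analyte index.
    """
    present = table.values.notna().T.groupby(level=0).sum().T
    keep = (present >= min_present).all(axis=1)
    return table.analytes[keep]


def _log2_blocks(table: ReplicateIntensityTable) -> pd.DataFrame:
    if table.is_log2:
        return table.values
    bad = table.values.le(0)
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive value for analyte {table.values.index[r]!r} in "
            f"sample {table.values.columns[c]}; log2 transform impossible"
        )
    return np.log2(table.values)


def fold_change_test(
    table: ReplicateIntensityTable,
    *,
    adjust_family: str = "layer",
    min_per_group: int = 2,
) -> FoldChangeMatrix:
    """Log2 fold changes vs control with two-sample Student t-tests.

    For each analyte and non-control treatment: the fold change is the mean
    of the treatment's log2 replicate values minus the mean of the control's;
    the p-value is a two-sided, equal-variance two-sample t-test between the
    two replicate groups. p-values are BH-adjusted over the layer's full
    (analyte, treatment) family (``adjust_family="layer"``) or within each
    treatment column (``"treatment"``).

    Groups with fewer than ``min_per_group`` present values give an absent
    p-value; the fold change is still reported when at least one value is
    present on each side.
    """
    if adjust_family not in ("layer", "treatment"):
        raise ValueError(f"unknown adjust_family {adjust_family!r}")
    logv = _log2_blocks(table)
    ctrl = logv[table.control_label]
    ctrl_np = ctrl.to_numpy(float)
    treatments = [t for t in table.treatments if t != table.control_label]

    log2fc, p_raw, n_quant = {}, {}, {}
    for t in treatments:
        block = logv[t].to_numpy(float)
        n_t = np.sum(~np.isnan(block), axis=1)
        n_c = np.sum(~np.isnan(ctrl_np), axis=1)
        with np.errstate(invalid="ignore"):
            fc = np.nanmean(block, axis=1) - np.nanmean(ctrl_np, axis=1)
        res = stats.ttest_ind(block, ctrl_np, axis=1, equal_var=True, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        # zero pooled variance: t is 0/0; define p = 1 for a zero difference
        # (no evidence of change) and p = 0 for a nonzero one
        degenerate = np.isnan(p) & (n_t >= min_per_group) & (n_c >= min_per_group)
        p[degenerate] = np.where(np.isclose(fc[degenerate], 0.0), 1.0, 0.0)
        p[(n_t < min_per_group) | (n_c < min_per_group)] = np.nan
        fc[(n_t < 1) | (n_c < 1)] = np.nan
        log2fc[t] = fc
        p_raw[t] = p
        n_quant[t] = n_t

    idx = table.analytes
    log2fc = pd.DataFrame(log2fc, index=idx)
    p_raw = pd.DataFrame(p_raw, index=idx)
    n_quant = pd.DataFrame(n_quant, index=idx)

    if adjust_family == "layer":
        flat = p_raw.to_numpy().ravel()
        adj = _bh_with_nan(flat).reshape(p_raw.shape)
        p_adj = pd.DataFrame(adj, index=idx, columns=p_raw.columns)
    else:
        p_adj = p_raw.apply(lambda col: pd.Series(_bh_with_nan(col.to_numpy()), index=idx))

    return FoldChangeMatrix(
        layer_name=table.layer_name,
        log2fc=log2fc,
        p_raw=p_raw,
        p_adj=p_adj,
        n_quantified=n_quant,
        adjust_family=adjust_family,
    )


def per_replicate_fold_changes(table: ReplicateIntensityTable) -> pd.DataFrame:
    """Per-replicate log2 fold changes: replicate value minus control mean.

    Returns an analyte x (treatment, replicate) frame over the non-control
    treatments; used when the co-expression network is built across all
    measured samples rather than treatment means.
    """
    logv = _log2_blocks(table)
    ctrl_mean = logv[table.control_label].mean(axis=1, skipna=True)
    keep = [t for t in table.treatments if t != table.control_label]
    out = logv[keep].sub(ctrl_mean, axis=0)
    return out


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = bh_adjust(p[mask])
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment of a p-value vector.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1; values are returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_significant(
    fc: FoldChangeMatrix, alpha: float = 0.05, *, use_adjusted: bool = False
) -> pd.DataFrame:
    """Per-treatment counts of significantly altered analytes, split by sign.

    Returns a treatment x {up, down, total} frame of analytes with
    p <= ``alpha`` (raw p by default) and positive / negative log2 fold
    change.
    """
    p = fc.p_adj if use_adjusted else fc.p_raw
    sig = p.le(alpha)
    up = (sig & fc.log2fc.gt(0)).sum(axis=0)
    down = (sig & fc.log2fc.lt(0)).sum(axis=0)
    out = pd.DataFrame({"up": up, "down": down})
    out["total"] = out["up"] + out["down"]
    out.index.name = "treatment"
    return out
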