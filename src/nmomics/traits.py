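"""Module–trait correlation, gene significance / module membership, key drivers.

Module eigengenes are correlated against a treatment x trait matrix mixing
binary indicators (treatment identity, core material, morphology,
activity classes) with continuous physico-chemical properties (agglomerate
size, zeta potential, surface area, cell viability ...). Correlation
p-values use the exact Student-t transform. Key drivers are analytes whose
profile correlates strongly both with a trait (gene significance, GS) and
with their own module's eigengene (module membership, MM): by default
|GS| >= 0.75 and |MM| >= 0.75, restricted to modules significantly
correlated with the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitMatrix",
    "TraitCorrelation",
    "module_trait_correlation",
    "gene_significance",
    "module_membership",
    "select_key_drivers",
    "export_driver_lists",
    "significance_stars",
]

TRAIT_KINDS = ("treatment", "core_material", "morphology", "physchem", "toxicity", "activity_class")


@dataclass
class TraitMatrix:
    """Sample x trait values with a kind tag per trait.

    Samples must match the expression matrix sample labels. Binary traits
    hold only {0, 1} (NaN allowed); continuous traits keep native units.
    """

    values: pd.DataFrame
    trait_kind: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.trait_kind is None:
            self.trait_kind = pd.Series("physchem", index=self.values.columns)
        self.trait_kind = self.trait_kind.reindex(self.values.columns).fillna("physchem")
        bad = set(self.trait_kind) - set(TRAIT_KINDS)
        if bad:
            raise ValueError(f"unknown trait kinds: {sorted(bad)}")

    @property
    def traits(self) -> pd.Index:
        return self.values.columns

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    def is_binary(self, trait: str) -> bool:
        vals = self.values[trait].dropna().unique()
        return set(np.asarray(vals)) <= {0, 1, 0.0, 1.0}


@dataclass
class TraitCorrelation:
    """Module x trait Pearson correlations with Student-t p-values and stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame


def significance_stars(p: float) -> str:
    """Star annotation: *** p<=0.01, ** p<=0.05, * p<=0.1, else empty."""
    if np.isnan(p):
        return ""
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.1:
        return "*"
    return ""


def correlation_pvalue(r, n):
    """Two-sided p from the Student-t transform t = r sqrt(n-2)/sqrt(1-r^2)."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(n < 3, np.nan, p)
    return p


def _pairwise_corr(x: pd.DataFrame, y: pd.DataFrame, min_n: int = 3):
    """Pearson correlation of every column of x with every column of y,
    over pairwise-complete rows; returns (r, n) DataFrames."""
    r = np.full((x.shape[1], y.shape[1]), np.nan)
    n = np.zeros((x.shape[1], y.shape[1]), dtype=int)
    xv = x.to_numpy(float)
    yv = y.to_numpy(float)
    for j in range(y.shape[1]):
        yj = yv[:, j]
        for i in range(x.shape[1]):
            xi = xv[:, i]
            mask = ~(np.isnan(xi) | np.isnan(yj))
            m = int(mask.sum())
            n[i, j] = m
            if m < min_n:
                continue
            a, b = xi[mask], yj[mask]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            r[i, j] = np.corrcoef(a, b)[0, 1]
    return (
        pd.DataFrame(r, index=x.columns, columns=y.columns),
        pd.DataFrame(n, index=x.columns, columns=y.columns),
    )


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: TraitMatrix
) -> TraitCorrelation:
    """Correlate module eigengenes (sample x module) with every trait.

    Pearson correlation over shared, non-absent samples; two-sided p from
    the t transform with n-2 degrees of freedom; star annotations at the
    0.1 / 0.05 / 0.01 thresholds. Zero-variance traits give absent entries.
    """
    shared = eigengenes.index.intersection(traits.samples)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples between eigengenes and traits")
    me = eigengenes.loc[shared]
    tv = traits.values.loc[shared]
    r, n = _pairwise_corr(me, tv)
    p = pd.DataFrame(
        correlation_pvalue(r.to_numpy(), n.to_numpy()), index=r.index, columns=r.columns
    )
    stars = p.map(significance_stars)
    return TraitCorrelation(r=r, p=p, stars=stars, n=n)


def gene_significance(x: pd.DataFrame, traits: TraitMatrix) -> pd.DataFrame:
    """Analyte x trait gene significance: Pearson r of profile vs trait.

    ``x`` is analyte x sample (the network input matrix)."""
    shared = x.columns.intersection(traits.samples)
    r, _ = _pairwise_corr(x[shared].T, traits.values.loc[shared])
    return r


def module_membership(x: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Analyte x module membership: Pearson r of profile vs each eigengene."""
    shared = x.columns.intersection(eigengenes.index)
    r, _ = _pairwise_corr(x[shared].T, eigengenes.loc[shared])
    return r


def select_key_drivers(
    gs: pd.DataFrame,
    mm: pd.DataFrame,
    module_of: pd.Series,
    trait_correlation: TraitCorrelation | None = None,
    *,
    gs_threshold: float = 0.75,
    mm_threshold: float = 0.75,
    require_significant_module: bool = True,
    module_alpha: float = 0.05,
    grey_label: str = "grey",
) -> pd.DataFrame:
    """Select key-driver analytes per trait.

    For each trait, candidates are the analytes of non-grey modules whose
    module–trait correlation is significant (p <= ``module_alpha``) when
    ``require_significant_module``; otherwise all non-grey analytes. A
    candidate is a key driver iff |GS| >= ``gs_threshold`` AND |MM to its
    own module| >= ``mm_threshold`` (boundary included).

    Returns a table with columns (analyte, module, trait,
    gene_significance, module_membership, go_export).
    """
    if require_significant_module and trait_correlation is None:
        raise ValueError("trait_correlation required when require_significant_module")
    rows = []
    module_of = module_of.reindex(gs.index)
    own_mm = pd.Series(
        [
            mm.at[a, m] if (m in mm.columns and not pd.isna(m)) else np.nan
            for a, m in module_of.items()
        ],
        index=gs.index,
        dtype=float,
    )
    for trait in gs.columns:
        candidates = module_of.notna() & (module_of != grey_label)
        if require_significant_module:
            sig_modules = trait_correlation.p[trait].le(module_alpha)
            sig_modules = set(sig_modules.index[sig_modules]) - {grey_label}
            candidates &= module_of.isin(sig_modules)
        sel = (
            candidates
            & gs[trait].abs().ge(gs_threshold)
            & own_mm.abs().ge(mm_threshold)
        )
        for analyte in gs.index[sel]:
            rows.append(
                {
                    "analyte": analyte,
                    "module": module_of[analyte],
                    "trait": trait,
                    "gene_significance": gs.at[analyte, trait],
                    "module_membership": own_mm[analyte],
                    "go_export": True,
                }
            )
    cols = ["analyte", "module", "trait", "gene_significance", "module_membership", "go_export"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(
        ["trait", "gene_significance", "analyte"],
        key=lambda s: -s.abs() if s.name == "gene_significance" else s,
    ).reset_index(drop=True)


def export_driver_lists(table: pd.DataFrame) -> dict[str, list[str]]:
    """Per-trait analyte identifier lists for external GO/pathway services.

    Ordered by |gene significance| descending, ties broken lexicographically
    by identifier; one list per trait (empty table gives no lists)."""
    out: dict[str, list[str]] = {}
    if table.empty:
        return out
    for trait, sub in table.groupby("trait", sort=True):
        sub = sub.assign(_abs=sub["gene_significance"].abs())
        sub = sub.sort_values(["_abs", "analyte"], ascending=[False, True])
        out[str(trait)] = sub["analyte"].astype(str).tolist()
    return out
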