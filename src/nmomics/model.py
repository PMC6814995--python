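"""Integrative WGCNA as a model/results pair.

``IntegrativeWGCNA`` bundles the network-analysis stages behind a single
fitted-model interface: construct it from a scaled analyte x sample matrix
(or straight from per-layer fold-change matrices via
:meth:`IntegrativeWGCNA.from_fold_changes`), call :meth:`fit`, and read
modules, eigengenes, trait correlations, gene significance / module
membership and key drivers off the returned :class:`WGCNAResults`.

>>> model = IntegrativeWGCNA.from_fold_changes({"proteomics": fc}, traits)
>>> res = model.fit()
>>> print(res.summary())
>>> drivers = res.key_drivers()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net
from . import traits as tr

__all__ = ["IntegrativeWGCNA", "WGCNAResults"]


class IntegrativeWGCNA:
    """Weighted co-expression network model over one or more omics layers.

    Parameters
    ----------
    data : ScaledMatrix or DataFrame
        Analyte x sample expression (integer-scaled fold changes by
        convention; any complete numeric matrix works).
    traits : TraitMatrix or DataFrame, optional
        Sample x trait matrix for the trait-integration stage.
    beta : soft power for the adjacency (default 18).
    network_type : "unsigned" (|cor|^beta) or "signed" (((1+cor)/2)^beta).
    min_module_size, merge_cut_height, cut_height, reassign_threshold :
        module-detection tunables, see :func:`nmomics.network.detect_modules`.
    """

    def __init__(
        self,
        data: net.ScaledMatrix | pd.DataFrame,
        traits: tr.TraitMatrix | pd.DataFrame | None = None,
        *,
        beta: float = 18,
        network_type: str = "unsigned",
        min_module_size: int = 25,
        merge_cut_height: float = 0.1,
        cut_height: float | str = "auto",
        reassign_threshold: float = 0.7,
    ) -> None:
        if isinstance(data, net.ScaledMatrix):
            self.data = data.values
            self.layer_of = data.layer_of
        else:
            self.data = data
            self.layer_of = pd.Series("all", index=data.index)
        if traits is not None and not isinstance(traits, tr.TraitMatrix):
            traits = tr.TraitMatrix(values=traits)
        self.traits = traits
        if traits is not None:
            missing = [s for s in self.data.columns if s not in traits.samples]
            if missing:
                raise ValueError(f"trait matrix lacks samples: {missing}")
        self.beta = beta
        self.network_type = network_type
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.cut_height = cut_height
        self.reassign_threshold = reassign_threshold

    @classmethod
    def from_fold_changes(
        cls,
        fc_layers: dict,
        traits=None,
        *,
        lo: int = 0,
        hi: int = 100,
        **kwargs,
    ) -> "IntegrativeWGCNA":
        """Build the model from per-layer fold-change matrices.

        Each layer (a :class:`~nmomics.preprocess.FoldChangeMatrix` or a
        plain analyte x sample DataFrame) is scaled to integers in
        [lo, hi] before network construction, mirroring the published
        workflow's 0–100 integer scaling.
        """
        frames = {
            name: (fc.log2fc if hasattr(fc, "log2fc") else fc) for name, fc in fc_layers.items()
        }
        scaled = net.scale_to_int_range(frames, lo=lo, hi=hi)
        return cls(scaled, traits, **kwargs)

    def fit(self) -> "WGCNAResults":
        """Run adjacency -> TOM -> module detection -> eigengenes (+ traits)."""
        network = net.adjacency(self.data, beta=self.beta, network_type=self.network_type)
        network = net.tom_similarity(network)
        partition = net.detect_modules(
            self.data,
            network,
            min_module_size=self.min_module_size,
            merge_cut_height=self.merge_cut_height,
            cut_height=self.cut_height,
            reassign_threshold=self.reassign_threshold,
        )
        if partition.modules:
            # grey's eigengene is computed too so its trait correlations can
            # be inspected; it never joins merging or key-driver candidacy
            eigengenes = net.module_eigengenes(self.data, partition, include_grey=True)
        else:
            eigengenes = net.EigengeneMatrix(
                values=pd.DataFrame(index=self.data.columns),
                variance_explained=pd.Series(dtype=float),
            )
        trait_corr = gs = mm = None
        if self.traits is not None and not eigengenes.values.empty:
            trait_corr = tr.module_trait_correlation(eigengenes.values, self.traits)
            gs = tr.gene_significance(self.data, self.traits)
            mm = tr.module_membership(self.data, eigengenes.values)
        return WGCNAResults(
            model=self,
            network=network,
            partition=partition,
            eigengenes=eigengenes,
            module_trait=trait_corr,
            gene_significance=gs,
            module_membership_=mm,
        )


@dataclass
class WGCNAResults:
    """Fitted integrative-WGCNA results.

    Attributes hold the co-expression network (adjacency + TOM), the module
    partition (grey = unassigned), sample x module eigengenes, and — when a
    trait matrix was supplied — module–trait correlations with p-values and
    per-analyte gene significance / module membership.
    """

    model: IntegrativeWGCNA
    network: net.CoexpressionNetwork
    partition: net.ModulePartition
    eigengenes: net.EigengeneMatrix
    module_trait: tr.TraitCorrelation | None = None
    gene_significance: pd.DataFrame | None = None
    module_membership_: pd.DataFrame | None = field(default=None)

    @property
    def module_membership(self) -> pd.DataFrame | None:
        return self.module_membership_

    @property
    def module_sizes(self) -> pd.Series:
        return self.partition.size_of()

    @property
    def n_modules(self) -> int:
        """Number of detected modules excluding grey."""
        return len(self.partition.modules)

    def scale_free_r2(self) -> float:
        r2, _ = net.scale_free_fit(self.network)
        return r2

    def key_drivers(
        self,
        gs_threshold: float = 0.75,
        mm_threshold: float = 0.75,
        require_significant_module: bool = True,
        module_alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Key-driver table (|GS| and |MM| above threshold, per trait)."""
        if self.gene_significance is None:
            raise ValueError("model was fitted without traits")
        return tr.select_key_drivers(
            self.gene_significance,
            self.module_membership_,
            self.partition.module_of,
            self.module_trait,
            gs_threshold=gs_threshold,
            mm_threshold=mm_threshold,
            require_significant_module=require_significant_module,
            module_alpha=module_alpha,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Integrative weighted co-expression network analysis",
            "===================================================",
            f"analytes: {len(self.network.analytes)}   samples: {self.model.data.shape[1]}",
            f"network: {self.network.network_type}, soft power beta = {self.network.beta}",
            f"modules detected (excl. grey): {self.n_modules}",
            "",
            "module sizes:",
        ]
        sizes = self.module_sizes
        for mod in list(self.partition.modules) + ([net.GREY] if net.GREY in sizes else []):
            ve = self.eigengenes.variance_explained.get(mod, float("nan"))
            ve_txt = f"  var.explained = {ve:.2f}" if np.isfinite(ve) else ""
            lines.append(f"  {mod:<12} {sizes.get(mod, 0):>5}{ve_txt}")
        if self.module_trait is not None:
            lines += ["", "module-trait correlations (r, stars: * p<=0.1 ** p<=0.05 *** p<=0.01):"]
            r, stars = self.module_trait.r, self.module_trait.stars
            for mod in r.index:
                cells = [f"{t}={r.at[mod, t]:+.2f}{stars.at[mod, t]}" for t in r.columns]
                lines.append(f"  {mod:<12} " + "  ".join(cells))
        return "\n".join(lines)

    def plot_module_trait_heatmap(self, ax=None):
        """Module x trait correlation heatmap with star annotations.

        Requires matplotlib; returns the axes."""
        if self.module_trait is None:
            raise ValueError("model was fitted without traits")
        import matplotlib.pyplot as plt

        r = self.module_trait.r
        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.9 * r.shape[1], 1 + 0.5 * r.shape[0]))
        im = ax.imshow(r.to_numpy(float), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(r.shape[1]), r.columns, rotation=90)
        ax.set_yticks(range(r.shape[0]), r.index)
        for i in range(r.shape[0]):
            for j in range(r.shape[1]):
                ax.text(
                    j, i,
                    f"{r.iat[i, j]:.2f}{self.module_trait.stars.iat[i, j]}",
                    ha="center", va="center", fontsize=7,
                )
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax
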