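"""Pipeline configuration and the end-to-end driver.

``run_pipeline`` executes the full analysis: per-layer preprocessing
(normalization, replicate filter, fold-change t-tests), per-layer and
integrated hierarchical clustering with activity calls, 0–100 integer
scaling, co-expression network construction and module detection, trait
correlation, gene significance / module membership, key-driver selection
and driver-list export. Every stage writes TSV outputs tagged with the
tool version and config hash, plus a structured run log; identical config
and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, io, network, preprocess, simulate, traits
from .model import IntegrativeWGCNA

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the published defaults.

    ``layer_paths`` maps layer name -> replicate-table TSV path (ignored
    when ``simulate`` is true, in which case the generator settings under
    ``generator`` are used). ``network_layers`` restricts which layers
    enter the co-expression network (e.g. the SH2 layer joins the
    clustering figures but not the network); empty means all.
    """

    out_dir: str = "nmomics_out"
    layer_paths: dict = field(default_factory=dict)
    trait_path: str | None = None
    simulate: bool = False
    generator: dict = field(default_factory=dict)
    normalization: dict = field(default_factory=dict)  # layer -> log2_median|none
    network_layers: tuple = ()
    min_present: int = 3
    alpha: float = 0.05
    min_significant: int = 1
    min_active_layers: int = 2
    beta: float = 18.0
    min_module_size: int = 25
    merge_cut_height: float = 0.1
    cut_height: str | float = "auto"
    reassign_threshold: float = 0.7
    gs_threshold: float = 0.75
    mm_threshold: float = 0.75
    network_type: str = "unsigned"
    adjust_family: str = "layer"
    use_adjusted_p: bool = False
    max_network_export: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.network_layers = tuple(self.network_layers)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["network_layers"] = list(d["network_layers"])
        return yaml.safe_dump(d, sort_keys=True)

    def hash(self) -> str:
        # out_dir does not influence the analysis, so reruns into different
        # directories produce byte-identical data files
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d["network_layers"] = list(d["network_layers"])
        return io.config_hash(yaml.safe_dump(d, sort_keys=True))


def _generator_config(cfg: PipelineConfig) -> simulate.GeneratorConfig:
    raw = dict(cfg.generator)
    raw.setdefault("seed", cfg.seed)
    if "traits" in raw:
        raw["traits"] = tuple(simulate.TraitSpec(**t) for t in raw["traits"])
    if "layers" in raw:
        raw["layers"] = tuple((n, int(s)) for n, s in raw["layers"])
    return simulate.GeneratorConfig(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the output bundle under ``cfg.out_dir``.

    Returns a dict of the in-memory products (fold changes, activity call,
    fitted results, key drivers, ...). Any stage failure raises with the
    stage name prepended.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    (out / "config.resolved.yaml").write_text(cfg.to_yaml())
    log: list[dict] = []
    products: dict = {"log": log}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                entry = {
                    "stage": name,
                    "seconds": round(time.perf_counter() - self_inner.t0, 3),
                    "ok": exc is None,
                }
                log.append(entry)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Stage()

    # ---- inputs -----------------------------------------------------
    truth = None
    with stage("load"):
        if cfg.simulate:
            gen_cfg = _generator_config(cfg)
            ds = simulate.generate_dataset(gen_cfg)
            tables = ds.tables
            trait_matrix = ds.traits
            truth = ds.truth
            io.write_trait_matrix(trait_matrix, out / "traits.tsv", cfg_hash=h)
            for name, table in tables.items():
                io.write_replicate_table(table, out / f"input_{name}.tsv", cfg_hash=h)
            io.write_matrix_tsv(
                truth.module_of.to_frame("module"), out / "ground_truth_modules.tsv", cfg_hash=h
            )
        else:
            tables = {
                name: io.read_replicate_table(path, layer_name=name)
                for name, path in cfg.layer_paths.items()
            }
            trait_matrix = io.read_trait_matrix(cfg.trait_path) if cfg.trait_path else None
        products["tables"] = tables
        products["traits"] = trait_matrix
        products["truth"] = truth

    # ---- preprocess -------------------------------------------------
    fcs: dict[str, preprocess.FoldChangeMatrix] = {}
    with stage("preprocess"):
        # simulated layers are generated on a common scale already, so the
        # default there is a plain log2 transform; measured intensity tables
        # default to log2 + median centering
        default_norm = "log2" if cfg.simulate else "log2_median"
        for name, table in tables.items():
            how = cfg.normalization.get(name, default_norm)
            if how == "log2_median" and not table.is_log2:
                table = preprocess.normalize_log2_median(table)
            elif how == "log2" and not table.is_log2:
                table = preprocess.log2_transform(table)
            elif how not in ("log2_median", "log2", "none"):
                raise ValueError(f"unknown normalization {how!r} for layer {name!r}")
            kept = preprocess.replicate_filter(table, cfg.min_present)
            table = dataclasses.replace(table, values=table.values.loc[kept])
            fc = preprocess.fold_change_test(table, adjust_family=cfg.adjust_family)
            fcs[name] = fc
            io.write_matrix_tsv(fc.log2fc, out / f"fc_{name}_log2fc.tsv", cfg_hash=h)
            io.write_matrix_tsv(fc.p_raw, out / f"fc_{name}_p_raw.tsv", cfg_hash=h)
            io.write_matrix_tsv(fc.p_adj, out / f"fc_{name}_p_adj.tsv", cfg_hash=h)
            counts = preprocess.count_significant(fc, cfg.alpha, use_adjusted=cfg.use_adjusted_p)
            io.write_matrix_tsv(counts, out / f"significant_counts_{name}.tsv", cfg_hash=h)
        products["fold_changes"] = fcs

    # ---- integration clustering + activity calls --------------------
    with stage("integrate"):
        integrated = clustering.scale_to_symmetric_range(fcs)
        dend = clustering.hierarchical_cluster(integrated, axis="columns")
        (out / "treatment_dendrogram.nwk").write_text(dend.to_newick() + "\n")
        io.write_matrix_tsv(
            pd.DataFrame({"leaf_order": dend.leaf_order()}),
            out / "treatment_leaf_order.tsv",
            cfg_hash=h,
        )
        call = clustering.call_activity(
            fcs,
            alpha=cfg.alpha,
            min_significant=cfg.min_significant,
            min_active_layers=cfg.min_active_layers,
            use_adjusted=cfg.use_adjusted_p,
        )
        io.write_matrix_tsv(call.evidence, out / "activity_evidence.tsv", cfg_hash=h)
        io.write_matrix_tsv(
            call.per_layer.assign(overall=call.overall), out / "activity_calls.tsv", cfg_hash=h
        )
        products["integrated"] = integrated
        products["dendrogram"] = dend
        products["activity"] = call

    # ---- network + modules + traits ---------------------------------
    with stage("network"):
        net_layers = cfg.network_layers or tuple(fcs)
        model = IntegrativeWGCNA.from_fold_changes(
            {n: fcs[n] for n in net_layers},
            trait_matrix,
            beta=cfg.beta,
            network_type=cfg.network_type,
            min_module_size=cfg.min_module_size,
            merge_cut_height=cfg.merge_cut_height,
            cut_height=cfg.cut_height,
            reassign_threshold=cfg.reassign_threshold,
        )
        results = model.fit()
        io.write_matrix_tsv(
            results.partition.module_of.to_frame("module"), out / "modules.tsv", cfg_hash=h
        )
        io.write_matrix_tsv(results.eigengenes.values, out / "eigengenes.tsv", cfg_hash=h)
        if len(results.network.analytes) <= cfg.max_network_export:
            io.write_matrix_tsv(results.network.tom, out / "tom.tsv", cfg_hash=h)
        products["results"] = results

    # ---- trait correlation + key drivers ----------------------------
    if trait_matrix is not None:
        with stage("traits"):
            mt = results.module_trait
            io.write_matrix_tsv(mt.r, out / "module_trait_r.tsv", cfg_hash=h)
            io.write_matrix_tsv(mt.p, out / "module_trait_p.tsv", cfg_hash=h)
            io.write_matrix_tsv(mt.stars, out / "module_trait_stars.tsv", cfg_hash=h)
            io.write_matrix_tsv(results.gene_significance, out / "gene_significance.tsv", cfg_hash=h)
            io.write_matrix_tsv(results.module_membership, out / "module_membership.tsv", cfg_hash=h)

        with stage("drivers"):
            drivers = results.key_drivers(
                gs_threshold=cfg.gs_threshold, mm_threshold=cfg.mm_threshold
            )
            io.write_matrix_tsv(drivers.set_index("analyte"), out / "key_drivers.tsv", cfg_hash=h)
            lists = traits.export_driver_lists(drivers)
            list_dir = out / "driver_lists"
            list_dir.mkdir(exist_ok=True)
            for trait_name, ids in lists.items():
                safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in trait_name)
                (list_dir / f"{safe}.txt").write_text("\n".join(["analyte"] + ids) + "\n")
            products["key_drivers"] = drivers

    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return products
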