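"""Synthetic multi-omics data with planted modules, traits and key drivers.

The generator emulates the structure of a nanomaterial multi-omics screen:
two (or more) omics layers measured over 12 treatments plus an untreated
control with 5 replicates each, block-structured co-expression driven by
latent module eigengene profiles, traits that are noisy linear (or
median-thresholded binary) functions of those eigengenes, planted
differential analytes, per-measurement missingness, and a background
("grey") fraction of pure-noise analytes. Every downstream stage can then
be scored against the returned ground truth.

Model per layer, on the log2 scale:

    value(analyte i, treatment t, replicate r)
        = baseline_i + latent_it + eps_itr,            eps ~ N(0, replicate_noise_sd)
    latent_it = loading_i * eigengene(module(i), t) + eta_it    (module analytes)
              = delta_it                                        (background),
    eta ~ N(0, noise_sd)

where eta models imperfect co-expression within a module and delta is the
planted differential effect (0 or +-effect_size) of background analytes.

with latent = 0 at the control, so treatment-vs-control log2 fold changes
recover the planted structure. Intensities are written as 2**value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GREY
from .preprocess import ReplicateIntensityTable
from .traits import TraitMatrix

__all__ = ["TraitSpec", "GeneratorConfig", "GroundTruth", "SimulatedDataset", "generate_dataset", "activity_fixture"]

#: Treatment names of the emulated 12-nanomaterial panel.
DEFAULT_TREATMENTS = (
    "SiO2_15_Unmod", "SiO2_15_Amino", "SiO2_15_Phospho", "SiO2_40", "SiO2_7",
    "SiO2_7_TMS2", "SiO2_7_TMS3", "TiO2_NM105", "Graphene_Oxide",
    "Phthalocyanine_Blue", "Phthalocyanine_Green", "Mn2O3",
)


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: driven by one module's eigengene.

    Continuous traits reach ``target_correlation`` with the driving
    eigengene exactly (noise built orthogonal, then mixed); binary traits
    threshold the eigengene at its median (sign taken from
    ``target_correlation``). ``scale``/``offset`` map the standardized
    values to native units.
    """

    name: str
    driving_module: int
    target_correlation: float
    binary: bool = False
    kind: str = "physchem"
    scale: float = 1.0
    offset: float = 0.0


def _default_traits() -> tuple[TraitSpec, ...]:
    return (
        TraitSpec("agglomerate_size", 0, 0.9, False, "physchem", 500.0, 900.0),
        TraitSpec("zeta_potential", 1, -0.9, False, "physchem", 12.0, -25.0),
        TraitSpec("surface_area", 2, 0.9, False, "physchem", 100.0, 180.0),
        TraitSpec("cell_viability", 3, -0.9, False, "toxicity", 20.0, 75.0),
        TraitSpec("active_in_vitro", 4, 0.9, True, "activity_class"),
        TraitSpec("active_in_vivo", 5, 0.9, True, "activity_class"),
    )


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic screen.

    Defaults are the emulated study conditions: 12 treatments x 5
    replicates (plus control), 1174 proteins + 88 metabolites, 9 planted
    modules plus a 10% grey background, loadings in [0.6, 0.95],
    noise_sd 0.1 and 2% missingness.
    """

    n_treatments: int = 12
    n_replicates: int = 5
    layers: tuple[tuple[str, int], ...] = (("proteomics", 1174), ("metabolomics", 88))
    n_modules: int = 9
    module_sizes: tuple[int, ...] | None = None
    background_fraction: float = 0.1
    loading_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 0.1
    replicate_noise_sd: float | None = None
    missing_rate: float = 0.02
    traits: tuple[TraitSpec, ...] = field(default_factory=_default_traits)
    effect_size: float = 2.0
    differential_rate: float = 0.1
    active_treatments: tuple[str, ...] | None = None
    signed: bool = False
    min_module_size: int = 25
    control_label: str = "control"
    treatment_names: tuple[str, ...] | None = None
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    @property
    def n_analytes_total(self) -> int:
        return sum(n for _, n in self.layers)

    def resolved_module_sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(self.module_sizes)
        if self.n_modules == 0:
            return ()
        assignable = int(round(self.n_analytes_total * (1.0 - self.background_fraction)))
        base = assignable // self.n_modules
        sizes = [base + (1 if i < assignable % self.n_modules else 0) for i in range(self.n_modules)]
        return tuple(sizes)

    def resolved_treatments(self) -> tuple[str, ...]:
        if self.treatment_names is not None:
            if len(self.treatment_names) != self.n_treatments:
                raise ValueError("treatment_names length must equal n_treatments")
            return tuple(self.treatment_names)
        if self.n_treatments == len(DEFAULT_TREATMENTS):
            return DEFAULT_TREATMENTS
        return tuple(f"T{i + 1:02d}" for i in range(self.n_treatments))

    def validate(self) -> None:
        sizes = self.resolved_module_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError(f"module sizes must be >= 1, got {sizes}")
        if sum(sizes) > self.n_analytes_total:
            raise ValueError(
                f"module sizes sum to {sum(sizes)} > {self.n_analytes_total} analytes"
            )
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or (self.replicate_noise_sd is not None and self.replicate_noise_sd < 0):
            raise ValueError("noise standard deviations must be non-negative")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ValueError("loading_range must satisfy 0 < lo <= hi")
        for t in self.traits:
            if not -1.0 <= t.target_correlation <= 1.0:
                raise ValueError(
                    f"trait {t.name!r}: target correlation {t.target_correlation} outside [-1, 1]"
                )
            if not 0 <= t.driving_module < max(len(sizes), 1):
                raise ValueError(f"trait {t.name!r} references missing module {t.driving_module}")
        if self.n_treatments < 3:
            raise ValueError("need at least 3 treatments")


@dataclass
class GroundTruth:
    """Planted structure: module labels, eigengenes, drivers, differentials."""

    module_of: pd.Series
    eigengene_profiles: pd.DataFrame
    driver_flags: pd.DataFrame
    differential_flags: pd.DataFrame
    loadings: pd.Series

    def module_names(self) -> list[str]:
        mods = [m for m in self.module_of.unique() if m != GREY]
        return sorted(mods)


@dataclass
class SimulatedDataset:
    """Generator output bundle: one replicate table per layer, traits, truth."""

    tables: dict[str, ReplicateIntensityTable]
    traits: TraitMatrix
    truth: GroundTruth
    config: GeneratorConfig


def _orthogonal_mix(rng, base: np.ndarray, target_r: float) -> np.ndarray:
    """Unit-variance vector whose sample correlation with ``base`` is exactly
    ``target_r`` (noise drawn orthogonal to base, then mixed)."""
    n = base.size
    b = (base - base.mean()) / base.std()
    for _ in range(100):
        z = rng.standard_normal(n)
        z = z - z.mean()
        z = z - (z @ b) / (b @ b) * b
        if z.std() > 1e-12:
            break
    else:
        raise ValueError("could not construct orthogonal noise for trait")
    z = (z - z.mean()) / z.std()
    return target_r * b + np.sqrt(max(0.0, 1.0 - target_r**2)) * z


def generate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """Generate the synthetic multi-omics screen described by ``config``.

    Deterministic given ``config.seed``. Returns replicate-level intensity
    tables (one per layer), the treatment x trait matrix and the ground
    truth used to score downstream recovery.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    treatments = config.resolved_treatments()
    sizes = config.resolved_module_sizes()
    k_modules = len(sizes)
    n_total = config.n_analytes_total
    rep_sd = config.noise_sd if config.replicate_noise_sd is None else config.replicate_noise_sd

    # analyte identifiers per layer, pooled
    analytes: list[str] = []
    layer_of: list[str] = []
    for li, (layer, n) in enumerate(config.layers):
        prefix = layer[:1].upper()
        analytes += [f"{prefix}{i + 1:05d}" for i in range(n)]
        layer_of += [layer] * n
    analytes_idx = pd.Index(analytes, name="analyte")
    layer_of = pd.Series(layer_of, index=analytes_idx)

    # module assignment over the pooled universe (modules may span layers)
    perm = rng.permutation(n_total)
    module_names = [f"M{i + 1}" for i in range(k_modules)]
    module_of = pd.Series(GREY, index=analytes_idx, dtype=object)
    start = 0
    for name, size in zip(module_names, sizes):
        module_of.iloc[perm[start : start + size]] = name
        start += size

    # latent eigengene profiles, i.i.d. standard normal per treatment
    eig = rng.standard_normal((k_modules, config.n_treatments))
    eigengenes = pd.DataFrame(eig, index=module_names, columns=list(treatments))

    # loadings: uniform in range; sign flips only in signed mode
    lo, hi = config.loading_range
    loadings = pd.Series(rng.uniform(lo, hi, size=n_total), index=analytes_idx)
    if config.signed:
        loadings *= rng.choice([-1.0, 1.0], size=n_total)
    loadings[module_of == GREY] = np.nan

    # planted background differentials
    active = treatments if config.active_treatments is None else tuple(config.active_treatments)
    unknown = set(active) - set(treatments)
    if unknown:
        raise ValueError(f"active_treatments not in treatment panel: {sorted(unknown)}")
    diff_flags = pd.DataFrame(False, index=analytes_idx, columns=list(treatments))
    delta = np.zeros((n_total, config.n_treatments))
    bg_mask = (module_of == GREY).to_numpy()
    for ti, t in enumerate(treatments):
        if t not in active or config.differential_rate <= 0:
            continue
        hit = bg_mask & (rng.random(n_total) < config.differential_rate)
        sign = rng.choice([-1.0, 1.0], size=int(hit.sum()))
        delta[hit, ti] = sign * config.effect_size
        diff_flags.iloc[hit, ti] = True

    # treatment-level latent values; the residual eta models imperfect
    # co-expression and so applies to module analytes only — background
    # analytes stay exactly null (up to replicate noise) unless planted
    latent = np.zeros((n_total, config.n_treatments))
    module_rows = (module_of != GREY).to_numpy()
    for mi, name in enumerate(module_names):
        rows = (module_of == name).to_numpy()
        latent[rows] = np.outer(loadings[rows], eig[mi])
    latent += delta
    eta = rng.normal(0.0, config.noise_sd, size=latent.shape)
    latent[module_rows] += eta[module_rows]

    # replicate-level log2 intensities, control latent = 0
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_total)
    all_treatments = list(treatments) + [config.control_label]
    columns = pd.MultiIndex.from_product(
        [all_treatments, range(1, config.n_replicates + 1)], names=["treatment", "replicate"]
    )
    n_cols = len(all_treatments) * config.n_replicates
    log2_vals = np.repeat(baseline[:, None], n_cols, axis=1)
    full_latent = np.hstack([latent, np.zeros((n_total, 1))])  # control column
    log2_vals += np.repeat(full_latent, config.n_replicates, axis=1)
    log2_vals += rng.normal(0.0, rep_sd, size=log2_vals.shape)

    if config.missing_rate > 0:
        mask = rng.random(log2_vals.shape) < config.missing_rate
        log2_vals[mask] = np.nan

    intensities = pd.DataFrame(2.0**log2_vals, index=analytes_idx, columns=columns)
    tables = {
        layer: ReplicateIntensityTable(
            layer_name=layer,
            values=intensities.loc[layer_of == layer],
            control_label=config.control_label,
        )
        for layer, _ in config.layers
    }

    # traits from driving eigengenes
    trait_cols, kinds = {}, {}
    for spec in config.traits:
        base = eig[spec.driving_module]
        if spec.binary:
            cut = np.median(base)
            col = (base >= cut).astype(float)
            if spec.target_correlation < 0:
                col = 1.0 - col
        else:
            col = _orthogonal_mix(rng, base, spec.target_correlation)
            col = col * spec.scale + spec.offset
        trait_cols[spec.name] = col
        kinds[spec.name] = spec.kind
    trait_values = pd.DataFrame(trait_cols, index=list(treatments))
    trait_matrix = TraitMatrix(values=trait_values, trait_kind=pd.Series(kinds))

    # planted key drivers: predicted |GS| and |MM| >= 0.75 by construction.
    # The prediction uses the realized sample correlation of EVERY module's
    # eigengene with the trait (n is small, so off-target modules can reach
    # the threshold by chance and their members then genuinely qualify),
    # times the analyte's population correlation with its own eigengene.
    driver_flags = pd.DataFrame(
        False, index=analytes_idx, columns=[s.name for s in config.traits]
    )
    sigma_t = np.sqrt(config.noise_sd**2 + rep_sd**2 / config.n_replicates)
    for spec in config.traits:
        tvals = trait_values[spec.name].to_numpy(float)
        if np.std(tvals) == 0:
            continue
        for mi, mod in enumerate(module_names):
            r_mt = float(np.corrcoef(eig[mi], tvals)[0, 1])
            members = module_of == mod
            l = loadings[members].abs().to_numpy()
            cor_me = l / np.sqrt(l**2 + sigma_t**2)
            pred_gs = cor_me * abs(r_mt)
            flag = (pred_gs >= 0.75) & (cor_me >= 0.75)
            driver_flags.loc[members, spec.name] = flag

    truth = GroundTruth(
        module_of=module_of,
        eigengene_profiles=eigengenes,
        driver_flags=driver_flags,
        differential_flags=diff_flags,
        loadings=loadings,
    )
    return SimulatedDataset(tables=tables, traits=trait_matrix, truth=truth, config=config)


def activity_fixture(
    seed: int = 0,
    n_analytes: int = 60,
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS,
    active_two_layer: tuple[str, ...] = (
        "TiO2_NM105", "Graphene_Oxide", "SiO2_40", "Phthalocyanine_Blue",
    ),
    single_layer: tuple[str, ...] = ("SiO2_7",),
    n_significant: int = 8,
):
    """Three fold-change layers with planted per-layer significance patterns.

    Treatments in ``active_two_layer`` receive significant analytes in all
    three layers, ``single_layer`` treatments in exactly one layer, the rest
    in none — mimicking a panel with 4 clearly active, 1 equivocal and 7
    passive treatments. Returns (layers dict of FoldChangeMatrix, expected
    call dict).
    """
    from .preprocess import FoldChangeMatrix

    rng = np.random.default_rng(seed)
    layer_names = ("proteomics", "sh2", "metabolomics")
    layers = {}
    for li, layer in enumerate(layer_names):
        idx = pd.Index([f"{layer[:1].upper()}{i + 1:04d}" for i in range(n_analytes)])
        fc = pd.DataFrame(
            rng.normal(0, 0.2, size=(n_analytes, len(treatments))),
            index=idx, columns=list(treatments),
        )
        p = pd.DataFrame(
            rng.uniform(0.2, 1.0, size=(n_analytes, len(treatments))),
            index=idx, columns=list(treatments),
        )
        for t in treatments:
            plant = t in active_two_layer or (t in single_layer and li == 0)
            if plant:
                rows = rng.choice(n_analytes, size=n_significant, replace=False)
                p.iloc[rows, p.columns.get_loc(t)] = rng.uniform(1e-6, 0.01, size=n_significant)
                fc.iloc[rows, fc.columns.get_loc(t)] = rng.choice([-1, 1], n_significant) * rng.uniform(1, 3, n_significant)
        layers[layer] = FoldChangeMatrix(
            layer_name=layer, log2fc=fc, p_raw=p, p_adj=p.copy(),
            n_quantified=pd.DataFrame(5, index=idx, columns=list(treatments)),
        )
    expected = {
        t: ("active" if t in active_two_layer else "equivocal" if t in single_layer else "passive")
        for t in treatments
    }
    return layers, expected
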