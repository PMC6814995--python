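# nmomics

Integrative multi-omics co-expression network analysis for treatment
categorization and key-driver (biomarker candidate) selection.

The package targets screens in which a panel of treatments — e.g. engineered
nanomaterials applied to a lung epithelial cell line — is profiled across
several omics layers (global proteomics, targeted metabolomics,
phospho-profiling), each as per-replicate intensity tables against an
untreated control. It answers two questions:

1. **Which treatments are biologically "active"?** Per layer, treatments
   with significantly altered analyte abundances are flagged; integrated
   hierarchical clustering and a cross-layer rule categorize each treatment
   as *active* / *equivocal* / *passive*.
2. **Which biomolecules drive the response?** A weighted co-expression
   network over all layers groups analytes into modules, modules are
   correlated with treatment and physico-chemical trait matrices, and
   analytes strongly tied to both a trait and their module are reported as
   key drivers.

## Method

Per layer, analyte intensities are normalized (log2 + per-sample median
centering for proteomics; cell-count normalization with below-LOD censoring
for metabolomics), filtered to analytes quantified in ≥ 3 of 5 replicates in
every treatment, and converted to log2 fold changes vs control with
two-sample Student t-tests and Benjamini–Hochberg adjustment.

The network core is weighted gene correlation network analysis (WGCNA). For
analyte profiles x_i scaled per layer to integers in [0, 100]:

- adjacency `a_ij = |cor(x_i, x_j)|^β` with soft power β = 18 (unsigned;
  signed `((1+cor)/2)^β` available),
- topological overlap `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`
  where `l_ij = Σ_u a_iu a_uj` and `k_i = Σ_u a_iu`,
- average-linkage clustering of `1 − TOM`, tree cut with minimum module
  size 25, eigengene-based module merging at dissimilarity 0.1, size-ranked
  color labels with `grey` for unassigned analytes,
- module eigengenes = first principal component of the standardized module
  expression,
- gene significance `GS(i, trait) = cor(x_i, trait)`, module membership
  `MM(i, m) = cor(x_i, ME_m)`, correlation p-values from the Student-t
  transform,
- key drivers: `|GS| ≥ 0.75` and `|MM| ≥ 0.75` within modules significantly
  correlated (p ≤ 0.05) with the trait.

A synthetic-data generator plants known modules, traits, differential
analytes and key drivers, so the whole pipeline is testable against ground
truth (see `docs/methods.md`).

## Worked example

```python
import nmomics as nm
from nmomics.simulate import TraitSpec

cfg = nm.GeneratorConfig(
    layers=(("proteomics", 200), ("metabolomics", 50)),
    n_modules=5,
    traits=(
        TraitSpec("agglomerate_size", 0, 0.9, False, "physchem", 500.0, 900.0),
        TraitSpec("cell_viability", 1, -0.9, False, "toxicity", 20.0, 75.0),
        TraitSpec("active_in_vitro", 2, 0.9, True, "activity_class"),
    ),
    seed=7,
)
ds = nm.generate_dataset(cfg)

# preprocess each layer: log2, replicate filter, t-tests vs control
import dataclasses
fcs = {}
for name, table in ds.tables.items():
    table = nm.preprocess.log2_transform(table)
    kept = nm.replicate_filter(table, 3)
    table = dataclasses.replace(table, values=table.values.loc[kept])
    fcs[name] = nm.fold_change_test(table)

res = nm.IntegrativeWGCNA.from_fold_changes(fcs, ds.traits).fit()
print(res.summary())
```

prints

```
Integrative weighted co-expression network analysis
===================================================
analytes: 250   samples: 12
network: unsigned, soft power beta = 18
modules detected (excl. grey): 5

module sizes:
  turquoise       46  var.explained = 0.93
  blue            45  var.explained = 0.97
  brown           45  var.explained = 0.98
  yellow          45  var.explained = 0.98
  green           45  var.explained = 0.99
  grey            24  var.explained = 0.21

module-trait correlations (r, stars: * p<=0.1 ** p<=0.05 *** p<=0.01):
  turquoise    agglomerate_size=-0.55*  cell_viability=-0.89***  active_in_vitro=-0.27
  blue         agglomerate_size=+0.90***  cell_viability=+0.33  active_in_vitro=+0.22
  brown        agglomerate_size=+0.12  cell_viability=+0.08  active_in_vitro=+0.85***
  yellow       agglomerate_size=-0.15  cell_viability=+0.05  active_in_vitro=+0.20
  green        agglomerate_size=-0.25  cell_viability=+0.26  active_in_vitro=+0.12
  grey         agglomerate_size=+0.06  cell_viability=+0.43  active_in_vitro=+0.34
```

(The grey row is reported for inspection only — unassigned analytes never
enter key-driver candidacy.)

The five planted modules are recovered (45–46 analytes each, eigengenes
explaining ≥ 93% of module variance) and each trait correlates strongly and
significantly with exactly its driving module. Key drivers follow from the
GS/MM rule:

```python
kd = res.key_drivers()        # 135 rows
kd.head(3)
# analyte module           trait  gene_significance  module_membership
#  P00020  brown active_in_vitro           0.894510           0.990735
#  P00152  brown active_in_vitro           0.882796           0.989160
#  P00094  brown active_in_vitro           0.881132           0.982309
```

Activity categorization on a panel where only four treatments respond
(planted differential analytes in both layers, BH-adjusted p ≤ 0.05, at
least 2 significant analytes per layer, active in ≥ 2 layers):

```python
call = nm.call_activity(fcs, alpha=0.05, min_significant=2, use_adjusted=True)
call.overall.value_counts()   # {'passive': 8, 'active': 4}
```

recovers exactly the four planted active treatments (TiO2_NM105,
Graphene_Oxide, SiO2_40, Phthalocyanine_Blue).

The same analysis runs from the shell:

```sh
nmomics simulate --config config.yaml --seed 7 --out results/
nmomics run --config config.yaml --out results/     # on measured tables
```

writing TSV matrices (fold changes, p-values, modules, eigengenes,
module–trait correlations, key drivers), Newick dendrograms, per-trait
driver lists for GO/pathway services, and a structured run log; every file
is tagged with the tool version and a config hash.

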