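# Methods

This note documents the models and procedures implemented in `nmomics`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Statistical preprocessing

Each omics layer arrives as an analyte × (treatment, replicate) intensity
table with an untreated control among the treatments. The default design is
12 treatments × 5 biological replicates plus control.

* **Protein quantification** (when starting from peptide tables): protein
  intensity per sample is the mean of the three highest peptide intensities
  present in that sample ("top-3" rule); proteins identified by fewer than
  two peptides are dropped. A sample with no quantified peptide yields an
  absent entry, never zero.
* **Normalization**: proteomics intensities are log2-transformed and
  median-centered per sample column (median over present entries, so each
  column's median is exactly 0 afterwards). Metabolite concentrations are
  divided by the sample's cell count (reported per 10⁶ cells by default)
  after censoring values below the analyte's limit of detection to absent.
  Absent values propagate; they are never imputed.
* **Replicate filter**: an analyte is retained only if quantified in at
  least `min_present = 3` of the replicates in *every* treatment, control
  included. The retained count is monotone non-increasing in the threshold.
* **Fold changes and tests**: log2 FC = mean log2 treatment replicates −
  mean log2 control replicates. Significance is a two-sided, equal-variance
  two-sample Student t-test of the two replicate groups on the log2 scale.
  When the pooled variance is exactly zero the p-value is defined as 1 for
  a zero difference and 0 otherwise (the t statistic is 0/0 there). Groups
  with fewer than two present values give an absent p-value; the FC is
  still reported when each side has at least one value.
* **Multiple testing**: Benjamini–Hochberg step-up over the layer's full
  (analyte × treatment) family by default; a per-treatment family is
  available. The implementation delegates to
  `statsmodels.stats.multitest` and is cross-checked in the test suite
  against a brute-force step-up oracle.
* **Significance counting** uses raw p ≤ 0.05 by default (an adjusted-p
  mode exists), split by FC sign, matching the usual per-layer reporting
  convention for such screens.

One genuinely open choice is whether fold changes should be computed from
group means (done here) or per replicate pair and averaged; with balanced
groups the two coincide in expectation and the group-mean version has the
cleaner relation to the t-test, so it is the default and only mode.

## Integration and activity calls

For joint clustering, each layer's FC matrix is linearly mapped so that its
global minimum and maximum land on −2 and +2 (constant layers map to 0) and
the layers are stacked over the shared treatment axis — this prevents the
layer with the widest dynamic range from dominating distances. Treatments
(or analytes) are clustered with Euclidean distance and complete linkage;
with absent values, distances fall back to pairwise-complete coordinates
rescaled by √(p/m) so they remain comparable. Dendrograms are exported as
Newick text.

Activity categorization formalizes the narrative "active/passive" calls of
such studies: a treatment is active *in a layer* when at least
`min_significant` analytes are significantly altered (p ≤ α); overall it is
**active** when active in ≥ 2 layers, **equivocal** when active in exactly
one, **passive** otherwise. All three knobs are configurable; the call is
monotone in α. This ≥2-layers rule is an interpretation — the studies the
pipeline is modeled on describe the overall call qualitatively — and is
flagged as such here rather than in the output files.

## Weighted co-expression network

The network stage follows the WGCNA methodology, re-implemented here and
verified against brute-force definitions:

* **Input scaling**: per layer, FCs are linearly mapped to integers in
  [0, 100] (min → 0, max → 100, rounding half away from zero for platform
  determinism; constant layers map to 50). Correlations are scale-free, so
  this step mainly standardizes the serialized input format.
* **Adjacency**: `a_ij = |cor(x_i, x_j)|^β`, Pearson over
  pairwise-complete samples, β = 18, unsigned by default (the signed
  variant `((1+cor)/2)^β` is a switch). Pairs sharing fewer than 3 samples
  are treated as uncorrelated rather than crashing the run.
* **TOM**: `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, `TOM_ii = 1`;
  the degenerate case `a_ij = 1` with zero surrounding connectivity is
  defined as 1. Verified to 1e−12 against a triple-loop oracle.
* **Module detection**: average-linkage clustering of `1 − TOM`. Published
  adaptive tree-cut algorithms carry many unstated heuristics, so a
  simplified, fully deterministic cut is used: the tree is cut at the
  midpoint of the largest gap between successive sorted merge heights above
  the median height ("auto"). On modular data the within-module merges and
  the between-module joins form two well-separated height bands and the
  largest gap sits between them. A fixed numeric height and a
  merge-height-quantile variant are available; a quantile default was
  considered and rejected because on modular dendrograms the top ~10% of
  merges *are* the between-module joins, so any high fixed quantile cuts
  above them and fuses modules.
* **Small-cluster rescue**: clusters below `min_module_size = 25` dissolve
  into grey; their members are individually reassigned to the module whose
  eigengene they correlate with most strongly if that |cor| ≥ 0.7,
  otherwise they stay grey. The 0.7 default keeps the rescue conservative:
  under the null (12 samples) |cor| ≥ 0.7 has probability ≈ 0.01 per
  module, so background analytes are rarely absorbed, while genuine module
  members (|cor| ≈ 0.95+) essentially always return home.
* **Module merging**: modules whose eigengenes have dissimilarity
  `1 − cor(ME_a, ME_b) < 0.1` are merged iteratively (closest pair first,
  eigengene recomputed after each merge). The 0.1 cut is read as this
  standard eigengene merge height: a static cut of the 1 − TOM dendrogram
  at 0.1 would leave almost everything unassigned.
* **Labels**: modules are named by the conventional color sequence
  (turquoise, blue, brown, ...) in decreasing size order, ties broken by
  first analyte position; `grey` is reserved for unassigned analytes.
* **Eigengenes**: analyte profiles are standardized (mean 0, sd 1 across
  samples, ddof = 1); the module eigengene is the standardized first
  principal component score vector over samples, with sign fixed so it
  correlates non-negatively with the module's mean standardized profile.
  `variance_explained` is the leading eigenvalue fraction, verified against
  full eigendecomposition to 1e−10. Zero-variance analytes are dropped from
  the PC computation.

## Trait integration and key drivers

Traits live in a treatment × trait matrix mixing binary indicators
(treatment identity, core material, morphology, activity classes coded
0/1) and continuous physico-chemical properties in native units
(agglomerate size in nm, zeta potential in mV, viability in %, ...).
Module–trait correlation, gene significance GS(i, t) = cor(x_i, t) and
module membership MM(i, m) = cor(x_i, ME_m) are plain Pearson correlations
over shared non-absent samples; p-values use the exact Student-t transform
t = r√(n−2)/√(1−r²) with n−2 df, two-sided, annotated with stars at
p ≤ 0.1 / 0.05 / 0.01. No multiplicity correction is applied across the
module × trait grid (none is standard for this heatmap; the per-cell
p-values are exported so users can adjust). Grey-module correlations are
computed but grey is excluded from key-driver candidacy.

Key drivers for a trait are analytes with |GS| ≥ 0.75 **and** |MM to their
own module| ≥ 0.75 (boundaries included), restricted by default to modules
whose trait correlation is significant at p ≤ 0.05 (an unrestricted mode
exists). Selection is monotone in both thresholds. Driver lists are
exported per trait, ordered by |GS| descending with lexicographic
tie-breaking, as one-column text files ready for external GO/pathway
enrichment services.

With only 12 treatment-level samples, correlation estimates are noisy
(se ≈ 0.3 under the null); thresholded rules at 0.75 therefore sit close to
the noise floor, which is a property of such study designs, not of the
implementation — see the recovery numbers below for what this costs.

## Synthetic-data generator

The generator produces the study conditions the pipeline is validated
under: 12 treatments (named after a 12-nanomaterial panel) × 5 replicates
plus control; 1174 protein and 88 metabolite profiles; 9 planted modules
with a 10% grey background; loadings uniform in [0.6, 0.95] (all-positive
by default, matching the unsigned network; random signs in signed mode);
treatment-level residual sd 0.1; replicate noise sd 0.1; 2% missingness.

On the log2 scale:

```
value(i, t, r) = baseline_i + latent_it + eps_itr,   eps ~ N(0, sd_rep)
latent_it      = loading_i · E_m(i),t + eta_it        (module analytes)
               = delta_it                             (background)
```

with latent ≡ 0 at the control. Eigengene profiles E are i.i.d. standard
normal per treatment. The residual eta models imperfect co-expression and
applies only to module analytes, so unplanted background analytes are
exactly null — without this, every analyte would be weakly differential
and significance counts would have no clean ground truth. Planted
differential effects delta (±effect_size, default 2) go to background
analytes of designated "active" treatments. Intensities are written as
2^value, so the pipeline's log2/fold-change machinery applies unchanged.
Because the generator emulates data already on a common scale, pipeline
runs on simulated data default to a plain log2 transform; median centering
remains the default for measured intensity tables (on simulated data,
where ~90% of analytes carry module signal, a per-column median would
itself track the eigengenes and contaminate every profile with a shared
component).

Continuous traits are built to hit their target correlation with the
driving eigengene *exactly*: noise is drawn, orthogonalized against the
eigengene, standardized and mixed as r·Ê + √(1−r²)·ẑ, then mapped to
plausible native units. Binary traits threshold the driving eigengene at
its median (point-biserial correlation ≈ 0.8 as realized). Default
driver-bearing continuous traits use |r| = 0.9 so predicted gene
significances (≈ 0.89) sit clear of the 0.75 selection boundary; the
binary traits land near 0.79 and contribute most residual flag flips.

Ground-truth driver flags are computed from the realized structure: for
every (module, trait) pair the realized sample correlation of the
eigengene with the trait is multiplied by each member's population
analyte–eigengene correlation l/√(l² + σ²); analytes with both predicted
|GS| ≥ 0.75 and predicted |MM| ≥ 0.75 are flagged. All modules are
scanned, not just the designated driver: with 12 samples an off-target
eigengene occasionally correlates above threshold by chance and its
members then genuinely satisfy the selection rule.

What the generator does **not** emulate: mass spectra or chromatograms,
peptide-level structure (the top-3 quantifier is tested on hand-built
tables), batch effects or sample-loading biases, analyte-specific variance
heterogeneity, correlated missingness (missingness is uniform at random),
or chemical realism of specific nanomaterials. Passing recovery tests
therefore demonstrates the correctness of the statistical machinery under
the planted model, not robustness to every artifact of real LC-MS data.

## Verification results (computed by the test suite / acceptance script)

* TOM and eigengene variance explained agree with brute-force definitions
  to 1e−12 / 1e−10.
* Over 20 planted screens (9 modules ≥ 25 analytes + 10% grey, noise 0.1):
  mean partition ARI ≈ 0.98, matched eigengene |cor| ≈ 0.999, key-driver
  recall ≈ 0.97 and precision ≈ 0.97 pooled over seeds and traits.
* t-test type-I error ≈ 0.05 at n = 5 vs 5 over 10,000 null simulations;
  BH equals the step-up oracle to machine precision on 1,000 random
  vectors.
* A planted 12-treatment panel (4 multi-layer active, 1 single-layer,
  7 silent) is called 4 active / 1 equivocal / 7 passive.
* At study scale the replicate filter retains ≈ 1174 proteins and 88
  metabolites and module detection finds the 9 planted modules (grey makes
  a 10th group). The scale-free topology R² is near zero on this synthetic
  network: equal-size planted modules produce a two-point connectivity
  distribution, not a power law, so the diagnostic is expected to be
  uninformative there (it is exercised separately on a constructed
  power-law network).

## Numerical conventions and limitations

Determinism: all randomness flows through `numpy.random.default_rng(seed)`;
identical config + seed reproduces outputs byte-for-byte (floats are
serialized with shortest-round-trip `repr`). Rounding in the 0–100 scaling
is half-away-from-zero, which unlike banker's rounding is stable across
platforms. Output files carry the tool version and a hash of the resolved
configuration (excluding the output directory).

Limitations: the network stage materializes dense n × n matrices, so it is
intended for up to a few thousand analytes, not transcriptome-scale inputs;
no consensus networks across datasets; no bootstrap support values on
dendrograms; the simplified tree cut has no deep-split ladder — data whose
dendrogram lacks a clear height gap between within- and between-module
merges will under-split relative to adaptive cutters. Whether the network
is built over treatment-level fold changes (default, 12 columns) or all
replicate-level samples is a config choice; per-replicate fold changes are
provided for the latter.
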