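# Methods

`spatialedge` re-implements, as a tested pipeline over fully synthetic
data, a spatially resolved analysis of tumor architecture in oral
squamous cell carcinoma (OSCC): malignant spot calling on a hex-lattice
spatial transcriptomics array, annotation of tumor core (TC),
transitory and leading edge (LE) states, consensus differential
expression, gene-set scoring, neighborhood composition, RNA-velocity
fate-transition graphs with in-silico drug perturbation, and prognostic
survival modelling of the TC/LE signatures.  This note records the
models, the parameters that matter, and the design choices made where
the design was genuinely open.

## The synthetic study system

Real inputs of this kind of study — Visium count matrices,
velocyto-style spliced/unspliced layers, CARD-style deconvolution
proportions, CNV posterior probabilities, pathologist labels, drug
panels, survival cohorts — are all emulated by `spatialedge.simulate`,
so every downstream stage can be exercised and validated against
planted ground truth without any download.

**Geometry.** Spots live on a Visium-style staggered grid (spot at
integer `(row, col)` iff row and column share parity; six neighbors at
`(row, col±2)`, `(row±1, col±1)`).  The tumor is concentric in hex
distance from the lattice center: core for `d ≤ 4`, transitory ring for
`4 < d ≤ 6`, leading edge for `6 < d ≤ 9`, stroma outside.  On the
default 40×40 lattice this gives 800 spots, 271 of them tumor (61 TC,
66 transitory, 144 LE).  Concentric zoning guarantees the LE borders
stroma and the TC is enclosed, which the neighborhood analysis relies
on.  Pseudotime is the normalized hex distance from the tumor center,
encoding the core→edge differentiation axis.

**Expression.** Counts are negative binomial
(`var = μ(1 + φμ)`, dispersion φ = 0.15) around gene base means
(lognormal, median ≈ 3) with lognormal spot library-size factors
(σ = 0.12).  Two planted cancer programs drive the zonal structure: a
core program (including the literature TC markers *CLDN4*, *SPRR1B*)
at 8×/3×/1× of base in TC/transitory/LE, and an edge program (including
the LE markers *LAMC2*, *ITGA5*) mirrored.  The multipliers are
region-stepped rather than continuous so that graph clustering sees
three discrete states, as the real analysis does after clustering a
continuum.  Stroma spots carry cell-type marker boosts (e.g. *LRRC15*,
*GJB2* for ecm-myCAF; *ADH1B*, *GPX3* for detox-iCAF) in distance bands
— a CAF collar hugging the LE, fibroblast/iCAF mixtures further out,
immune types beyond — matching the fibroblast-at-the-front organisation
the neighborhood analysis is meant to detect.

**Channels.** Tumor spots draw cancer deconvolution proportion and CNV
probability from `0.99 + 0.01·Beta(2,2)` (mean 0.995, almost surely
above the 0.99 calling threshold); stroma spots get low values and a
cell-type-dominant deconvolution row.  Pathology is "SCC" exactly on
tumor spots.  By default the channels are noise-free with respect to
the truth, so the malignancy call recovers the planted tumor exactly;
`channel_noise` degrades a configurable fraction of tumor spots.  No
claim is made about the error structure of real deconvolution or CNV
inference — these magnitudes are free parameters.

**Splicing kinetics.**  The spliced/unspliced layers follow the
standard two-stage model `du/dt = α − βu`, `ds/dt = βu − γs` evaluated
in closed form at each spot's pseudotime (β = 1, γ ~ U(0.4, 1)), with
Poisson sampling and a 0.5 unspliced capture factor.  Edge-program
genes are in induction (rising along TC→LE, positive velocity),
core-program genes in repression from steady state (falling, negative
velocity), and all other genes at steady state (zero expected
velocity).  This makes the planted velocity field point from the TC
state toward the LE state in expression space.

The degradation-rate recovery benchmark
(`simulate_gamma_benchmark`) samples each gene's induction curve at
uniform times with a random per-gene phase offset (wrap-around time).
Asynchrony matters: if all genes moved along the trajectory together,
per-spot library-size normalization would compress the shared
trajectory and bias the ratio estimate; with asynchronous genes —
the realistic condition — the estimator's median relative error is
about 2% at 2,000 spots × 200 genes.

**Drug panel.**  Per drug, AAC values (area above the dose-response
curve, in [0, 1]) are generated per cell line × dataset around a
drug-level base drawn from Beta(12.6, 50.4) (mean 0.20, SD 0.05 —
matching the scale of aggregated AAC values reported for HNSCC cell
line panels, median ≈ 0.16, range ≈ 0.03–0.56).  Half the drugs are
"flow-reversing": they target planted LE-driver genes with
down-regulating interaction keywords and their base AAC is shifted up
by the effect size (default 0.2, i.e. 4 SD of the drug-level spread).
The rest target housekeeping genes with keywords drawn from the
up/down/neutral pools; drugs whose keywords carry no direction are
dropped by the screen, as in the real filtering.

**Survival cohort.**  275 patients by default.  Latent TC and LE
factors are bivariate normal (correlation −0.2, the weak negative
regime reported for these programs); signature genes (40 per program
out of 2,000) load on their factor with unit weight over unit noise.
Scores are then computed from the realized expression with the same
rank-based scoring the analysis uses, standardized, and the hazard is
`λ0·exp(log HR_LE·z_LE + log HR_TC·z_TC)` — or, in binary-risk mode, a
jump of log HR at a quantile of the LE score, which is the design the
cutpoint-recovery experiments use.  Censoring is administrative:
uniform entry before a fixed cutoff, with the follow-up window
calibrated by bisection so the expected censored fraction hits the
target (default 30%).  The transcriptome is kept large (2,000 genes)
because rank scores of two sets within one sample are mechanically
anti-correlated in proportion to the sets' share of the transcriptome;
at 40/2,000 that artifact is negligible and the realized TC/LE score
correlation tracks the configured latent correlation.

All generators draw from a single `numpy.random.Generator` per call;
identical (config, seed) pairs are byte-identical.

## Annotation

Spots detecting fewer than 200 genes are removed; counts are scaled to
the median library size and log1p-transformed.  (The variance-
stabilizing regression used by Seurat's SCTransform is deliberately not
re-implemented; downstream contracts only require a monotone
normalized layer.)

A spot is malignant iff (cancer deconvolution proportion > 0.99 OR
CNV probability > 0.99) AND the pathologist label is SCC — both
inequalities strict, so 0.99 itself does not qualify.  Non-malignant
spots are typed by the largest non-cancer deconvolution proportion,
ties broken by the declared column order.

Malignant spots are embedded with PCA (30 components by default),
joined into a Seurat-style shared-nearest-neighbor graph (k = 20,
Jaccard weights, pruned below 1/15) and partitioned with Leiden
community detection (RBConfiguration, resolution 1.0, seeded — the
resolution parameter has the same meaning as in Louvain modularity
clustering, and Leiden is the maintained successor available here).
Cluster-mean PC embeddings are joined by an average-linkage Euclidean
tree cut into three nodal groups; the group with the highest mean
normalized expression of the core markers becomes TC, of the edge
markers LE, the remainder transitory.  If one group maximizes both
scores, or a marker score cannot single out a group, the annotation
refuses rather than guessing.  Cross-sample batch integration is not
re-implemented; synthetic samples are generated batch-free.

## Differential expression and consensus

Per sample, TC vs LE is tested gene-wise with a two-sided Wilcoxon
rank-sum test on the normalized layer.  Midranks handle ties; for
groups of at most eight spots the null is enumerated exactly over all
assignments of the pooled midranks, otherwise the tie-corrected normal
approximation with continuity correction is used.  Only genes detected
in at least three spots of either group are tested, and the Bonferroni
factor is that per-sample count.  The fold-change convention is
`log2((mean expm1(norm_A) + 1) / (mean expm1(norm_B) + 1))`;
significance requires |log2FC| > 0.25 and adjusted p < 0.001.

A gene enters the consensus when significant *with the same direction*
in ≥ 10 of 12 samples (direction consistency is implied but not stated
in the protocols this follows; it is required here and pinned by test).  Its
cumulative log2FC sums the qualifying samples' values; ranking is by
support count, then |cumulative log2FC|.  Region-by-sample structure is
summarized by Pearson correlation of region-mean expression profiles.

## Gene-set scoring

Three scorers, matching the three scoring styles used in this kind of
analysis:

* **Control-bin module score** (the `AddModuleScore` scheme): genes are
  cut into 24 equal-frequency bins of mean expression; each signature
  gene contributes 100 control genes sampled with replacement from its
  bin (seeded); score = mean signature expression − mean control
  expression per spot.  The score is linear in expression and exactly
  zero when controls replicate the signature.
* **Signed composite score** for two-sided programs (e.g. cancer
  stem-cell states with predicted up- and down-regulated genes):
  module score of the up-set minus module score of the down-set.  The
  "inverse expression (1/x)" transform sometimes used for single
  down-genes is noted but not used — reciprocals are unstable at zero.
* **Rank score** (single-sample, singscore-style): with set size k and
  transcriptome size n, the mean ascending midrank of the set is mapped
  linearly onto [−0.5, +0.5] between its minimum (k+1)/2 and maximum
  (2n−k+1)/2 achievable values.  Invariant under monotone transforms.

Region comparisons run either on per-sample region means with a paired
two-sided Wilcoxon signed-rank test (the paired design cancels
between-sample baselines) or on spot-level values with the rank-sum
test, corrected by Bonferroni or Benjamini–Hochberg.  Both units are
provided because either unit is defensible for the
paired tests.

## Neighborhood composition

For each of TC and LE, the non-malignant spots directly in contact
(hex adjacency) with at least one spot of the region are collected,
classified by their dominant non-cancer deconvolution type and counted
per cell type.  A spot touching both regions counts toward both;
double-counting is a design choice, pinned by test.
Spots (not contact edges) are counted, also a pinned choice.
Transitory neighbors are excluded from the comparison, which contrasts
TC against LE only.  Across samples, per-type counts are compared with
a two-sided rank-sum test, BH-corrected across cell types.

## Velocity, state graphs and perturbation

The dynamical-EM velocity model and the analytic vector-field
perturbation machinery of scVelo and Dynamo are large published
methods in their own right; this package replaces them with a transparent steady-state analog that preserves every
contract the downstream analysis depends on (flow direction,
row-stochastic state graphs, signature sums).  The correspondence is
structural, not numerically exact, and the Jv-style magnitude units
are mapped by convention (below).

* **Moments.** Spliced and unspliced layers are library-size
  normalized and smoothed as first-order moments over k = 30 neighbors
  (self included) in a 10-component PCA embedding of the log spliced
  layer.
* **Steady-state ratio.** Per gene, γ̂ is the regression of u on s
  through the origin (`Σus/Σs²`) over the union of the top and bottom
  5% quantiles of s — the spots closest to the extremes of the
  phase portrait.  Genes with zero spliced signal are masked.
* **Velocity.** `v = u − γ̂·s` on the smoothed layers, projected into
  the embedding through the PCA loadings with the log1p chain rule
  (`v/(1+s)`).  Velocity confidence is the Pearson correlation between
  a spot's velocity vector and the mean velocity of its 30 embedding
  neighbors; zero-variance vectors get confidence 0 with a warning.
* **Vector field.** A radial-basis-function kernel-ridge regressor
  from embedding positions to embedded velocities, fit around the mean
  velocity (so infinite ridge shrinks to the mean, and tiny ridge
  interpolates).  Bandwidth defaults to the median pairwise distance;
  ridge to 1e-4.
* **Transition matrix.** For each spot and its 30 nearest embedding
  neighbors, `P_ij ∝ exp(cos∠(v_i, x_j − x_i)/σ)` with σ = 0.1, rows
  normalized, no self-loops; spots with numerically zero velocity
  spread uniformly.  Rank order of the flow signatures is stable for
  σ ∈ [0.02, 0.5] (test-pinned).
* **State graph.** `Q[A→B]` is the mean over spots of state A of their
  total transition mass into state B — normalize-then-average, pinned
  by test (averaging before normalizing is the rejected alternative).  The
  "edge outgoing" signature is `Q[LE→transitory] + Q[LE→TC]`; "core
  incoming" is `Q[LE→TC] + Q[transitory→TC]`.
* **Perturbation.** Each target gene's velocity column is overridden
  with `(M/200)` standard deviations of its smoothed spliced
  expression per unit time at every spot — M = −200/+200 for down/up
  interactions, −1000 for the checkpoint-gene variant, M = 0 meaning
  no perturbation.  The SD-per-unit-time mapping is a convention for
  Jv-style units, not a claim of equivalence.  After
  the override the field is re-projected, smoothed through the vector
  field, and the state graph rebuilt.  `PerturbationEngine` caches the
  embedding neighbors and the kernel factorization, so a 40-drug screen
  costs milliseconds per drug after the one-off setup.

On the planted system the baseline graph has net TC→LE flow, and
down-perturbing the LE drivers raises the edge-outgoing signature by
two to three orders of magnitude — the flow-reversal phenotype the drug
screen quantifies.

## Drug screen

Aggregation follows the two-step rule: per cell line, AAC is averaged
across datasets; per drug, the 10% trimmed mean across cell lines
(dropping `floor(0.1·n)` values from each tail — the conventional
symmetric trim; "10% trimmed mean" alone does not fix a tail
convention).  Drugs in fewer than 25 cell lines are excluded.
Interaction keywords map to directions by exact, case-insensitive
membership in the published up/down keyword lists; anything else is
"none" and the target is dropped.  Drugs with no directional,
expressed target are excluded.  Retained drugs are stratified at the
median aggregated AAC (values exactly at the median go to "low"; strict
inequalities alone would leave the median element unassigned) and
the flow signatures are compared high vs low with a two-sided rank-sum
test.  A thin utility groups drugs into mechanism-of-action classes
(fuzzy string match, Levenshtein ≤ 3; classes need > 1 member) and
compares signatures across classes by Kruskal–Wallis.

## Survival

The optimal cutpoint maximizes the absolute standardized log-rank
statistic over all unique score values that leave at least
`minprop = 0.2` of patients on each side (0.1 for the pan-cancer
variant), ties to the smaller cutpoint.  Kaplan–Meier curves and Cox
fits (Efron tie handling) come from lifelines; the hand-authored
log-rank statistic is cross-checked against lifelines in the tests.
The reported p-value comes from the
subsequent Cox fit and is **not** corrected for the cutpoint selection;
under the null, the selected-split Cox interval covers HR = 1 only
about three times in four, so selection bias is real and the null
calibration checks use the continuous-score Cox fit instead.  Monotone
likelihood (complete separation) raises with context rather than
returning silently.

## Problem sizes and validation

Default experiment sizes — 800-spot samples (271 malignant), 300–400
genes, 12-sample cohorts, 40-drug screens, n = 275–300 cohorts, 20–100
Monte Carlo replicates — were chosen so every recovery and calibration
property is measurable with comfortable statistical margins on a single
CPU in minutes.  The acceptance checks verify, end to end: γ̂ recovery
(median relative error < 10%; observed ≈ 2%), row-stochasticity and a
brute-force recomputation of the transition kernel, flow reversal under
driver knockdown (20/20 seeds), screen power at the planted effect
(≥ 90%) with type-I error ≈ 5% under the null, exact truth-table
agreement of the malignancy rule, ≥ 95% region recovery, consensus
sensitivity ≥ 0.9 with ≤ 1 false gene, the within- vs between-region
correlation ordering, cutpoint/HR recovery and null coverage ≥ 90%
(100 simulations per arm; the cutpoint-recovery arm uses 15% censoring
to realize clearly separated risk groups), and oracle agreement of the
shared statistical primitives.

## What passing does and does not show

The generators plant exactly the structure each stage is built to
detect, with noise levels that make the planted effects recoverable at
the stated sizes.  Passing therefore demonstrates that the
implementations are correct and internally consistent — not that the
biological conclusions transfer, and not that the simplified velocity
analog reproduces the numerical outputs of the dynamical-EM/vector-
field stack it stands in for.  Real tissue adds segmentation error,
batch effects, spatially varying capture, deconvolution and CNV error
structure, and drug–target promiscuity, none of which are modelled.
Known limitations: no cross-sample integration; no selection-bias
correction for maximally selected cutpoints (a deliberate design mirror,
documented above); neighbor analysis assumes the concentric
geometry's LE–stroma contact; the consensus direction-consistency rule
is an interpretation, pinned by test.
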