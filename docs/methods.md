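# Methods

This note documents the models, conventions and numerical choices behind
`ontomet`, in the order data flows through the package.

## Ontology model

An ontology is a set of CURIE-identified terms with `is_a` parents; only
the subclass hierarchy defines reachability.  Relationship edges such as
`part_of` or `regulates` are deliberately not traversed: the engine's
queries are *subclass* queries, and mixing relation semantics into the
closure would silently change what a query means.  Multiple parents are
supported everywhere (GO is a DAG); taxonomies happen to be trees but the
code never assumes single parents.

Obsolete terms are loaded (so files round-trip) but excluded from every
closure.  A parent reference that does not resolve within the file is
recorded in a dangling-parent report rather than dropped or raised:
production ontology releases legitimately contain both situations, and a
hard failure would make real files unreadable while silent dropping would
corrupt closures.  Acyclicity is verified at load time; a violation
reports one concrete cycle.

Taxonomic ranks are read from `property_value: has_rank` lines (the NCBI
taxonomy convention); a missing rank is `"no rank"`.  Label resolution is
case-insensitive and exact — no fuzzy matching, because a near-miss that
silently resolves to the wrong class is worse than an error.

Subset extraction keeps the requested terms plus all recursive parents,
restricting edges to the retained set.  Written OBO output sorts stanzas
by term id so the serialization is byte-stable.

## Store and queries

Count tables are long-format `(sample, term, count)` with duplicate keys
summed under a warning — parallelized annotation jobs can shard one term
across files, so duplicates are a merge artifact, not corruption.

Sample QC removes samples with fewer than 5,000,000 raw reads or fewer
than 10,000 distinct taxon annotations; both thresholds are inclusive at
the boundary and configurable.  The richness rule is applied to the loaded
taxon table as-is.

A query combines: the subclass closure of a feature class (GO class →
function table, otherwise taxon table); optional project, environment
class, required-measurement, depth-range and measurement-range
constraints.  Environment matching expands the queried ENVO class over its
subclass closure by default (a sample tagged `coastal water body` matches
a query for `marine water body`), with a flag for exact matching; the
expansion is the natural reading of ontology-driven discovery, and the
flag preserves the stricter alternative.  All numeric ranges are half-open
`[lo, hi)` so adjacent bins partition a gradient without overlap or gap.

### RDF export

The store exports to N-Triples under a minimal namespace
(`https://w3id.org/ontomet/`): samples are typed `Sample`, linked to a
project resource via `from_project` and to OBO PURL term IRIs via
`has_env_class`; each (sample, term) count and each (sample, parameter)
measurement is a dedicated node typed by its term IRI and carrying a
`count` (xsd:integer) or `value` (xsd:double) literal.  URIs, never blank
nodes, identify count/measurement nodes, and triples are emitted sorted,
so exports are byte-identical across runs and fully round-trippable by
any conformant reader.  The vocabulary is this package's own, chosen for
structural fidelity to count/measurement/context data rather than
compatibility with any particular triplestore.

## Preprocessing

* **Relativization.** Gene counts are divided by the sample's ORF count;
  taxon counts by its post-QC read count.  These are the denominators that
  generated the counts, so the quotients are comparable across samples.
* **Clade aggregation** sums relativized abundance over a clade root and
  its full subtree.  This assumes each read/ORF is counted at exactly one
  node (Kraken2-style assignment), so a subtree sum never double-counts;
  that assumption is a data contract, not something the code can verify.
* **Species/strain filter** keeps terms ranked `species` or below a
  species-ranked term (strains, subspecies).
* **Prevalence filter** retains a term iff it reaches ≥ 1 count-per-million
  in ≥ 5% of samples.  CPM uses the per-sample total *of the same table*
  (not the QC read count): "counts per million" is table-relative, and the
  choice is explicit here so users can substitute the read-count
  denominator if they prefer.
* **CLR transform.** `clr_i = ln x_i − mean_j ln x_j` per sample.  Zero
  handling must be explicit for reproducibility: the default adds a
  pseudocount of half the matrix's smallest nonzero value, *only when
  zeros are present* (zero-free compositions are transformed exactly);
  multiplicative replacement (zeros → 65% of the row minimum, nonzeros
  rescaled to preserve the total) is available.  An all-zero row has no
  composition and is an error.
* **Variance filter** removes the `ceil(0.30 · p)` highest-variance
  features, ties broken by term id for determinism.  The packaged recipes
  apply it after relativization and before CLR; the order is recorded in
  every run manifest.
* **Binning** assigns half-open intervals; a value exactly on a cut point
  falls in the upper bin.  Default bin boundaries (depth 200/600 m,
  anoxic < 20 µmol/kg dissolved O₂, river/marine DIC cut at
  1000 µmol/kg) are configuration values chosen from common oceanographic
  usage, not constants of the method.

## Statistics

All permutation tests use the add-one estimator
`p = (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm)`, whose floor at the
default 999 permutations is exactly 0.001; all randomness is driven by a
caller-supplied seed, making results bit-reproducible.

* **Spearman** is the Pearson correlation of average ranks with pairwise
  deletion of missing values (scipy's implementation after deletion);
  fewer than three complete pairs or degenerate ranks raise.
* **PERMANOVA** uses Euclidean distances.  With squared distances d²,
  `SS_total = Σ_{i<j} d²_ij / n`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`,
  `pseudo-F = ((SS_total − SS_within)/(k−1)) / (SS_within/(n−k))`.  In one
  dimension this reduces exactly to the classical one-way ANOVA F, which
  the tests assert to 1e-10.
* **Dispersion test** computes each sample's distance to its group
  centroid (raw Euclidean space — centroids, not spatial medians; with a
  Euclidean embedding no negative-eigenvalue correction arises) and
  permutes group labels over those fixed distances.
* **IndVal.g**: for feature f and group g, specificity
  `A = mean(f|g) / Σ_k mean(f|k)` (per-group means, so unbalanced designs
  do not bias A) and fidelity `B = occupancy of f in g`; the statistic is
  `√(A·B)`, 1 only for a feature present in every sample of one group and
  absent elsewhere.  Each feature's p-value compares its best-group
  statistic against label permutations.  Only single groups are scored;
  site-group combinations are out of scope.  All-zero features are
  reported as absent rather than failing the run.
* **Elastic net.** Objective
  `(1/2n)·deviance + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` over a decreasing λ path
  (100 points from the data-derived λ_max down by 10⁻³ for gaussian,
  10⁻² for binomial — tiny penalties on small-n binomial fits are
  ill-conditioned and never win the 1-SE rule).  Features are standardized
  internally; coefficients are reported on the original scale.  K-fold CV
  uses seeded fold assignment, stratified for binomial; `lambda_1se` is
  the largest λ with CV error within one standard error of the minimum.
  The default mixing is α = 1 (pure lasso): the workflows this package
  packages describe themselves as elastic net while relying on their
  toolchain's default mixing parameter, which is 1; α is a first-class
  knob and every recipe manifest records it.  Inner solvers are
  scikit-learn's coordinate descent (`enet_path`, whose objective matches
  the one above exactly) and saga logistic regression with
  `C = 1/(n·λ)`.
* **Coefficient z-scaling** centers and scales the selected coefficients
  with the sample standard deviation (ddof = 1, the `scale()` convention
  in R); the returned table includes |z| restricted to negative
  coefficients, the ranking used to display taxa that increase as a
  gradient decreases.  Scaling is per regression; pooling across multiple
  regressions is the caller's choice.

## Synthetic data

The generator emulates a marine depth-transect corpus:

* **Ontologies.**  A GO-like DAG embeds a fixed fragment (the metabolic
  process / photosynthesis / methanogenesis chain, the binding → ion
  binding → cation binding family with 17 leaf genes, biosynthesis and
  catabolism branches, an oxidoreductase branch) plus seeded random terms
  with ≤ 3 parents, attached only under internal nodes so the fixed
  leaves remain count categories.  The taxonomy is a ranked tree embedding
  *Prochlorococcus* (with its named low-light-adapted strains),
  *Synechococcus*, and the OMZ-affiliated phyla, plus random genera /
  species / strains.  A small fixed ENVO-like vocabulary covers water-body
  classes and measurable parameters.
* **Counts** follow a logistic-normal / multinomial model: term weight
  `w_fj = exp(a_f + b_f·z_j + ε_fj)` with seeded log-normal baselines
  `a_f`, planted slopes `b_f` against standardized depth, an
  anoxic-group contrast, or a river/marine contrast, and per-(sample,
  term) Gaussian overdispersion (σ = 0.8 by default — log-scale spread of
  the size seen across ocean samples, and enough to make co-planted
  predictors jointly informative rather than redundant).  Counts are
  multinomial with the sample's ORF / read total.  Logistic-normal
  overdispersion was chosen over a Dirichlet because it gives uniform
  relative noise across rare and abundant terms, which is both the
  standard compositional noise model and what planted-signal calibration
  requires.
* **Abundance regimes.**  Planted gradient genes sit at modest baselines
  while the unplanted members of the queried family are abundant and
  stable; consequently the top-variance band that the 30% exclusion
  removes consists of housekeeping-like genes, which is the regime the
  exclusion step assumes for genomic data.  Perfect anoxia indicators get
  zero weight in oxic samples and a fixed solid weight in anoxic ones, so
  their expected count is far above the detection floor.
* **Measurements.**  Depth is a uniform 5–1000 m grid (64 samples by
  default); dissolved oxygen follows an OMZ-like sigmoid (oxycline near
  300 m, suboxic below ~450 m), phosphate a nutrient-type increase, DIC a
  river/marine contrast (180 vs 2050 µmol/kg); all with 5% relative
  log-normal noise.  Sequencing totals default to ~10⁷ QC reads and ~10⁶
  ORFs per sample, the corpus scale; the `scale` knob (10⁻³ throughout
  the test suite and acceptance script) shrinks totals without touching
  any other condition, and the ledger records it.
* **QC planting** lowers a sample's raw reads below the design threshold
  or concentrates its taxa onto a few categories so richness collapses.
  Because the synthetic taxonomy has ~10² categories rather than the ~10⁴+
  of a full reference database, the design's richness threshold defaults
  to half the category count; the library-level QC defaults remain the
  published 5,000,000 / 10,000 values.
* The **ledger** records every planted effect, expected abundances of
  planted terms, per-sample totals, group labels and planted QC failures —
  the oracles for all downstream tests.

What passing tests on this corpus show: the engine's closures, filters,
transforms and statistics are correct, and the packaged workflows recover
structure that is genuinely present at realistic compositional noise.
What they do not show: robustness to annotation bias, chimeric
assignments, batch effects, or phylogenetically correlated abundances,
none of which the generator models.

## Verification quantities

`scripts/acceptance.py` recomputes, from freshly generated inputs: closure
agreement with brute-force BFS over 100 random DAGs (≤ 200 terms each);
QC fidelity on a fixture with planted violations at the published
thresholds; relativization/CLR/clade-aggregation identities; prevalence
rule agreement on boundary cases; PERMANOVA's 1-D ANOVA equivalence, its
p-floor of 0.001 on separated clusters at 999 permutations, and null
calibration (Kolmogorov–Smirnov uniformity of p over 200 shuffled-label
replicates at 199 permutations each); IndVal closed forms (1 and √0.5);
elastic-net recovery of a 5-of-100 equal-strength planted signal at
n = 200, SNR 5 over 10 seeds; the gene-vs-gradient recipe's planted-term
recovery and closure-subset property over 10 synthetic cohorts; the
anoxic-indicator recipe's perfect indicator (stat 1, p 0.001); and the
byte-stable RDF round trip.  The problem sizes reflect the scaled-down
synthetic conditions above and are printed as `n` alongside each value.
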