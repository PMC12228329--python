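# Methods

## The annotation model

`hippotype` scores single cells (or nuclei) against a **marker gene set**
`S = {S_c}`: an assignment of a gene list `S_c` to each cell type `c` in a
tissue. Given an expression matrix `X` (genes x cells), the pipeline is:

1. **QC filter** (optional, raw counts only): keep cells with at least
   `min_genes` detected genes and at most `max_umis` total counts. The
   defaults (200 genes, 20,000 UMIs) are the standard thresholds for
   nuclear RNA-seq.
2. **Normalization**: library-size scaling of each cell to a fixed total
   (default 1e4) followed by `log(1 + x)`. Matrices that are already
   normalized (e.g. TPM) are accepted as-is via `layer_tag="normalized"`.
3. **Standardization**: each gene in the marker universe
   `M_t = union of all S_c` is z-scored *across all cells* with sample
   standard deviation (ddof = 1). Zero-variance genes map to all-zero
   rows rather than NaN.
4. **Specificity weighting**: with `n_i` the number of cell types whose
   marker list contains gene `i`,

       theta_i = (1/n_i - min_j 1/n_j) / (max_j 1/n_j - min_j 1/n_j),

   rescaled to [0, 1] so genes private to one type weigh fully and
   ubiquitous markers weigh nothing. When all `n_i` are equal the formula
   is 0/0; we define theta = 1 for all genes (all markers maximally
   informative), which preserves scoring instead of zeroing it.
5. **Enrichment score**: for each type `c` and cell `j`,

       E[c, j] = (1 / sqrt(|S_c|)) * sum_{i in S_c} theta_i * z[i, j],

   computed as a single product of a per-type indicator/weight matrix
   with the weighted z-score matrix. A brute-force triple loop is kept in
   the test suite as the oracle; the two agree to 1e-9.
6. **Assignment**: each cell takes the argmax type; cells whose best
   score is <= `unknown_threshold` (default 0, i.e. below-average marker
   expression for every type) are labelled `"unknown"`. Exact ties break
   to the lexicographically first type name, deterministically. An
   optional cluster mode sums scores over a cluster's cells and labels
   the cluster "unknown" when the best sum is below n_cluster/4 — the
   convention of the marker-scoring lineage this engine extends; the
   per-cell mode matches the scoring formula itself and is the default.

Markers requested but absent from the data are dropped from `S_c` with a
warning and the `1/sqrt(k)` scaling uses the reduced size; a type with no
available markers scores NaN and can never win the argmax. If under half
of the marker universe is present the annotation warns; at zero presence
it errors.

## The cross-validated objective

Candidate marker sets are scored by **leave-one-cell-type-out (LOCTO) x
K-fold cross-validation** on a labelled reference. For each type `c`, the
markers of `c` are removed from `S`; a well-constructed marker set then
pushes cells of type `c` below the unknown threshold. For fold `k`, the
accuracy `f_{c,k}` is the fraction of correctly assigned held-out cells
over all types, where "correct" means the true label for cells of types
other than `c` and `"unknown"` for cells of the masked type (a flag flips
masked-type cells to always-incorrect for sensitivity analysis). The
objective is the grand mean over all `C x K` combinations.

Design notes:

* Folds are stratified by true type and deterministic given a seed
  (scikit-learn `StratifiedKFold` with shuffling).
* Per-gene means and standard deviations are computed on the *full*
  matrix — the classifier standardizes across all cells — so fold
  evaluation deliberately shares those moments. This mirrors how the
  classifier is deployed and is documented leakage.
* theta is recomputed after masking, since occurrence counts change with
  the current set.
* Because the scores depend on the masked set but not on the fold, the
  evaluator annotates once per masked type and slices folds afterwards;
  this is algebraically identical to the per-(c, k) loop and makes a
  full evaluation of a five-type, 1,500-cell benchmark cost ~3 ms.
* K-fold is implemented as a partition of cells (standard K-fold), not
  repeated random splits.

## Optimizing the marker sets

The search space is an assignment of `k_min..k_max` genes per type from
a candidate pool. It is astronomically large (for a 5,000-gene pool,
1-30 markers and 33 types, over 10^2500 configurations — far beyond the
10^83 lower bound usually quoted for this setting), so the optimizer
treats the objective as expensive and black-box:

* **Surrogate**: a Gaussian process over marker sets with the kernel
  `k(S, S') = exp(-gamma * (1 - Jbar))`, `Jbar` the mean per-type Jaccard
  similarity. This is symmetric, 1 at identity, and PSD-stable with a
  small jitter; `gamma` defaults to 1.0 and observation noise to 1e-4.
  The GP prior mean is constant (the mean of observed objectives unless
  fixed explicitly).
* **Acquisition**: Expected Improvement in its closed form
  `sigma * (z Phi(z) + phi(z))`, `z = (mu - f_best)/sigma`, with the
  `sigma = 0` limit `max(0, mu - f_best)`. A stratified Monte-Carlo
  integrator of the defining integral is kept as an independent
  numerical cross-check (agreement well under 1e-3 at 1e6 samples).
  Maximizing EI over the whole space is intractable; it is maximized
  over the EM-proposed candidate batch (default 32 per iteration).
* **EM proposals**: the E-step annotates the data with the incumbent
  set; the M-step ranks pool genes per type by a specificity statistic —
  the mean z-score among that type's assigned cells minus the best mean
  z-score in any other type. Candidates are seeded mutations of the
  incumbent: swapping the lowest-ranked current markers for top-ranked
  outsiders (geometrically weighted toward rank 1), pruning a block of
  the weakest markers, or adding top outsiders, all within the size
  bounds. Mutation strength is geometric (1 gene w.p. 1/2, 2 w.p. 1/4,
  capped at 4): multi-gene prunes are essential because removing several
  uninformative markers at once both improves the `1/sqrt(k)`-scaled
  score and moves the candidate far enough in Jaccard space to be
  distinguishable to the surrogate. A type with no assigned cells in the
  E-step keeps its markers unchanged (with a warning).
* **Initialization**: per type, the top `k_max // 2` pool genes by the
  same specificity statistic computed on the true labels.
* **Budget**: the number of objective evaluations after the initial one;
  `budget = 0` returns the initial set with its objective. The desk-scale
  default is a few hundred evaluations with mechanics identical to an
  arbitrarily long run.

All randomness in a run flows from one integer seed; equal seeds yield
bit-identical traces. The package also ships an equal-budget baseline
(`random_search_markers`): same initialization and hill-climbing
acceptance, but uniformly random single-gene mutations. On the default
synthetic benchmark the EM/GP optimizer's median final objective over
five seeds exceeds this baseline, which is the relevant comparison for
the proposal machinery.

`count_configurations` computes the exact size of the search space in
big-integer arithmetic and returns its log10 (via `Decimal`), so the
"over 10^83" style claims can be checked rather than estimated.

## Synthetic data

The simulator plants a known cell-type structure so that every layer of
the stack is testable without external downloads:

* per-gene base means lognormal around `base_mean` (sigma
  `gene_mean_sigma` = 1.0);
* each type owns `markers_per_type` planted markers (disjoint across
  types by default; an `overlap_fraction` mode shares markers between
  neighbouring types to exercise theta < 1);
* marker means are multiplied by `2**marker_log2fc` in their own type's
  cells;
* per-cell size factors lognormal(0, `libsize_sigma`);
* counts negative binomial with mean `mu` and variance
  `mu + mu^2 / nb_dispersion` (`nb_dispersion` is the NB size parameter;
  drawn as a gamma-Poisson mixture).

Default parameters (5 types x 300 cells, 2,000 genes, 8 markers/type at
log2FC 2, `nb_dispersion` 50, `base_mean` 10, `libsize_sigma` 0.35) were
fixed once at design time to emulate deeply sequenced split-pool nuclear
RNA-seq: UMI counts are near-Poisson (var/mean ~ 1.2 at the mean depth),
and the 2,000 simulated genes stand for the informative, highly variable
fraction of the transcriptome — hence ~10 counts/gene and 15-20k counts
per cell. In this regime planted markers behave like canonical cell-type
markers: annotation with the planted set is essentially perfect, and
masking a type sends >90% of its cells below the unknown threshold.

What the simulator does **not** model: batch effects, doublets, ambient
RNA, gene-gene correlation beyond the type structure, or continuous
differentiation gradients. Passing tests therefore demonstrate the
correctness and internal consistency of the scoring/optimization
machinery under a clean generative model, not performance on real
tissue; on real data the attainable objective and the sharpness of the
unknown rule will be lower.

## Composition permutation test

For two conditions, the per-type statistic is the difference of pooled
proportions, `prop(B) - prop(A)`. Condition labels are permuted over
cells (default) or whole samples; the one-sided ("less") p-value is the
add-one Monte-Carlo estimate `(1 + #{perm <= obs}) / (n_perm + 1)`, or
the exact fraction when all label arrangements (<= 1e6) are enumerated.
Benjamini-Hochberg adjusted p-values across types are reported alongside.
The estimator is slightly conservative under the null (ties in the
discrete proportion statistic are counted against rejection), which the
calibration check reflects: empirical type-I error at alpha = 0.05 sits
near 0.04. Sample-level permutation is provided for completeness but is
underpowered with a handful of samples per condition: with 2 + 2 samples
the p-value cannot go below 1/6.

## Numerical choices

* z-scores use sample sd (ddof = 1); zero-variance genes give z = 0.
* GP Gram matrices get a 1e-10 jitter, escalated once to 1e-6 before a
  singularity error is raised.
* EI returns exactly 0 at `sigma = 0, mu <= f_best`.
* Argmax ties in assignment and EI-candidate selection are broken
  deterministically (lexicographic type name; seeded uniform choice
  among exact EI ties).
* Matrix Market files are 1-based on disk and 0-based in memory; gzip is
  transparent; malformed triplet lines are reported with their line
  number.

## Known limitations

* Negative or low-expression ("absent") markers are not supported; the
  scoring formula is purely additive.
* The set kernel sees how *many* genes two sets share, not *which*
  genes; candidates at equal edit distance are indistinguishable to the
  surrogate, so proposal quality (the EM ranking) carries most of the
  search signal.
* The EM "likelihood" is operationalized by the specificity statistic;
  no explicit probabilistic model of assignments is fitted.
* Cross-validation shares standardization moments across folds by
  design (see above); reported objectives are therefore internal
  consistency scores, not estimates of transfer to unseen datasets.
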