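# hippotype

Marker-based cell-type annotation for single-cell and single-nucleus
RNA-seq, with cross-validated Bayesian optimization of the marker gene
sets themselves.

Annotating cells in complex tissues such as the hippocampus is hard:
closely related neuronal subtypes share most of their transcriptome, and
the quality of a marker-based classifier is decided almost entirely by
*which* genes each cell type's marker list contains. `hippotype` treats
that choice as an optimization problem. It provides:

* a **vectorized marker-enrichment classifier**: for cell `j` and type
  `c` with marker list `S_c`,

  `E[c,j] = (1/√|S_c|) · Σ_{i∈S_c} θ_i · z_{ij}`,

  where `z` is the per-gene z-score of log-normalized expression across
  all cells and `θ_i ∈ [0,1]` down-weights genes shared by many cell
  types. Cells take the argmax type, or `"unknown"` when every score is
  ≤ 0;
* a **leave-one-cell-type-out (LOCTO) × K-fold objective** `f(S)`: mask
  one type's markers at a time — its cells should become `"unknown"` —
  and average held-out accuracy over all `C × K` (type, fold) pairs;
* a **Bayesian optimizer** for `S* = argmax_S f(S)`: a Gaussian-process
  surrogate over a mean-Jaccard set kernel, Expected Improvement
  acquisition, and EM-style candidate proposals that swap, prune, or add
  markers ranked by a per-type specificity statistic;
* a **negative-binomial simulator** with planted cell types and markers,
  so the whole stack is testable end to end;
* a **composition permutation test** for between-condition shifts in
  cell-type proportions, plus Matrix Market / delimited-text IO and a
  command-line interface.

The search space is combinatorially huge — for a pool of 5,000 highly
variable genes, 1–30 markers per type and 33 cell types there are more
than 10^83 possible marker-set configurations (the exact count, via
`count_configurations(5000, 1, 30, 33)`, has log10 ≈ 2590.8) — hence the
surrogate-model approach.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

```python
from hippotype import (SimSpec, simulate_dataset, annotate, cv_objective,
                       optimize_markers, planted_recovery)

# a synthetic benchmark: 5 cell types x 300 cells, 2,000 genes,
# 8 planted markers per type at 4-fold elevation
sim = simulate_dataset(SimSpec(seed=1))

# 1. annotate with the planted (true) marker set
res = annotate(sim.X_raw, sim.planted)
print((res.labels == sim.true_labels).mean())   # 1.0
print(res.label_frame().head(3))
#     cell_id   label  top_score
#    cell0000  type01   5.170916
#    cell0001  type01   5.006089
#    cell0002  type01   4.701786

# 2. its cross-validated LOCTO objective
rep = cv_objective(sim.X_raw, sim.true_labels, sim.planted, K=5, seed=0)
print(rep.objective)                            # 0.9911

# 3. optimize a marker set from scratch (short demo run)
result = optimize_markers(sim.X_raw, sim.true_labels,
                          pool=list(sim.X_raw.gene_ids), budget=50, seed=0)
print(result.trace[0]["objective"], result.best_objective)
# 0.9228 0.9644   (data-driven init, then improved within 50 evaluations)
rec = planted_recovery(result.best_set, sim.planted)
print(rec.macro_recall, rec.macro_precision)    # 0.925 0.813
```

The top scores (~5 on the z-sum scale) say that each cell's own type's
markers sit several standard deviations above the dataset average; the
objective 0.9911 is the mean held-out accuracy over all 25 (type, fold)
combinations with one type masked at a time. At the default budget of
300 evaluations the optimizer typically reaches f(S*) ≈ 0.992 and prunes
its 15-gene initial lists down to the planted markers.

The same operations are available from the shell:

```bash
hippotype simulate --out-dir sim/ --seed 1
hippotype annotate --matrix sim/matrix.mtx --markers sim/planted_markers.json --out labels.tsv
hippotype optimize --matrix sim/matrix.mtx --labels sim/labels.tsv --budget 300 --seed 1 --out best.json
hippotype composition-test --table counts.csv --cond-a sham --cond-b HI --out shifts.tsv
hippotype count-space --pool 5000 --kmin 1 --kmax 30 --n-types 33
```

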