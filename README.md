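# phytomapper

Topological Mapper analysis of cross-species plant gene expression.

Public plant RNA-seq catalogs span dozens of species, tissues and stress
treatments, but the signal that organises them — which tissues resemble each
other, how far a stressed sample has drifted from healthy expression — is
buried under batch effects, family-level divergence and wildly unbalanced
sampling. `phytomapper` summarises such a catalog as a **Mapper graph**: a
compact topological skeleton of the sample cloud whose branches and
gradients trace tissue identity and stress response across species. It is
aimed at comparative transcriptomics researchers who want a hypothesis-
generating view of a heterogeneous expression compendium, at orthogroup
(rather than per-gene) resolution.

## The method

1. **Orthogroup matrix assembly.** Per-species gene-level TPM tables are
   mapped through an OrthoFinder-style `Orthogroups.tsv` membership table.
   Orthogroups must be present in at least *k* of the *S* species and carry
   a mean of at most *c* genes per diploid species that contains them
   (polyploids are exempt); within each species, TPMs of an orthogroup's
   genes are summed, and the per-species matrices are column-concatenated
   into one orthogroup × sample matrix.

2. **Residual lens functions.** For a chosen reference condition — leaf
   samples (tissue lens) or healthy samples (stress lens) — an affine
   subspace is fit to the log2(TPM+1) reference profiles: mean μ plus the
   leading left singular vectors *B* of the centered reference matrix
   (rank chosen by cumulative explained variance, default 95%). Every
   sample *x* is scored by its residual norm off that subspace,

   f(x) = ‖(x − μ) − BBᵀ(x − μ)‖₂,

   so f ≈ 0 means "looks like idealized reference expression" and large f
   means strong deviation (non-photosynthetic tissue, severe stress).

3. **Mapper graph.** The lens range is covered by *n* uniform-length
   intervals with overlap fraction *g*; each interval's preimage is
   clustered with DBSCAN (correlation or Euclidean distance); the graph is
   the 1-dimensional nerve of the resulting cover: one node per cluster,
   an edge wherever two clusters share samples, weighted by the shared
   count. A parameter sweep over (n, g) summarises graph stability, and
   greedy Jaccard agglomeration coarsens the graph to a target node count
   (default 18) for interpretation.

4. **Lens-correlated orthogroups and enrichment.** Each orthogroup's
   log2 expression is correlated with the lens; the top and bottom 2.5%
   tails are tested for membership in a reference inventory (GreenCut2-
   style photosynthesis gene set) with an exact one-sided binomial test,
   and against flat term → gene sets (GMT) with hypergeometric tests and
   Benjamini–Hochberg correction. An adjusted-R² helper
   (1 − (1 − R²)(n − 1)/(n − p − 1)) summarises factor associations of
   surrogate variables.

5. **Balance audit.** Observed (family, tissue, stress) combination counts
   are tallied against the number possible, and the most common
   combinations can be capped by seeded subsampling to test robustness of
   the graph topology to sampling bias.

A synthetic-data generator (`phytomapper.simulate`) emulates the statistical
structure of a real catalog — planted photosynthesis-analog and
stress-responsive orthogroup modules, per-sample stress severity, family and
bioproject batch offsets, Zipf-skewed factor combinations — with full ground
truth, so the entire pipeline is testable at desk scale.

## Worked example

```python
from phytomapper import (SimulationConfig, simulate_metadata, simulate_expression,
    select_reference, fit_reference_model, residual_lens, mapper_pipeline,
    simplify_graph, lens_correlation, select_extremes, binomial_enrichment, GeneSet)
from scipy.stats import spearmanr

cfg = SimulationConfig(seed=1)                      # 1,000 orthogroups x 300 samples
meta = simulate_metadata(cfg)
X, truth = simulate_expression(cfg, meta)

ref = select_reference(meta, "stress")              # healthy reference samples
model = fit_reference_model(X, ref)                 # affine subspace, 95% EV rank rule
f = residual_lens(X, model)                         # stress lens values

graph = mapper_pipeline(X, f, n_intervals=8, overlap=0.3, eps=0.2, min_samples=3)
summary = simplify_graph(graph, target_nodes=18)
print(f"mapper graph: {len(graph.nodes)} nodes, {len(graph.edges)} edges; "
      f"simplified: {len(summary.nodes)} nodes, {summary.n_components} components")

rho = spearmanr(f.loc[truth.severity.index], truth.severity)[0]
print(f"stress lens vs planted severity: Spearman rho = {rho:.3f}")

tails = select_extremes(lens_correlation(X, f), tail_frac=0.025)
hits = set(tails[0]) & truth.stress_gene_ids
res = binomial_enrichment(tails[0], GeneSet("planted", truth.stress_gene_ids), list(X.index))
print(f"positive tail: {len(tails[0])} orthogroups, {len(hits)} planted "
      f"(p0 = {res.p0:.3f}, binomial p = {res.p_value:.2e})")
```

prints

```
mapper graph: 6 nodes, 4 edges; simplified: 6 nodes, 2 components
stress lens vs planted severity: Spearman rho = 0.838
positive tail: 25 orthogroups, 25 planted (p0 = 0.050, binomial p = 2.98e-33)
```

The stress lens — built *only* from healthy samples — tracks the planted
per-sample stress severity (ρ = 0.84), and the 2.5% most positively
lens-correlated orthogroups are exactly the planted stress-responsive
module, which the binomial test calls overwhelmingly enriched against its
5% background rate.

The same workflow is available from the shell:

```bash
phytomapper simulate --n-samples 300 --seed 1 --outdir demo
phytomapper lens --matrix demo/expression.csv --metadata demo/metadata.csv \
    --lens stress --out demo/lens_stress.tsv
phytomapper mapper --matrix demo/expression.csv --lens-file demo/lens_stress.tsv \
    --target-nodes 18 --outdir demo
phytomapper run-all --config config.yaml --outdir run1   # everything at once
```

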