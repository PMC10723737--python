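# Methods

## Pipeline model and assumptions

`phytomapper` treats a cross-species expression catalog as a point cloud of
samples in orthogroup-expression space and summarises it as the
1-dimensional nerve of a cover (a Mapper graph). The construction assumes:

- expression is comparable across species only at the orthogroup level, and
  only for deeply conserved low-copy orthogroups — hence the presence
  (≥ `min_species`) and mean-copy (≤ `max_mean_copies` genes per diploid
  species containing the orthogroup) filters before any analysis;
- TPM values are non-negative and within-sample normalised; all geometry
  (lens fits, distances, correlations) is computed on log2(TPM+1) unless
  configured otherwise, since fold-change structure, not absolute
  abundance, carries the biology;
- a meaningful "reference state" exists (leaf tissue for the tissue lens,
  healthy condition for the stress lens) and deviation from it is
  informative. The lens is the residual norm off an affine subspace fit to
  reference samples; it deliberately collapses the *direction* of deviation
  and keeps only its magnitude.

### Lens fit

The reference model is μ (mean of transformed reference columns) plus the
leading left singular vectors of the mean-centered reference matrix. The
rank rule `ev:τ` keeps the smallest rank whose cumulative squared singular
values reach τ (default 0.95); `fixed:k` is available. Rank is always capped
at `n_ref − 1` and singular values below 1e-10 of the largest are treated as
zero, so identical reference columns yield a pure-mean (rank-0) model and
the basis satisfies BᵀB = I to ~1e-12. The residual is computed as
(x − μ) − BBᵀ(x − μ); no flattening of the in-span component is performed —
the lens is one non-negative scalar per sample.

### Cover and clustering

The cover consists of `n` intervals of common length
L = (fmax − fmin)/(n − (n−1)g) with overlap fraction `g` ∈ [0, 1); interval
j starts at fmin + j(1−g)L and the last endpoint is pinned to fmax exactly.
Interval membership is closed at both ends so the extreme lens values are
always covered. Preimages are clustered with DBSCAN
(scikit-learn, `metric="precomputed"`); a point counts itself toward
`min_samples`, which the test oracles assume as well. Distances between
samples are either Euclidean or correlation distance (1 − Pearson r between
expression columns; constant columns get distance 1 to every other point).
Noise points are excluded from nodes but reported in a sidecar table, never
silently dropped.

### Simplification

The published-style "simplified" graph is produced by greedy agglomeration:
repeatedly merge the edge-connected pair of nodes with the highest Jaccard
similarity of member sets (ties broken by the smaller sorted id pair) until
at most `target_nodes` (default 18) remain or no edges are left. Meta-node
members are unions, meta-edges are recomputed from member intersections, so
the covered sample set is invariant and the number of connected components
never increases. This scheme is this package's own design choice: any
clustering of nodes could stand here, and Jaccard-on-members was chosen
because it merges the redundant overlapping bins first and is fully
deterministic.

## Tunable parameters

| parameter | units / scale | default | rationale |
|---|---|---|---|
| `min_species` | count of species | 52 (CLI) | keep orthogroups conserved in nearly all species |
| `max_mean_copies` | genes per diploid species | 2.0 | exclude multigene families |
| lens `transform` | — | `log2(TPM+1)` | variance-stabilising, standard for TPM |
| `rank_rule` | explained variance | `ev:0.95` | keep reference variation, discard noise floor |
| `n_intervals` | count | 8 | sweep-stable on the default synthetic catalog |
| `overlap` g | fraction of L | 0.3 | sweep-stable; g < 0.5 keeps non-adjacent intervals disjoint |
| `eps` | correlation distance | 0.2 | graph shape is unchanged over eps 0.2–0.4 in the sweep |
| `min_samples` | count | 3 | small enough to keep sparse bins, kills singleton noise |
| `target_nodes` | count | 18 | interpretable summary size used for both lenses |
| `tail_frac` | fraction per tail | 0.025 | extreme 2.5% tails per direction |
| balance `top_k`, `cap` | count | 30, 30 | cap the 30 most common combos at 30 samples |

The Mapper defaults were fixed once by running `parameter_sweep` on the
default synthetic catalog and choosing the plateau where node/edge/component
counts stop responding to (n, g, eps) — the same stability criterion a
practitioner applies by inspecting sweep panels. They are configuration, not
universal constants: real catalogs need their own sweep.

## The synthetic generator

`simulate_metadata`/`simulate_expression` emulate, at desk scale, the
structure the analysis assumes in real catalogs: 16 families × 8 tissues ×
10 stresses (1,280 possible 3-way combinations) sampled with Zipf-like
weights (skew 1.0) over a canonical combo ordering that places healthy and
leaf combinations first — reproducing both the heavy skew of observed
combination counts and the dominance of healthy/leaf samples that makes the
reference sets large. Expression is generated on the log2 scale as baseline
(Uniform[2, 8]) plus a planted tissue module (5% of orthogroups, −2.0 log2FC
outside leaf: a photosynthesis analog), a planted stress module (5% of
orthogroups, +2.0 log2FC per unit severity, severity ~ Uniform[0.25, 1.75]
for stressed samples and exactly 0 for healthy), family offsets (sd 0.25),
per-bioproject batch offsets (sd 0.25) and i.i.d. noise (sd 0.5), then
mapped to TPM-like values via 2^x − 1 clipped at 0. Defaults are 1,000
orthogroups × 300 samples.

Gene-level draws (baselines, module membership, factor offsets) and
sample-level draws (severity, noise) use separate RNG streams derived from
`seed`, so enlarging the sample set does not perturb gene-level structure.

What it does **not** emulate: read-count sampling noise and library-size
effects, mean–variance coupling, correlated gene modules beyond the two
planted ones, missing orthogroups per species, or lineage-specific
expression divergence. Passing the parameter-recovery tests therefore shows
the pipeline's statistical machinery is correct and well-calibrated on
factor-structured log-normal data; it does not certify performance on real
SRA-derived matrices, whose nuisance structure is richer.

## Numerical choices and degenerate inputs

- Cover interval endpoints follow the closed form to ~1e-12; the final
  endpoint is assigned exactly to avoid excluding the max-lens sample.
- Zero-variance expression rows get correlation r = 0 with a `degenerate`
  flag and are barred from tail selection, keeping the ranking total without
  inventing signal.
- Tail size is ⌊tail_frac · N⌋ over all table rows; ties are broken by
  orthogroup id, making the selection fully deterministic.
- Binomial and hypergeometric p-values come from scipy's exact
  distributions (verified against direct pmf summation / combinatorics to
  1e-12 in the tests); Benjamini–Hochberg uses statsmodels.
- Empty preimages are legal (no node); an empty reference sample set is an
  error, as is fitting a lens on fewer than two reference samples.
- Merging per-species matrices zero-fills orthogroups missing from a
  species and flags them, rather than propagating NaN into the lens.
- All randomness (simulation, downsampling) flows through
  `numpy.random.default_rng` seeded from explicit integer seeds; Mapper
  construction itself has no randomness.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 1,000 × 300 synthetic catalog, 100 randomised brute-force Mapper
cross-checks at up to 200 samples each, and exact-test oracles at n up to
1,000 — a few seconds in total on one CPU. These sizes were chosen as the
smallest at which every planted-signal recovery statistic is stable across
seeds.

## Known limitations

- The lens collapses deviation direction; two samples deviating oppositely
  from the reference can receive identical lens values and co-cluster only
  if their expression profiles are also close under the chosen metric.
- Graph topology depends on (n, g, eps, min_samples); the sweep summarises
  but does not optimise them, and no formal stability statistic is
  computed.
- Enrichment operates on flat gene sets; term hierarchies (GO DAG
  propagation) are out of scope.
- Surrogate-variable estimation itself is out of scope; only the
  adjusted-R² association summary is provided.
- The copy-number filter trusts the supplied diploid/polyploid labels and
  applies a single threshold across all diploids.
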