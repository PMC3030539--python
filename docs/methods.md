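# Methods

This note documents the statistical model behind each stage, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Synthetic profiles

`generate_profiles` draws a metabolites × samples matrix on log2 scale:

    x_is = mu_i + shift(group(s), i) + l_i * f_{m(i), s} + eps_is

* `mu_i ~ Normal(10, 2)` — baseline log2 abundances spanning the dynamic
  range typical of relative GC-MS peak areas.
* Each of the planted modules has one latent factor `f_m,s ~ Normal(0,1)`
  per sample; module members load on it with
  `l_i = factor_loading · Uniform(1 − jitter, 1 + jitter)`. Loadings are
  all positive (empirically, metabolomic correlation networks are
  dominated by positive correlations) and heterogeneous (jitter 0.4):
  real pathway members couple to shared regulation with varying strength.
  With strictly equal loadings every within-module pair would share one
  population correlation, creating an artificial knife-edge at which the
  whole module disintegrates in the threshold sweep — a feature real data
  does not have.
* `eps_is ~ Normal(0, noise_sd)`; with probability `outlier_fraction` an
  entry's residual is multiplied by `outlier_scale`, giving the
  heavy-tailed contamination that motivates rank correlation. The
  contamination is on the residual, not the mean, so Spearman's
  robustness is testable against Pearson.
* Genotype effects are additive log2 mean shifts for designated
  metabolites (defaults: one metabolite shifted +2 in the `mto1`-like
  group, emulating a strong single-metabolite over-accumulation).

Defaults are the study design the rest of the package is exercised at:
59 metabolites, three groups of 17/16/20 samples, four modules of sizes
12/10/8/6, loading 1.0, noise 0.5 (signal-to-noise 2). Randomness uses
numpy's PCG64 (`default_rng`); the seed is part of the configuration and
output is bit-reproducible.

What the generator does **not** emulate: missing peaks patterned by
abundance, batch effects, retention-time artefacts, compositional
constraints, or correlated noise between modules. Passing tests
demonstrate correctness and calibration of the machinery under the
stated model, not performance guarantees on any particular instrument's
data.

## Rank product

Two-group variant over all `K = n_a · n_b` cross-group sample pairs:
per-pair log-ratios (differences on log2 data) are ranked over
metabolites — rank 1 is the most up-regulated for the "up" analysis and
the most down-regulated for "down", with average ranks on ties — and
`RP_g` is the geometric mean of the K ranks (computed in log space).

The null distribution permutes the **sample group labels** and recomputes
RP, rather than drawing K independent uniform rankings. The K cross
pairs of one metabolite share samples and are therefore strongly
dependent; an independent-ranks null badly understates the spread of RP
(measured null call rate ~0.17 at a nominal 0.05). Label permutation
preserves that dependence and restores calibration; by symmetry one null
serves both directions. The estimate
`pfp(g) = E[# null RP ≤ RP_g] / rank(g)` may exceed 1 and is reported
uncapped next to a capped convenience column. Default 1000 permutations;
calls use pfp < 0.05.

## PCA

Column-centered SVD of the samples × metabolites matrix, by default with
unit-variance scaling — appropriate for metabolomic data whose variances
span orders of magnitude; `scaling="none"` is available when variances
are meaningful. Missing values are handled by row drop or mean
imputation (logged), never silently.

## Spearman correlation and local fdr

Spearman `r` is the Pearson correlation of average ranks over
pairwise-complete samples, with each pair's `n` recorded and used in
every test denominator (also in the Fisher-Z variance). Pairs with
`n < 4` or zero rank variance are excluded with a warning. The t-test
uses `t = r√((n−2)/(1−r²))` with `n−2` df; `|r| = 1` maps to p = 0 by
convention.

The local fdr is the posterior null probability under the two-component
mixture `f(p) = η₀ + (1−η₀)h(p)`: `η₀ = min(1, #{p > 0.5}/(0.5·N))`
(Storey at λ = 0.5) and `f̂` is the Grenander estimator — the slopes of
the least concave majorant of the p-value ECDF, obtained by antitonic
regression of the ECDF segment slopes weighted by segment widths;
`fdr(p) = min(1, η₀/f̂(p))`. p-values are clipped to `[1e-15, 1]` so the
estimator is defined at p = 0. The construction is pinned here; numeric
agreement with any particular fdr package is not a contract — the
calibration properties in the test suite are. Local fdr is computed per
analysis set (one network, or one differential comparison), not jointly
across sets. Calls use fdr < 0.05.

## Threshold sweep and selection

Networks keep all metabolites as nodes; an edge requires `r ≥ t` and
`r > 0` (negative correlations are rare in this setting and excluded by
default; `only_positive=False` switches to `|r| ≥ t`). Six metrics per
grid threshold (0 to 1, step 0.01): density `2E/(N(N−1))`, global
transitivity (3·triangles / connected triples; the average-local variant
is available separately), average degree, average shortest-path length
over connected ordered pairs only (well-defined for the disconnected
graphs high thresholds produce; NaN when edgeless), component count and
edge count. Metrics are computed from the adjacency matrix with
breadth-first expansion by boolean matrix products — for panels of tens
to a few hundred metabolites this is faster than per-graph sparse
machinery, and it is tested against a brute-force BFS oracle.

The null band repeats the sweep on randomized datasets in which every
metabolite's values are independently permuted across samples: marginals
are preserved exactly, all inter-metabolite dependence is destroyed.
(Value permutation, not edge rewiring, is the pinned interpretation of
data randomization here; it is the null the correlation test itself
assumes.)

**Selection rule.** The component count transitions from small (one
giant chance-edge component) to large (modules plus singletons) as the
threshold crosses the range of spurious correlations. With a null band
available the selected threshold is the smallest grid point at which the
mean null component count reaches 99% of the node count — i.e. where
chance correlations can no longer form edges, so everything surviving is
real structure. This lands at the end of the fragmentation rise (≈0.46
under the default synthetic conditions, matching the r ≥ 0.5 regime such
studies converge on). Without a null band the fallback is the grid point
maximizing the one-step forward difference of the real component curve
(ties toward the smaller threshold); a flat curve falls back to 0.5 with
a warning, and an explicit override always wins. The steepest-jump
fallback alone is not robust: on data with tight modules it can lock
onto the high-threshold jump at which a module itself disintegrates.

## DPClus

Reconstruction of the density/periphery graph-clustering scheme from its
defining quantities; bit-compatibility with the original GUI program is
not promised — the contract is the invariant suite (density and cp
conditions hold at every admission, determinism, disjointness in
non-overlapping mode).

* Edge weight = number of common neighbours; node weight = sum of
  incident edge weights.
* Seed = heaviest node (ties: higher degree, then lexicographic id).
* Growth: periphery candidates ordered by (edges into cluster desc,
  node weight desc, id asc); the first candidate keeping density ≥ `d_in`
  whose `cp = E_nk/(d_k·|N_k|) ≥ cp_in` is admitted; the periphery and
  ordering are recomputed after every admission (first-qualifying rather
  than single-top-candidate: a broader, still deterministic search).
* A singleton cluster's density is defined as 1.0 so the first growth
  step is well-posed.
* Emitted clusters (size ≥ `min_cluster_size`, default 2) are removed
  from the working copy; the loop ends when it is edgeless. Never-
  clustered nodes are reported as the unclustered set.
* Overlapping mode (default, as pathways overlap): each emitted cluster
  is extended in the *original* graph by repeatedly re-admitting removed
  neighbours under the same two conditions; extension never alters the
  working copy. Defaults `cp_in = d_in = 0.5`.

## Enrichment and the S-value

The universe is the annotated subset of the analyzed metabolites — not
the full annotation — because the background choice changes every
p-value; clusters are restricted to it, and a cluster with no annotated
member scores "n.s.". Each cluster × pathway 2×2 table is tested
one-sidedly for over-representation: `p = P(X ≥ a)` hypergeometric with
the pathway size, cluster size and universe size as margins.
No multiple-testing correction is applied across pathways within a
cluster (raw p-values are the reported quantity); the global control is
the S-value permutation: `S` = mean of per-cluster `p_min`, compared
with `n_random = 100` size-preserving randomized cluster sets, each
cluster's members redrawn uniformly without replacement from the
universe (independently per cluster; a `global_permutation` flag instead
applies one random relabelling per set, preserving overlap structure).
`empirical_p = (1 + #{S_null ≤ S}) / (n_random + 1)` is never zero.
Overlapping cluster members count fully in every cluster they belong to.

## Pipeline

One top-level seed fans out to per-stage child seeds via
`SeedSequence.spawn` in a fixed order (synthetic, annotation, rankprod,
randomize, assessment), so stages are independently reproducible and a
full run is byte-deterministic (all writers sort their rows; the run log
records package versions and the derived seeds, no timestamps). Output
is one directory per analysis condition plus shared comparison tables; a
summary table reports per-condition significant-edge counts and
per-comparison differential-correlation counts. Cross-dataset comparison
restricts both datasets to their exact-string common metabolites
(identifier reconciliation is out of scope) and requires at least 4.

## Problem sizes used in tests

Calibration tests use 10,000 simulated correlation pairs (Fisher-Z
type-I), 200 null datasets (edge-call rate), and 10–12 rank-product
datasets at 250 permutations; recovery tests use 20 replicate datasets
at the default 59 × 53 design with 100 randomizations for both the
threshold null band and the cluster assessment. Unit tests use smaller
instances chosen to exercise the same code paths.

## Known limitations

* The DPClus reconstruction may partition borderline graphs differently
  from the original program; divergences on real data should be
  attributed here first.
* The Grenander-based local fdr is unstable below ~50 p-values (warned).
* The rank product requires complete rows; impute or drop first.
* Average path length over connected pairs only makes disconnected and
  connected graphs comparable but is not the classical (undefined)
  quantity on disconnected graphs.
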