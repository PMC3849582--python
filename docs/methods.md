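# Methods

This note documents the models implemented in `phenosets`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Gene-set derivation

A curated association table is a list of (gene, phenotype) records. Parsing
produces association pairs; collection building collapses duplicate
(phenotype, gene) combinations and emits one gene set per unique phenotype
term. Two normalization rules are load-bearing:

- **Gene identifiers** are printed as `locus_tag(symbol)` in worm
  annotation files, and the same gene can appear under different casings
  (`B0035.8(HIS-48)` vs `B0035.8(his-48)`). Identifiers are therefore
  compared case-insensitively after stripping the parenthesized symbol; the
  first-seen casing is kept for output, and symbols are metadata only
  (membership and overlap counts always use the canonical identifier, so a
  gene is never double-counted under tag and symbol).
- **Phenotype terms** mix spaces and underscores (`life span variant` vs
  `life_span_variant`); internal whitespace is collapsed to single
  underscores.

FlyBase-style allele rows (`arm[4]`) are mapped to genes by stripping the
bracketed allele designator by default; because the published collections do
not document their allele→gene mapping for driver constructs like
`Scer\GAL4`, the parser exposes an `allele_to_gene` hook instead of guessing
further. Each full phenotypic descriptor is kept as its own term (no
ontology roll-up). Malformed rows are skipped with a logged warning rather
than aborting: large curated dumps routinely contain stray rows.

Size filtering is inclusive on both bounds and, inside gene-set analysis,
counts genes *matched in the contrast* (the statistic's n_i), not nominal
set size.

## Genome-wide phenotype model

The pairwise distance is one minus the overlap coefficient,
`D_ij = 1 − |C_i ∩ C_j| / min(N_i, N_j)`, zero on the diagonal. Note the
min-denominator makes any nested pair (one set a subset of another) distance
0 even when the sets differ — a deliberate property of the overlap
coefficient, which reads nestedness as full relatedness.

The tree is fitted by weighted least squares on branch lengths:

    S = Σ_{i<j} n_ij (D_ij − d_ij)² / D_ij^P

- The sum runs over unordered pairs once. A full double count would scale S
  by 2 and move no minimizer.
- `P = 2` (default) is the Fitch–Margoliash weighting; `P = 0` is
  unweighted least squares. `n_ij = 1` by default (a replicate-count matrix
  is accepted).
- Zero off-diagonal distances would make the `1/D^P` weight infinite; they
  are replaced by `zero_distance_epsilon = 1e-6` in the weight denominator
  (residuals are unchanged), with a logged warning.
- Branch lengths are constrained nonnegative by default and solved by NNLS
  on the path-incidence design (this is exactly "clamp negative solutions
  to zero and refit"); `allow_negative_branches=True` switches to an
  unconstrained solve.

Topology search is heuristic: stepwise leaf addition in sorted label order
(each placement scored by a full branch-length fit), then
nearest-neighbor-interchange hill climbing until no move improves the
criterion. Ties are broken by the lexicographically smallest canonical split
set, so results are deterministic. Exhaustive enumeration of all
(2n−5)!! unrooted topologies is available for ≤ ~7 leaves and serves as the
search oracle in tests. A neighbor-joining starting topology
(`start="nj"`, via scikit-bio) is available as a faster seed for larger
collections. On exactly additive matrices the fit recovers the generating
topology and branch lengths with criterion 0 (tested to 1e-12).

Newick output roots the display at the internal node adjacent to the
lexicographically smallest leaf, orders children by smallest descendant
label, writes lengths at 12 significant digits, and quotes labels containing
spaces.

## PAGE gene-set scores

For one contrast (a per-gene change score GC), each set i with n_i matched
genes is scored

    Z_i = sqrt(n_i) * diff_i / sigma_a,   diff_i = mean(GC_i) − mean(GC_a),

with sigma_a the standard deviation of all n_a change values. The
alternative literal reading `(n_i − 1)·diff_i/sigma_a` is available behind
`statistic="n_minus_1"` but off by default; the sqrt(n) form is the
parametric gene-set enrichment statistic this analysis is named after, and
the two differ only by a monotone per-size rescaling.

The reported p-value is the two-sided normal tail of the set-vs-array mean
difference,

    sigma(diff_i) = sqrt(sigma_i²/n_i + sigma_a²/n_a),
    p_i = 2 (1 − Φ(|diff_i| / sigma(diff_i))),

with the limit convention p = 1 (diff = 0) or p = 0 otherwise when
sigma(diff) = 0. All standard deviations use the n−1 denominator.
Multiple-testing control is Benjamini–Hochberg across the sets surviving
the size filter, per contrast.

Known approximation properties, measured by the calibration routines:

- The normal approximation is anticonservative for very small sets (a z- vs
  t-test effect), and `sigma(diff_i)` adds `sigma_a²/n_a` where the exact
  subset null would subtract a finite-population term. For realistic
  conditions (2000-gene arrays, set sizes 10–200) the two effects roughly
  offset and the realized type-I error is ≈ 0.04–0.06 at nominal 0.05.
  For sets of < 10 genes expect inflation.
- The Z statistic's own normal-theory p, `2(1 − Φ(|z|))`, agrees with a
  resampling null that redraws the set's scores iid from the array's
  empirical distribution (within < 0.01 at 10⁵ draws). A
  without-replacement subset null is narrower by the finite-population
  correction, and the diff-based p above is wider still; at n_a = 200,
  n_i = 20 those conventions differ by up to ~0.05 in the mid-range of the
  p scale. The package reports the diff-based p (the convention the score
  table defines) and the calibration module quantifies the gap.

**Z-ratio preprocessing.** Expression matrices are first Z-scored per
sample column (mean 0, SD 1, sample SD); the contrast score per gene is the
difference of group-mean Z values divided by the SD of those differences
across genes, so contrast scores always have unit spread. Genes with
missing values in either group are dropped; duplicate gene rows should be
collapsed upstream (the matrix container rejects duplicate identifiers).

## Gene-set PCA

The set × sample Z matrix is row-centered (each gene set to mean 0 across
samples; optional unit-variance scaling via `scale=True`, default off —
centering only, matching the SVD-on-centered-rows convention) and
decomposed as `X_c = U S Vᵀ`. Sample coordinates are `Vᵀᵀ S` (right singular
vectors scaled by singular values), variance fractions are `s_k²/Σs²`, and
signs are fixed by making the largest-magnitude loading of each component
positive, so runs are bit-reproducible. Projection is invariant to adding a
per-row constant, and coordinates of identical samples coincide.

## Synthetic data and what passing tests mean

`simulate_association_table` plants block structure: phenotype terms are
assigned round-robin to `n_blocks` blocks; each gene of a set comes from
the block's shared pool with probability `within_block_sharing` (default
0.8), from another block's pool with probability `between_block_sharing`
(default 0.05), else from a shared background pool. The shared-pool size is
`gene_pool_size // (4·n_blocks)` (at least the maximum set size), which for
the defaults (12 phenotypes, 240 genes, sets of 6–12) produces within-block
distances ≈ 0.7–0.9 against between-block distances ≈ 1 — the strong
gene-sharing contrast that related phenotype families show in the real
collections. Emitted tables use locus-tag-style identifiers with
parenthesized symbols and space-separated terms so the real normalization
path is exercised. The ledger records every pair, block assignment and
shifted gene, and fully determines the output given the seed.

`simulate_expression` adds group-specific shifts for chosen target sets on
iid Gaussian baselines. It does **not** emulate microarray platform noise,
probe effects, gene–gene correlation, or structured missingness; passing
tests therefore demonstrate correctness and calibration of the algorithms
under their own model assumptions, not robustness to real-array artifacts.

## Problem sizes used in validation

The calibration studies run at sizes chosen to give stable Monte-Carlo
estimates while staying comfortably interactive: planted-block tree
recovery over 20 seeds of 12-leaf collections; type-I error over 20 × 200
random sets on 2000-gene null arrays; resampling comparison on 20 instances
(n_a = 200, n_i = 20, 10⁵ draws); power at shifts {0, 0.25, 0.5, 1}σ with
200 replicates each; end-to-end sensitivity over 10 seeds of 30-set
collections with three planted sets at 1σ; PCA separation over 20 seeds of
50 × 12 matrices with a 2σ shift on 20% of sets. Exhaustive topology
enumeration is used as an oracle only at 6 leaves (105 topologies).

## Known limitations

- The overlap-coefficient distance is not a metric (nested sets collapse to
  distance 0), so the fitted "tree" is a visualization of gene sharing, not
  a phylogeny; interpret branch lengths comparatively.
- Stepwise + NNI search is a local optimizer; on noisy matrices it can stop
  in local minima (the exhaustive oracle bounds this only at small sizes).
- PAGE assumes approximately independent gene scores; correlated sets
  (common in practice) inflate |Z|. The empirical p-value inherits the
  normal approximation caveats above.
- Directionality encoded in phenotype term names (e.g. `reduced_...`) is
  not interpreted; a positive Z means the set's genes are up-shifted in the
  contrast regardless of the term's own polarity.
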