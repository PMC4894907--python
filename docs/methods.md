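# Methods

## Model

PLSC decomposes the cross-product matrix A = X₁'X₂ of two
column-standardized blocks by SVD; weight vectors are singular vectors,
and each singular value equals the covariance (raw, un-normalized scale)
between the paired latent scores. PLSC-RP replaces a high-dimensional
block by its image under a random projection X·R before the SVD and
back-transforms the reduced-space weights through the cross-product with
the other block, scaled by 1/(sᵢ‖w‖²), followed by unit-normalization of
the weight columns.

Assumptions: the two blocks share an identical sample ordering; all
columns are finite with nonzero variance (constant columns — monomorphic
SNPs, dead voxels — are dropped with a warning, not an error); the
association of interest is linear in the standardized variables.

## Conventions and numerical choices

- **Standardization** uses the sample standard deviation (ddof = 1).
  Cross-products are the raw X₁'X₂ of standardized data with no further
  divisor; any common scale cancels in the back-transformation after the
  final unit-normalization. Because the literature is split on whether
  latent-score covariance is reported raw or per sample, `PlscModel`
  exposes both (`score_covariance(per_sample=...)`).
- **SVD sign**: the entry of largest absolute value in each block-2
  weight column is made positive; the paired block-1 column flips
  jointly. A joint flip leaves the model unchanged, so this is pure
  determinism, needed for reproducible output and cross-run comparison.
- **Columns constant up to rounding** (std below 1e-12 of the column
  scale) are treated as constant; bootstrap resamples in which a column
  becomes constant are redrawn and counted.
- **Component count**: either fixed, or the smallest number whose
  cumulative share of Σsᵢ² reaches a target (default 0.80).
- **Cross-validated component selection**: fold weights are jointly
  sign-aligned to the full-data fit before averaging the held-out score
  covariances (without alignment the folds' arbitrary SVD signs would
  cancel); the held-out covariance is per-sample (ddof = 1 within the
  fold). Components are matched across folds by singular-value rank —
  a known caveat when components are closely spaced.
- **Matrix-free path**: when d₁·d₂ exceeds a memory budget (default
  5·10⁷ entries), A is never materialized; A·v is computed as X₁'(X₂v),
  the truncated SVD uses a linear operator, and Σsᵢ² is obtained from
  the N×N Gram matrices via tr(G₁G₂). Below the budget the dense path
  is used for debuggability. Both paths are tested for agreement.

## Random projection

- Entries are i.i.d. N(0, 1) from a seeded generator; the same seed
  regenerates a matrix bit-identically, and a JSON sidecar (seed, shape,
  flag) makes any projection exactly reproducible.
- Orthogonalization (classical Gram–Schmidt, computed as thin QR with
  the R-diagonal made positive, which is algebraically the same map and
  numerically stabler) is applied by default below 1000 source
  dimensions and skipped above, where Gaussian columns are already
  nearly orthogonal; columns are unit-normalized afterwards in either
  case. The threshold is a module constant.
- The Menon bound k₀ = ((16+8β)/ε²)·ln N uses the natural logarithm
  (verified: it reproduces the published k₀ = 97.6486 and the full
  accuracy grid; base-10 does not). k defaults to ⌈k₀⌉ and can be
  overridden upward; requesting k below k₀ is an error unless explicitly
  overridden with a logged warning. ε outside [3/4, 3/2] — where the
  bound adapts best — warns but computes.
- Projected blocks are **not** re-standardized: the back-transformation
  identity operates on X·R directly, and re-standardizing would break it.
  Consequently `distortion_profile` rescales reduced distances by
  √(d/k), the expectation-preserving factor for unit-norm-column
  projections, before auditing the 1±ε band (stated on squared
  distances, as in the distance-preservation guarantee).

## Inference

- Permutation test: rows of block 2 are permuted without replacement
  (equivalent to reassigning observations, at half the cost of permuting
  both blocks); the statistic is the per-component singular value,
  matched across permutations by rank. p = (1 + #{permuted ≥ observed})
  / (B + 1): the add-one form keeps p in (0, 1] (a plain count/B can
  return 0), and ties count against significance. B < 19 is rejected
  because α = 0.05 cannot be resolved.
- For PLSC-RP fits the random matrices are held fixed across
  permutations and bootstrap replicates, so permutation testing runs
  entirely in the reduced space: the hypothesis tested is the
  association of the *projected* statistic actually reported. Redrawing
  R per permutation would test a different (marginal) null; it is not
  implemented.
- Bootstrap reliability: rows resampled with replacement,
  re-standardized, refit; replicate weights jointly sign-aligned to the
  original fit; SE = sd over replicates; a variable is reliable when
  |weight/SE| ≥ 2 (≈ two-sided z at 0.05; configurable — no canonical
  threshold exists).

## Synthetic study designs

The generator reproduces the three validation designs:

| preset | d₁ × d₂ | planted signal |
|---|---|---|
| `pheno_high` | 1000 voxels × 50 SNPs | 3 SNPs, mean r = 0.3 |
| `geno_high` | 2 phenotypes × 1000 SNPs | 3 SNPs, mean r = 0.45 |
| `both_high` | 1000 voxels × 1000 SNPs | 3 SNPs, mean r = 0.3 |

all at N = 100, Hardy–Weinberg Binomial(2, q) genotypes with q uniform
in [0.05, 0.5] (monomorphic columns redrawn), and multivariate-normal
phenotypes. The association is planted by blending every column of the
causal collinear block with the standardized sum g of the causal SNP
columns, v ← αg + √(1−α²)·z(v), with one α solved from the realized
corr(g, snpⱼ) so the mean causal voxel–SNP correlation hits the target;
α > 1 (target above the attainable mean |corr(g, snpⱼ)|) is an error
reporting the attainable maximum. Blending the whole block — rather than
one column with fresh noise — is what lets the collinear neighbours
inherit the association, as in the motivating designs.

**Collinear block size.** Real contrast images are strongly spatially
correlated, which is what makes a planted association the *dominant*
covariance component; with mostly-independent noise voxels the chance
bulk of a 1000×50 cross-product at N = 100 (top singular value ≈ 580)
would swamp a 20-voxel planted block (≈ 230). The presets therefore make
the collinear block 20% of the phenotype variables (signal ≈ 1300 vs
bulk ≈ 480 at the default sizes), the regime in which the causal
component ranks first, is permutation-significant, and exact/projected
weights agree — the documented behaviour of the method. Block size and
within-block correlation (default 0.5) remain exposed parameters.

**The two-phenotype design** (`geno_high`) emulates a candidate-
phenotype GWAS. Its planted correlation (0.45 over 3 SNPs) is the upper
end of what the single-blend construction can reach and corresponds to
a genome-wide-significant hit at this sample size. A caveat this
generator makes visible: with only two phenotype columns the left
singular space is a 2-vector whose orientation is partly set by the
chance covariance aggregated over all SNPs, which no attainable planted
signal can dominate at N = 100; phenotype weights under projection are
therefore reproduced qualitatively (two-component solution, high
SNP-side similarity, reliable planted SNPs), not to many digits.

**What the generator does not emulate:** linkage disequilibrium (an
optional adjacent-SNP correlation is deliberately out of scope),
population structure, 3-D voxel topology, and non-Gaussian phenotype
noise. Passing tests therefore show correctness of the algebra and the
claimed exact/projected equivalence under these idealized conditions,
not robustness to realistic LD or imaging artifacts.

## Problem sizes used in the acceptance script

Analytic quantities (Menon bound, accuracy grid) are exact. Similarity
targets use 20 seeds (one-sided and dual designs) or 10 seeds
(orthogonalization comparison) at the preset sizes above. The dual
high-dimensional sweep runs six size combinations — (1000, 1000),
(1500, 1500), (2000, 2000), (2500, 2500), (3000, 1000), (1000, 3000) —
one seed each: the same four-equal-steps-plus-two-asymmetric structure
as the original sweep, scaled so the *exact* PLSC reference fits (the
expensive part, quadratic-to-cubic in min(d₁, d₂)) stay tractable on a
single CPU. The similarity average over these combinations sits slightly
above the full-scale value, consistent with the documented trend of
similarity decreasing as dimensionality grows at fixed N.

## Known limitations

- Dual reduction at extreme d/N inherits the method's own caveat:
  chance correlation depresses similarity and permutation significance;
  no correction is applied because none is established.
- Component matching everywhere is by singular-value rank; closely
  spaced singular values can swap ranks across folds, permutations or
  projection seeds.
- The permutation and bootstrap loops refit via dense SVDs of the
  (reduced) cross-product; for un-reduced blocks with both dimensions
  large this is the exact method's cost, not the projected one's.
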