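# Methods

## The model: population-level PET covariance networks

A PET scan yields a single static quantification per subject, so
subject-level connectivity matrices — routine in fMRI or DTI — do not exist
for PET. The interregional correlation approach works at the population
level instead: given a homogeneous group of S subjects with one kinetic
parameter (CMRgl, Ki, BPnd) quantified in N regions of interest, the N x N
matrix of pairwise Pearson correlations across subjects is treated as the
group's adjacency ("covariance") matrix. Regions whose kinetic estimates
co-vary across subjects are read as functionally coupled.

The pipeline implemented here is:

1. **Per-subject z-scoring.** Each subject's N regional values are mapped to
   mean 0, sample SD 1 (denominator S-1). This removes multiplicative and
   additive inter-subject differences in global tracer uptake exactly: the
   correlation step becomes invariant to any per-subject affine rescaling of
   the raw values.
2. **Correlation with p-values.** r_ij is the Pearson correlation of the two
   ROI columns across subjects; the two-sided p-value comes from
   t = r sqrt((S-2)/(1-r^2)) on S-2 degrees of freedom.
3. **Thresholding** (never binarising) on either the p-value matrix
   (default: discard p > 0.05) or the correlation magnitude (|r| below a
   cutoff). Surviving correlations are optionally (default: yes) replaced by
   their absolute values so anticorrelations contribute connection weight.
4. **Fisher r-to-z.** Surviving weights are arctanh-transformed
   (variance-stabilising; |r| clipped at 1 - 1e-12 so degenerate inputs stay
   finite). The order is threshold -> absolute value -> transform: the
   p-value matrix is defined on r, and the transform is monotone, so the
   surviving edge set is identical either way.

### Graph metrics

On the thresholded weight matrix W (zero diagonal):

- **Node strength** s_i = sum_j W_ij.
- **Weighted clustering coefficient** (Onnela geometric-mean form, as in the
  Brain Connectivity Toolbox): with weights rescaled by the maximum weight,
  C_i = [sum_{j,h} (w_ij w_ih w_jh)^(1/3)] / [k_i (k_i - 1)], where k_i is
  the number of nonzero links; C_i = 0 for nodes with fewer than two links.
  The max-weight rescaling is required because Fisher-z weights exceed 1;
  it puts C_i in [0, 1]. Negative weights are refused (use absolute-value
  thresholding).
- **Edge-weight distribution**: the N(N-1)/2 lower-triangle Fisher-z values
  of the *unthresholded* matrix, so its element count and shape cannot be
  threshold artefacts.
- **Functional entropy**: Shannon entropy of the eigenvalue spectrum of the
  raw correlation matrix, H = -sum lam_i ln lam_i after clipping negative
  eigenvalues at zero and normalising the spectrum to sum to 1 (0 ln 0 := 0).
  H runs from 0 (rank-1, a single global mode) to ln N (identity, maximal
  disorder) and strictly decreases as a common equicorrelation rises.
  Natural log, unnormalised by default; `normalized=True` divides by ln N.

### Group comparison

Metric vectors and the edge distribution are compared in mean (Welch t,
Welch–Satterthwaite df) and variance (F ratio; two-sidedness via
2 min(cdf, sf) parametrically and |ln F| exceedance in permutations).
Whole-matrix comparisons: the entropy difference H_A - H_B (reported with
the mean relative difference 100 (H_A - H_B)/H_B, the second group being the
reference) and Krzanowski's principal-component test on the unthresholded
matrices — lambda = k - trace(S^T S) with S = L_A^T L_B the inner-product
matrix of the leading-k eigenvector sets (equal to the sum of squared sines
of the principal angles between the two k-dimensional subspaces: 0 when they
coincide, k when orthogonal), and mu = the sum of squared differences of the
sorted top-k eigenvalues. k defaults to the smallest number of pooled-data
components explaining 90% of variance, resolved once per comparison (and
once per resampling experiment) so the statistic's definition does not drift
across permutations.

Every statistic carries a **permutation p-value**: subjects of both groups
are pooled, group assignment is reshuffled (10,000 permutations by default),
and the *entire* pipeline — z-score, correlation, threshold, transform,
metric, statistic — is recomputed per permutation. This is the only null
that respects the population-level definition of the adjacency matrix.
p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm) (add-one rule, so p is never
zero and never below 1/(n_perm + 1)). No multiple-comparison correction is
applied across tests or metrics. Parametric p-values are reported alongside
but should not be trusted: the per-edge and per-node values entering them
are strongly dependent and non-normal, which is precisely what the
resampling experiment quantifies.

**Test-retest reliability** uses ICC(2,1) — two-way random effects, absolute
agreement, single measure — computed from the n_items x 2 mean-squares
decomposition, applied to the paired edge Fisher-z values and the per-ROI
strength and clustering vectors.

### Resampling validation

`fpr_experiment` repeatedly halves one homogeneous population (unordered
partitions, never repeated within a run; an odd subject count drops one
random subject per split), runs every test on the two halves, and reports
the per-cell rejection fraction at level alpha — the empirical false
positive rate, which should match alpha for a well-calibrated test. Node
metrics are evaluated both at the p < 0.05 cut and across an |r| threshold
scan (default 0.1–0.6). `population_size_experiment` draws two disjoint
subsets of a chosen size instead of halves (and reduces exactly to the
split-half design when the size is half the population). Each resample
index owns its own RNG substream derived from (seed, index), so enlarging
the experiment never reshuffles earlier splits.

## Synthetic populations

`SyntheticSpec`/`make_population` draw subject x ROI tables from a
multivariate normal with block equicorrelation: correlation `rho_within`
inside each block (default 4 near-equal blocks), `rho_between` across
blocks; positive semidefiniteness is verified by eigendecomposition at
construction. On top of the latent draw:

- values are placed on a CMRgl-like scale (mean 6, SD 1 in mg/100 g/min) or
  passed through a lognormal marginal (log-scale SD 0.5) to produce the
  right-skewed regional values that help drive parametric tests off their
  nominal level;
- each subject receives a multiplicative gain (lognormal, log-scale SD 0.2)
  and an additive offset (SD 0.5), emulating global uptake differences that
  the z-scoring step must remove;
- an optional `group_effect = (block, delta_rho)` raises one block's
  internal correlation, creating a detectable group difference;
- `make_testretest_pair` mixes a shared subject-level latent with fresh
  noise, sqrt(reliability) against sqrt(1 - reliability), so reliability 1
  reproduces the first occasion (up to per-occasion gain/offset) and 0 is an
  independent redraw.

Defaults (40 subjects, 23 ROIs, rho_within 0.5, rho_between 0.1) mirror a
typical resting [18F]FDG control cohort and are the conditions of the
calibration experiments below.

### What the generator does and does not emulate

Two properties of the real pipeline deserve emphasis because they shape
what passing tests mean:

- **Per-subject z-scoring across the N analysed ROIs imposes a zero-sum
  constraint**: each subject's centered values sum to zero, so every row of
  the across-subject covariance matrix sums to (approximately) zero and the
  *average* off-diagonal correlation is forced slightly negative
  (about -1/(N-1)). Consequently a nominal within-block correlation of 0.5
  appears as roughly 0.39 after z-scoring, and a *global* equicorrelation
  component is removed entirely — it is mathematically indistinguishable
  from a per-subject gain. Group contrasts must therefore live in
  block-level (relative) correlation differences. Real studies that z-score
  over a much larger region set than they analyse escape this constraint,
  which is one reason published PET covariance matrices can be almost
  uniformly positive while the emulation here cannot.
- **Thresholded networks are sparser than typical published PET networks.**
  With the default conditions, the p < 0.05 cut at 10 subjects per group
  (|r| >= 0.632) removes most edges; the clustering vector then degenerates
  to all zeros in many resamples, its variance test becomes a tie-dominated
  (conservative, never anticonservative) comparison, and its empirical FPR
  falls well below alpha. The same happens in the |r| scan at cuts of 0.5
  and above. The calibration conclusions for the non-degenerate cells are
  unaffected, but the spread of FPRs across *all* cells at small group
  sizes is dominated by this structural effect rather than by test error.

## Numerical choices

- Correlations clipped to |r| <= 1 - 1e-12 before arctanh; matrix symmetry
  checks with allclose tolerances; negative eigenvalues clipped at zero
  before spectral-entropy normalisation (thresholded or absolute-valued
  matrices can be slightly indefinite).
- The p-value threshold inside the resampling engine is applied through the
  exactly equivalent critical-|r| cutoff r_crit = t_crit /
  sqrt(S - 2 + t_crit^2), precomputed once per group size, so no
  distribution functions are evaluated inside the permutation loop.
- Degenerate (zero-variance) metric vectors: Welch t and ln F are 0 when
  the two sides agree and a large sentinel value when they cannot; the
  permutation exceedance count treats ties as exceedances, keeping the test
  valid (conservative) under degeneracy.
- Permutation streams are drawn over the *sorted* pooled subject set, so
  the p-value is invariant to input row order and (for equal group sizes)
  to swapping the two groups.
- Missing values in input tables: rows containing any missing value are
  dropped with a logged count, never imputed — pairwise deletion would make
  the effective n differ per edge. Non-numeric junk is a hard error naming
  row and column.
- Text precision: estimate tables round-trip bitwise (shortest float repr);
  derived matrices and edge lists use 10 significant digits, stable under
  write -> read -> write.

## Experiment sizes

The resampling experiments default to 500 resamples x 1000 inner
permutations (the full design used 10,000 x 10,000; both knobs are plain
arguments). At 500 resamples the binomial SE of an empirical FPR at the 5%
level is ~0.97 percentage points, which is the yardstick used by the
calibration checks. The parameter-recovery check uses 5000 subjects; the
test-retest monotonicity check uses 200 subjects x 12 ROIs over
reliabilities {0, 0.5, 0.95}.

## Known limitations

- Group-level only: no subject-level adjacency matrices, by construction of
  the method.
- Simple Pearson correlation only — partial correlation, sparse inverse
  covariance and distance correlation are deliberate non-goals.
- No covariate adjustment inside the permutation scheme; remove ancillary
  covariates from the estimates beforehand.
- No multiple-comparison correction across the test battery.
- The entropy and Krzanowski statistics follow the constructions documented
  above; published magnitudes computed with differently scaled variants are
  not comparable number-for-number, though the zero/identity limits and
  calibration behaviour are.
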