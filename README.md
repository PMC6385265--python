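# petcov

Covariance statistics and weighted network analysis for regional brain PET
kinetic estimates.

A PET scan delivers one static quantification per subject, so the
subject-level connectivity matrices familiar from fMRI do not exist for PET.
`petcov` implements the population-level alternative: given a homogeneous
group's subjects × ROIs table of one kinetic parameter (CMRgl, Ki, BPnd),
it builds the group's N × N interregional Pearson correlation matrix — the
*PET adjacency matrix* — after per-subject z-scoring, thresholds it (on
p-values or |r|, never binarising), applies the Fisher r-to-z transform, and
derives weighted network metrics:

- node strength s_i = Σ_j W_ij and the Onnela weighted clustering
  coefficient C_i = [Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}] / [k_i(k_i − 1)]
  (Brain Connectivity Toolbox definitions, max-weight rescaled);
- the unthresholded edge-weight (Fisher-z) distribution;
- the functional entropy H = −Σ_i λ̃_i ln λ̃_i of the correlation matrix's
  normalised eigenvalue spectrum (0 for rank-1 order, ln N for the identity).

Because the adjacency matrix is defined at the group level, group
comparisons need group-level inference: every statistic (Welch t and F on
metric vectors and edges, the entropy difference, Krzanowski's
principal-component λ and μ) comes with a permutation p-value obtained by
reshuffling subjects between groups and recomputing the *entire* pipeline
per permutation, p = (1 + b)/(1 + n_perm). The package also ships the
machinery to audit this: split-half resampling experiments that measure
empirical false-positive rates per test and threshold, population-size
sensitivity runs, and ICC(2,1) test-retest reliability. It is aimed at
molecular-imaging researchers analysing regional quantifications (e.g.
metabolic connectivity in ageing or dementia cohorts) and at
methods-minded users who want the calibration evidence alongside the
p-values.

## Worked example

Two synthetic populations of 40 subjects × 23 ROIs; the "patient" group has
the internal correlation of one ROI block raised by 0.35:

```python
import numpy as np
from petcov import (SyntheticSpec, make_population, compare_all,
                    build_adjacency, fisher_transform, apply_threshold,
                    ThresholdSpec, node_strength, functional_entropy)

ctrl = make_population(SyntheticSpec(n_subjects=40, seed=7),
                       group_label="controls")
pat = make_population(SyntheticSpec(n_subjects=40, seed=8,
                                    group_effect=(0, 0.35)),
                      group_label="patients")

A = fisher_transform(build_adjacency(ctrl))          # z-score -> r, p, z
W = apply_threshold(A, ThresholdSpec("pvalue", 0.05))
print(round(functional_entropy(A), 3))               # 2.693  (ln 23 = 3.135)
print(np.round(node_strength(W).values[:5], 2))      # [0.75 0.38 1.71 0.47 1.98]

res = compare_all(pat, ctrl, n_perm=2000, seed=17)
for name in ("strength_mean", "edge_distribution_mean", "entropy",
             "krz_eigenvalue"):
    r = res[name]
    print(f"{name:24s} obs={r.observed:+.3f} perm_p={r.permutation_p:.4f}")
```

```
strength_mean            obs=+3.700 perm_p=0.0380
edge_distribution_mean   obs=+0.354 perm_p=0.0005
entropy                  obs=-0.240 perm_p=0.0015
krz_eigenvalue           obs=+7.293 perm_p=0.0005
```

The tightened block raises the mean edge weight and node strength, lowers
the entropy (the system becomes more ordered; the mean relative difference
reported on the result is −8.9%), and shifts the leading eigenvalues —
each detected by its permutation test at n_perm = 2000.

The same pipeline is available from the shell:

```bash
petcov simulate --n-subjects 40 --n-rois 23 --seed 7 --out controls.tsv
petcov build --input controls.tsv --threshold-mode pvalue --cutoff 0.05 \
             --out weights.tsv --r-out corr.tsv
petcov metrics --adjacency weights.tsv --metric strength --out strength.json
petcov compare --group-a patients.tsv --group-b controls.tsv \
               --n-perm 10000 --seed 17 --out comparison.json
petcov validate-fpr --input controls.tsv --n-resamples 500 --n-perm 1000 \
                    --alpha 0.05 --seed 7 --out fpr.json
```

Input tables are CSV/TSV with subject IDs in the first column and ROI
labels in the header; every JSON output embeds the resolved configuration
and seed, so identical invocations are byte-identical.

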