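# cellrplr

Cellwise outlier diagnostics and biomarker identification for grouped
metabolomics abundance tables, based on robust pairwise log ratios
(cell-rPLR).

## The problem

Untargeted metabolomics delivers an n samples x d features table of
positive abundances, typically with few samples, thousands of features, and
two or more groups (controls vs. disease). Two things make these tables
awkward for classical statistics:

* **size effect** — each sample carries an unknown multiplicative factor
  s_i (urine dilution, injection volume), so raw values are not comparable
  across samples and normally require normalization (TSN, PQN);
* **cellwise outliers** — single anomalous cells rather than whole
  anomalous samples. Downweighting entire rows is futile when most rows
  contain at least one bad cell, yet an outlying cell may be either a data
  artifact or exactly the biomarker signal one is looking for.

## The method

The elemental statistic is the pairwise log ratio
`y_ijk = ln(x_ij / x_ik)`, which cancels the size effect
(`ln(s*x/(s*y)) = ln(x/y)`), so no normalization is needed. For every
feature pair (j, k):

1. compute the log ratios for all samples;
2. standardize them with a robust center (one-step Tukey-biweight weighted
   mean) and scale (MAD with consistency factor 1.483) estimated **on the
   majority group only**, so that group differences survive;
3. map the standardized ratios through a bounded odd *outlyingness
   function* `w*(u)` in [-1, 1] — an adjusted Tukey biweight
   (`(1 - omega_c(u)) * sgn(u)`, c = 4.685), adjusted Huber (k = 1.345,
   identically zero on [-k, k]) or adjusted Hampel (knots at the
   0.95/0.975/0.99 standard-normal quantiles, exactly +-1 beyond the last);
4. aggregate robustly over the denominator index:
   `w_ij = median(w*_ij1, ..., w*_ijd)`.

The result is an n x d outlyingness matrix W with entries in [-1, 1]:
values near 0 are unremarkable, near +1 the cell is far above what the
reference group predicts, near -1 far below. W is visualized as a
red/white/blue heatmap (no hard outlier cutoff is imposed).

For exactly two groups, the per-feature statistic

```
m_j = median(w_j | group 1) - median(w_j | group 2)
```

ranks biomarker candidates (all w_ij live on a common scale), and a
permutation test — shuffling the feature index independently within each
sample's row, which provably commutes with step 4 — attaches p-values
`p_j = (1/B) * #{b : m_j <= m_j(b)}` (or the symmetric version on |m_j|),
with B = 1000 replicates by default.

## Worked example

```python
import numpy as np
from cellrplr import (CellRPLR, SyntheticSpec, generate_dataset, contaminate,
                      permutation_test, roc_points, biomarker_metrics)

# two groups of 10 samples, 100 features, 5 planted biomarkers,
# a strong per-sample size effect -- then contaminate 10% of the cells
X, truth = generate_dataset(SyntheticSpec(), seed=1)
Xc, record = contaminate(X, (0.10, 0.10), seed=2)

est = CellRPLR(function="tukey")          # scikit-learn style estimator
W = est.fit_transform(Xc.values, Xc.groups)
print(est.reference_group_)               # g1  (the majority group)
print(W.shape, W.min().round(3), W.max().round(3))
# (20, 100) -0.86 1.0

fpr, tpr, auc = roc_points(np.abs(W), record.mask)
print(round(auc, 3))                      # 0.749

res = permutation_test(W, Xc.groups, B=1000, seed=3)
tpr_b, tnr_b, avg_rank = biomarker_metrics(res, truth, alpha=0.05)
print(tpr_b, round(tnr_b, 3), avg_rank)   # 1.0 0.916 3.0
```

The AUC of 0.749 measures recovery of the contaminated cells; it is
conservative here because the planted biomarker cells of group 2 also score
high — legitimately — yet count as negatives against the contamination
mask (on tables without planted biomarkers the same setting averages about
0.82). The permutation test finds all five planted biomarkers at the 5%
level (TPR 1.0) while retaining 91.6% of the 95 non-biomarkers (TNR), and
the biomarkers occupy an average rank of 3.0 out of 100 despite the
corrupted cells — the outlyingness values, being medians of bounded
scores, are barely moved by contamination.

The same pipeline is available from the shell:

```bash
cellrplr simulate --d 100 --seed 1 --out data.csv --truth truth.json
cellrplr score --input data.csv --sample-id-col sample_id --function hampel --output W.csv
cellrplr heatmap --input data.csv --sample-id-col sample_id --output W.png
cellrplr biomarkers --input data.csv --sample-id-col sample_id -B 1000 --seed 3 --output biomarkers.csv
```

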