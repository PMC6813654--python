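# reosig

Rank-based gene-pair signatures for predicting chemotherapy response
from survival-annotated expression cohorts.

## The problem

Most transcriptional signatures for predicting treatment response score
a patient by summing (normalized) expression values of signature genes.
Such quantitative scores are fragile in the clinic: they shift with
measurement batch, with the normalization cohort, with tumor-cell
fraction, and with RNA degradation — and a patient's risk call can
change depending on which *other* samples happen to be processed
alongside theirs.

`reosig` implements the qualitative alternative: signatures built from
**within-sample relative expression orderings (REOs)** of gene pairs.
For an oriented pair (a, b) the only information used is whether
`E_a > E_b` *inside one sample*. Any strictly increasing per-sample
distortion — the mathematical form of a batch effect — leaves every
such ordering unchanged, so a REO signature can be applied to a single
sample in isolation, on any platform.

The package targets the setting of high-grade serous ovarian cancer
(HGS-OvCa) treated with platinum–taxane adjuvant chemotherapy, where
the clinical outcome is recurrence-free survival (RFS) and pathological
response is recorded as complete response (CR) vs non-CR. It ships the
published four-pair ovarian-cancer signature (`four_gps()`: FUS>THBS2,
GUCY2C>RCVRN, PCSK6>ZNF365, PASK>DNAJB14) with its strict-majority
rule: a sample is called a **responder iff more than half of the pairs
show the favorable ordering** (for four pairs: at least three).

## What the package does

- **Discovery** (`run_discovery`): from a training cohort with CR /
  non-CR labels and RFS, (1) select genes differentially expressed
  between CR and non-CR (pooled t-test, p < 0.05) whose expression is
  associated with RFS (univariate Cox, p < 0.05); (2) reduce every
  pair of surviving genes to its ordering indicator `1[E_a > E_b]`,
  fit Cox on the indicator, orient so the favorable pattern has hazard
  ratio < 1, and keep pairs at Benjamini–Hochberg FDR < 0.05; (3) grow
  a majority-voting committee by seeded greedy forward selection
  maximizing Harrell's C-index.
- **Classification** (`vote_classify`, `four_gps`): strict-majority
  voting, cohort-independent by construction; plus the median-anchored
  point-score comparator (`quant_score_classify`) whose labels *do*
  depend on cohort composition — included to demonstrate the contrast.
- **Validation** (`validate_signature`, `response_crosstab`,
  `subgroup_survival`, `cross_cohort_comparison`): Kaplan–Meier curves
  per predicted group, log-rank test, univariate and covariate-adjusted
  Cox models of the predicted label (age ≥ 60, ordinal stage, grade 3
  vs 2, residual tumor ≥ 11 mm; covariates screened at univariate
  p < 0.2), Harrell's C-index, and Fisher's exact cross-tabulation of
  predictions against pathological response.
- **Simulation** (`generate_cohort`): seeded synthetic cohorts with a
  latent responder state, planted oriented pairs, exponential
  proportional-hazards recurrence, uniform censoring and noisy CR
  labels, plus batch-effect and degradation operators for robustness
  experiments.

The statistical kernel (`reosig.stats`) exposes Cox fits with Efron
tie handling and Wald inference, Kaplan–Meier, log-rank, Harrell's C,
BH FDR, pooled t, Fisher exact and chi-square tests behind one
validated interface.

## Worked example

```python
import reosig as rs
from reosig.data import truncate_followup

cohort = rs.generate_cohort(rs.GeneratorConfig(seed=7))   # 300 patients, 150 genes
train, test = rs.split_cohort(cohort, [0.5, 0.5], seed=7)

signature, counts = rs.run_discovery(train.expression, train.clinical)
print(counts)
print([p.name for p in signature.pairs], round(signature.training_cindex, 3))

report = rs.validate_signature(test.expression,
                               truncate_followup(test.clinical), signature)
fit = report.cox_univariate
print(report.n_non_responders, report.n_responders,
      report.logrank.p_value, fit.hazard_ratios[0], report.cindex)
```

Output:

```
{'samples': 150, 'de_genes': 17, 'prognostic_genes': 10, 'candidate_pairs': 45,
 'prognostic_pairs': 8, 'signature_pairs': 7}
['G0024>G0005', 'G0096>G0043', 'G0096>G0145', 'G0010>G0027', 'G0024>G0146',
 'G0051>G0107', 'G0051>G0145'] 0.646
84 66 6.28e-06 2.62 0.646
```

Reading: of 150 training patients, 17 genes survive the
differential-expression screen, 10 the prognostic screen; of their 45
pairs, 8 orderings are FDR-significant, and forward selection keeps a
7-pair committee (training C-index 0.646) that contains all 4 planted
pairs. On the held-out half, the 84 predicted non-responders recur
significantly faster than the 66 predicted responders (log-rank
p = 6.3e-06) with hazard ratio 2.62 — close to the simulated
non-responder hazard ratio of 3 — and C-index 0.646.

The same pipeline is scriptable from a shell: `reosig simulate`,
`reosig discover`, `reosig classify`, `reosig validate`,
`reosig robustness` (see `reosig --help`).

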