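# Methods

This note records the statistical model behind `reosig`, the
conventions and tolerances the implementation commits to, and the
design decisions that were genuinely open.

## Setting and model

Each patient contributes a vector of log-scale expression values
(genes × samples matrix), a recurrence-free survival time in months
with an event indicator, a pathological response label (CR / non-CR,
possibly missing), and coded clinical covariates. Follow-up is
truncated at 60 months before any survival analysis: a record with
more than 60 months of follow-up is censored at 60 (strict inequality;
truncation is idempotent).

The object of inference is an oriented gene-pair signature: a list of
pairs (a, b) with the convention that the *favorable* pattern —
associated with longer recurrence-free survival — is `E_a > E_b`
within a sample. Classification is by strict majority: a sample is a
responder iff strictly more than half of the pairs show their
favorable ordering; a tie in expression (`E_a = E_b`) counts as not
favorable (ties have measure zero in continuous data; the convention
only matters for degenerate inputs). Because the rule consumes only
within-sample order statistics, it is exactly invariant to any
strictly increasing per-sample transform and needs no reference
cohort — the two properties that motivate rank-based signatures over
quantitative risk scores.

## Discovery pipeline

Stage 1 (quantitative): genes separating CR from non-CR by
pooled-variance t-test at two-sided p < 0.05, then genes whose
continuous expression is associated with survival by univariate Cox at
Wald p < 0.05. Samples with missing response state are excluded from
the t-test; genes with zero pooled variance are skipped with a logged
warning, as are genes whose Cox fit does not converge. All thresholds
are strict inequalities.

Stage 2 (rank-based): every unordered pair of surviving genes is
reduced to its ordering indicator `1[E_a > E_b]`. Pairs whose
indicator is constant across the cohort carry no information and are
dropped. A univariate Cox fit on the indicator is oriented so the
favorable pattern has hazard ratio < 1; Wald p-values are
Benjamini–Hochberg adjusted over all tested pairs and pairs with
q < 0.05 are kept, each annotated with the concordance index of its
single-pair vote (risk 1 for the unfavorable ordering).

Stage 3 (search): seeded greedy forward selection of a majority-voting
committee maximizing Harrell's C-index of the vote (risk 1 for
predicted non-responders). Details below, since this is where the
genuinely open design choices live.

From stage 2 onward the pipeline consumes only order information, so
stages 2–3 produce identical outputs under any strictly increasing
per-sample distortion of the expression matrix.

## Forward selection: committee growth

Three observations shape the search design.

1. **Even-sized majority votes are structurally conservative.** With
   2k pairs, a k–k split is *not* a majority, so the vote defaults to
   non-responder. Empirically the C-index of a grown committee dips at
   every even size and recovers at the next odd size. A one-pair-at-a-
   time search that demands strict improvement at every step therefore
   stalls at sizes 1–2 regardless of how informative the remaining
   pairs are. The committee is instead grown **two pairs at a time**
   from each seed, so every growth step is evaluated on a
   decision-coherent odd-sized vote.
2. **C-index differences below sampling resolution are not
   evidence.** At a few hundred observed events the standard error of
   Harrell's C is roughly 0.01. The search treats differences smaller
   than `cindex_tol` (default 0.01) as ties. Tied candidate additions
   are resolved by the **weakest member** of the resulting committee —
   the candidate double whose larger pair-level q is smallest wins
   (then lexicographic pair name). Ranking by the weakest member
   rather than the strongest prevents a weakly associated pair from
   riding into the committee on a strong partner's association.
3. **Stopping and final choice use the same resolution.** Growth stops
   when the chosen addition worsens the C-index by more than
   `cindex_tol`; within-tolerance plateaus continue (tie-broken toward
   strongly associated pairs). Each seed returns its fully grown set.
   Among seed-grown sets, those within `cindex_tol` of the best final
   C-index are tied; the tie is again resolved by the weakest member's
   association strength, then fewest pairs, then lexicographic names.
   The whole search is deterministic given the data.

Consequences: committees have odd size; along a growth path the
C-index never drops by more than the tolerance between steps (it need
not be strictly increasing); and the returned C-index can sit below
the best single-pair C-index by at most roughly one tolerance per
growth step — the price of preferring larger, more stable voting
committees when performance is statistically indistinguishable. An
alternative design that trimmed each path back to its maximal-C
prefix was evaluated and rejected: with strongly associated pairs the
bare seed is often the exact argmax, which collapses committees to a
single pair and discards real signal.

## Statistical kernel conventions

- **Cox proportional hazards**: Efron tie handling, Newton-type
  maximisation (via lifelines), Wald tests, 95% CIs as
  `exp(coef ± 1.96·se)`. Constant covariates raise a degenerate-
  covariate error; monotone-likelihood fits are returned flagged
  `converged=False` and are excluded from screens with a warning.
  Fits require n ≥ p + 2 and at least one event.
- **Harrell's C**: a pair (i, j) is comparable iff the times differ
  and the earlier subject had an event; concordant when the earlier
  subject has the strictly higher risk score; tied scores contribute
  0.5. These conventions are implemented directly (not delegated) so
  they are explicit and testable against O(n²) enumeration.
- **Covariate codings** for clinical Cox models: age ≥ 60 vs < 60;
  stage ordinal II/III/IV → 2/3/4; grade 3 vs 2; residual tumor
  ≥ 11 mm vs 0–10 mm. Covariates are screened univariately at p < 0.2
  (each on its own complete cases) before entering the adjusted model,
  which is fit on complete cases with `n_used` reported.
- **t-test**: pooled-variance (Student) form, two-sided. The Welch
  form is deliberately not the default; the pooled form is what
  "Student's t-test" names, and the choice is isolated in one
  function.
- **Fisher's exact test**: two-sided by the minimum-likelihood
  convention — the p-value sums hypergeometric probabilities of all
  tables with the observed margins whose probability does not exceed
  the observed table's (relative comparison tolerance 1e-7). On the
  2×2 table [[10, 12], [2, 14]] this yields p = 0.0403 to four
  decimals.
- **Benjamini–Hochberg**: step-up adjusted values with monotonicity
  enforcement; selection at level q means adjusted value strictly
  below q.
- **Log-rank**: k-sample chi-square with k − 1 degrees of freedom.

## The synthetic-data generator

`generate_cohort` draws, per patient: a latent responder state
(Bernoulli, prevalence 0.5); recurrence time exponential with rate
λ0 = 0.02/month for responders multiplied by hazard ratio 3 for
non-responders; censoring uniform on (0, 80) months (together with
the 60-month truncation this yields roughly one-third censored
records); and a recorded CR / non-CR label that contradicts the latent
state with probability 0.1. Background genes are i.i.d. normal with
per-gene means uniform on [4, 12] (a log2-like scale) and sd 1. For
each of the 4 planted pairs (a, b), the within-sample difference
`value(a) − value(b)` is positive for latent responders and negative
for non-responders, with the sign flipped independently per sample
with probability 0.05 (`reo_error`) and magnitude drawn |N(1, 0.5)|.
Clinical covariates (age, stage, grade, residual tumor) are drawn at
the marginal frequencies of a typical late-stage HGS-OvCa trial cohort
and carry no survival signal of their own.

Planted-pair baseline levels are evenly spaced across the expression
range with small jitter rather than drawn i.i.d. This is an
identifiability choice: if two planted pairs landed at overlapping
levels, the *cross* orderings (gene a of one pair vs gene b of the
other) would track the latent state as well as the planted orderings
do, and "the planted pairs" would no longer be the unique ground truth
that recovery experiments measure. With spaced levels, cross orderings
are nearly constant and drop out of the pair screen.

What the generator does *not* emulate: RNA-seq count distributions
(negative binomial), gene–gene correlation structure, platform- or
probe-specific effects, informative censoring, covariate–outcome
confounding, and time-varying hazards. Tests passing on these cohorts
therefore demonstrate correctness of the pipeline's logic and its
calibration under a proportional-hazards world, not performance on
real tumor data.

Perturbation operators: `apply_monotone_distortion` applies an
independent strictly increasing map per sample (affine, power, or
softplus-composite families with per-sample random parameters) —
within-sample orderings are preserved by construction;
`degrade_samples` adds i.i.d. Gaussian noise and floors a random
fraction of each sample's genes to that sample's minimum (dropout),
which does perturb orderings. `split_cohort` partitions a cohort
reproducibly with alignment preserved.

## Reference experiment scales

The test-suite and the acceptance script run the pipeline end-to-end
at the scales the package documents as its reference study conditions:
cohorts of 300 patients × 150 genes for discovery (20 replicates for
recovery rates), 1000 patients for hazard-ratio recovery, 100 null
replicates for calibration, 200 replicates for log-rank uniformity,
and 1,000 random monotone transforms for the invariance suite. The
problem sizes are stated in each reported JSON entry.

## Known limitations

- The greedy search offers no optimality guarantee; it is a faithful,
  deterministic implementation of seeded forward selection, not an
  exhaustive subset search.
- The C-index tie tolerance (0.01) is calibrated to cohorts with a
  few hundred events; for much larger cohorts a smaller value would
  be appropriate (it is a parameter of `forward_select_signature`).
- Hazard-ratio attenuation: the vote misclassifies a small fraction of
  latent states (a function of `reo_error` and committee size), so the
  recovered group hazard ratio is biased slightly toward 1 relative to
  the latent-state hazard ratio.
- The comparator's 23-gene point-score list is user-supplied; the
  package ships no default gene list, only the scoring rule.
- Missing expression values are not supported (the matrix must be
  finite); abstention semantics for partially measured signatures are
  deliberately out of scope.
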