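# Methods

`talentscreen` implements a holistic athlete-development analysis for small,
unbalanced two-group cohorts: a low-performing majority (default n = 23) and
a high-performing minority (default n = 6) profiled on several hundred
mixed-type developmental attributes.  The pipeline has four stages —
performance grouping, logical-attribute screening, consensus feature
selection, and leave-one-out classification — plus a synthetic-cohort
generator that makes every stage testable without real athlete data.

## Performance grouping

Competition totals are ranked against a normative reference population
stratified by age group × sex × bodyweight class.  The percentile is the
weak empirical one, 100 · #(reference ≤ total)/n, so ties count and the
stratum maximum sits at 100.  An athlete is labelled *high* when their best
total over the evaluation window reaches the threshold percentile (default
80); `statistic="latest"` uses the chronologically last record instead.
"Top 80th percentile" is read inclusively (≥ 80).  Raising the threshold can
only move athletes from high to low (monotonicity), and labels are invariant
to record order.

## Logical-attribute screening

For each attribute a *parameter vector* of exactly 100 equally spaced
thresholds spans the observed minimum to maximum.  A *logical attribute* at
threshold θ codes an athlete 1 when their value is strictly above θ
(equality codes 0 by default; configurable), with missing values propagated
and excluded pairwise.

**Threshold selection.**  The two "directional samples" are interpreted as
two one-sided Fisher exact tests: enrichment of the rule among high
performers, and depletion of the rule among low performers.  Conditional on
the table margins these two tests coincide numerically, so the first branch
of the selection cascade — lowest θ with both directional p-values < α —
reduces to the enrichment p.  The second branch (lowest θ with at least one
directional p < α) also admits the protective direction, which is how rules
that are *more* common among low performers (odds ratio < 1) become
selectable.  The third branch falls back to the range minimum when nothing
is significant; a constant attribute is flagged degenerate.  A `literal`
mode replaces both directional tests with the two-sided p, collapsing
branches 1 and 2.

Because the cascade deliberately takes the *lowest* significant threshold,
the selected 2×2 table is often the most marginal significant one.  The
discriminator verdict therefore uses the same directional p-values that
drove selection (`p_selection`); the two-sided p is reported alongside for
reference.  No multiplicity correction is applied — the report prints the
number of tests performed so users can judge the familywise burden
themselves.

**Effect summary.**  The small-sample-adjusted odds ratio is

    OR_small = a·d / ((b+1)·(c+1))

with a = exposed ∧ high, b = exposed ∧ low, c = unexposed ∧ high,
d = unexposed ∧ low.  The +1 in the off-diagonal cells keeps the estimate
finite for every table, including zero cells (a = 0 gives exactly 0).
Fisher exact p-values are computed in-package from the conditional
hypergeometric distribution (the classical minimum-likelihood two-sided
rule), vectorised over the threshold grid; the implementation is checked in
the test suite against independent brute-force enumeration and against
`scipy.stats.fisher_exact`.  Confidence intervals are the exact conditional
(noncentral-hypergeometric tail-inversion) intervals from
`scipy.stats.contingency.odds_ratio`; note they bracket the conditional MLE,
not the small-adjusted point estimate, whose +1 correction matches no
standard interval recipe — they are reported for context only.

**Importance grading.**  A significant rule is positioned on two 0–100
scales — one for odds-ratio size, one for the true positive rate (the
rule's prevalence among high performers) — and graded by the midpoint.
Both scales are piecewise linear through configurable anchors.  The default
OR anchors are (4.6, 17, 23, 31) → (0, 33, 66, 100) and the TPR anchors
(0, 30, 60, 100)% → (0, 33, 66, 100), with grade cut-offs High ≥ 33 and
Moderate ≥ 15.  These defaults satisfy the calibration constraint that any
odds ratio above 4.6 combined with a TPR above 60% grades High, and they
reproduce 51 of 53 of the printed High/Moderate labels in the motivating
discriminator tables — the two misses are (OR 8.25, TPR 50%) and (OR 5.25,
TPR 50%), each of which appears in those tables under *both* labels, so no
single configuration can reproduce all of them.  An alternative
`ImportanceScales.from_distribution` anchors the OR scale at the
0th/33rd/66th/100th percentiles of a run's own significant odds ratios; it
is not the default because, on the printed label set, percentile anchors
provably cannot satisfy the 4.6/60% constraint and the printed Moderate
labels simultaneously (the printed ORs cluster in [5, 9.5], forcing the
scale to rise steeply exactly where the labels require it to be flat).

Protective rules (OR < 1) indicate the low-performing group, so when cell
counts are available they are graded by the magnitude 1/OR and the
low-group prevalence.  Without counts the risk-direction scale applies, so
an OR of 0 with TPR 0 grades Low.  One published protective row (prevalence
52% among low performers, graded Low in print) grades higher under this
scheme; the printed grading of protective rows is not fully self-consistent
and the choice here favours the rows with clear prevalence support.

**Commonalities.**  Rules that do not discriminate but are met by ≥ 60%
(configurable) of *both* groups are flagged as candidate baseline
requirements for participation.  The second published criterion —
theoretical relevance — is a domain judgement and is deliberately not
automated: the output is a reviewer checklist.

## Consensus feature selection

Attributes are min-max normalised (constant columns map to 0 and are
flagged).  Four ranking procedures score every attribute *individually* by
its leave-one-out discrimination under a classifier family:

* `bayes` — Gaussian naive Bayes with exact leave-one-out class moments;
* `tree` — a depth-1 entropy stump (C4.5-style split) refit per fold;
* `margin` — the class-midpoint threshold rule, the one-dimensional
  analogue of a linear maximum-margin classifier;
* `neighbour` — 1-nearest-neighbour, distance ties to the lowest row index.

Scores are balanced accuracy (mean of per-class correct rates): with a
23-vs-6 imbalance, plain accuracy would reward majority-class guessing.
Score ties break by attribute name, making rankings fully deterministic.
The scorers are closed-form/vectorised over the whole attribute matrix,
which keeps 100-replicate simulations over 648 attributes to a few tens of
seconds.  The internals of the reference implementation's feature selection
are not published; single-feature wrapper scoring was chosen as the
reproducible default honouring the four named algorithm families.

The summary model intersects the four top-k lists (k = 20 by default):
membership in all four tiers as very important, in three as important, in
two as fairly important; fewer appearances exclude the attribute.  Each
selected attribute carries a direction of influence per group: '+' for the
group with the greater normalised mean, '−' for the other, '0' on ties.

## Classifier evaluation

The selected features are evaluated by leave-one-out cross-validation under
four classifier families (scikit-learn): Gaussian naive Bayes, an
entropy-criterion decision tree with a two-sample leaf floor as the pruning
analogue, a linear SVM with C = 1, and 1-nearest-neighbour.  Training rows
are sorted before fitting so predictions cannot depend on presentation
order.  The positive class is the *low*-performing group — back-derived
from the motivating summary table, where sensitivity 0.913 = 21/23 and
specificity 0.500 = 3/6 only if positives are the 23-member class — and is
configurable and reported.  Metrics per classifier: accuracy (%),
sensitivity, specificity, and rank-based (Mann–Whitney, midrank-tied) AUC
over the pooled held-out scores; constant scores yield AUC 0.5 with a
warning.  The aggregate row is the arithmetic mean of the four rows.

## Synthetic cohorts

Defaults mirror the study conditions: 23 low / 6 high athletes and 648
attributes across five themes (5% demographics, 15% physiology, 15%
psychosocial, 25% sport history, 40% practice microstructure).  Per dtype:
anthropometric attributes are standard-normal deviations from age/sex norms;
Likert scale scores are clipped latent normals on [1, 7]; training histories
are zero-inflated log-normal hours/week (40% structural zeros); practice
proportions come from a Dirichlet within each family of four activities so
families sum to 1; demographic counts are Poisson, indicators Bernoulli,
homeplace-population values log-normal.  The missing rate defaults to 0
(the motivating tables imply complete data) and is configurable.

Planted effects make attributes discriminative by construction:
`prevalence_shift` draws each athlete above a latent zero threshold with
group-specific probability — defaults p_high = 5/6 and p_low = 1/23, the
idiomatic strong separation of the motivating discriminator tables —
and `mean_shift` separates group means by a standardised effect size.
`exact=True` fixes exposed counts to round(p·n) for deterministic
contingency patterns.  Non-planted attributes are identically distributed
across groups, so any screening hit on them is a false positive by
construction.  The generator also emits competition records and a normative
reference population constructed so that re-deriving labels through the
percentile-grouping stage reproduces the generated labels exactly, allowing
end-to-end testing of that stage.

What the generator does *not* emulate: correlations between attributes
beyond the planted effects and proportion families, longitudinal
autocorrelation between testing points, and any realistic covariance
between themes.  Passing recovery tests therefore demonstrates that the
pipeline finds strong marginal effects among independent nuisance
attributes — not that it untangles correlated real-world profiles.

## Numerical choices and problem sizes

* Fisher two-sided tail collects tables with probability ≤ observed ×
  (1 + 1e−7), the standard relative-slack convention.
* Threshold ties code 0; grid spacing is exact `linspace`, so the first and
  last grid points equal the observed extrema.
* Degenerate inputs: constant attributes are flagged and skipped by the
  grid (all thresholds equal); single-class label vectors raise for
  classification and warn for ranking; constant scores give AUC 0.5.
* Replicate-based properties in the test suite run at the study scale —
  648 attributes, 100 replicate cohorts for recovery, 500 for the
  type-I-error property — and complete in well under a minute each thanks
  to the vectorised scorers and the cached hypergeometric tables.

## Known limitations

* The exact conditional CI does not correspond to the small-adjusted point
  estimate; intervals are contextual, not inferential anchors.
* Single-feature wrapper ranking ignores feature interactions; a genuinely
  multivariate selection could choose different consensus sets.
* With k = 1 nearest-neighbour, predicted "probabilities" are 0/1, which
  coarsens that classifier's ROC curve.
* The importance grade of protective rules depends on the availability of
  cell counts (see above).
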