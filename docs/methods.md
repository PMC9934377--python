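# Methods

## Scoring model

The scorer is a Naive-Bayes-style additive model over binary ever-coded
features. Feature *i*'s partial risk score is the natural-log odds ratio
of its lifetime (pre-censoring) prevalence in cases versus controls,
estimated from distinct-patient counts in the training arm. The model
assumes conditional independence of features given case status; the sum
of PRS values is then the log posterior odds up to an additive constant
(the class prior), which shifts every patient's score equally and
therefore cancels in percentile thresholding, ranking, and ROC analysis.
The class prior/intercept is accordingly omitted.

Interactions between features are deliberately not modeled; correlated
features (e.g. a diagnosis and its usual medication) double-count, which
is a known and accepted property of this model family.

### Counting conventions

- Counts are patients, never events: a code recurring 40 times in one
  chart contributes exactly what a single occurrence does.
- Natural log. The base rescales all scores and cutoffs jointly and is
  irrelevant to classification; natural log keeps scores interpretable
  as log odds ratios.
- Zero cells: the Haldane–Anscombe correction adds 0.5 to **all four**
  cells, applied only when some cell is zero. Tables without zero cells
  are computed exactly, so published-style OR tables reproduce exactly
  while every fitted score stays finite. Smoothed features are flagged.
- Degenerate all-carrier features (e.g. the marker code in a pure marker
  cohort, where both "without" cells are zero) smooth to an extreme OR
  whose value depends only on the cohort sizes. This is harmless: a
  feature carried by everyone adds a constant to every score and cannot
  affect classification, thresholds, or AUC. It is left in the model
  table (flagged `smoothed`) rather than silently dropped.

### Threshold calibration

The cutoff for a benchmark specificity q is the smallest observed
training-control score s such that the fraction of control scores
strictly above s is at most 1 − q; classification is positive iff
score > cutoff. On tie-free scores the achieved training specificity
lies in [q, q + 1/n]; under ties it is guaranteed to be ≥ q (never
below benchmark). Cutoffs are non-decreasing in q by construction. At
least 20 control scores are required.

## Prospective replay

Validation replays each held-out patient chronologically at day
resolution. All variables first occurring on the same day are aggregated
before the day's cumulative value Risk_t is emitted, making trajectories
invariant to within-day record ordering. Each distinct variable
contributes once, at its first occurrence; variables outside the learned
vocabulary contribute zero but keep their date in the trajectory log.
The overall risk score is the running maximum; an empty record scores 0
by convention (cases with empty pre-event records are excluded upstream,
so this affects only controls, for whom 0 is the natural "no evidence"
score). Demographic features are treated as known from the first visit
onward, since the replay needs a date for every scored variable;
continuous age enters as per-decade categories evaluated at the first
visit.

AUC is computed in the rank (Mann–Whitney) form with midranks, i.e.
exactly P(case score > control score) + ½P(tie). Metric panels report
both exact metrics and an integer-percent variant in which the
likelihood ratios are recomputed from the rounded percentages — the
arithmetic convention of printed clinical summary tables (e.g. counts
TP 19 / TN 6757 / FP 751 / FN 33 give exact LR+ 3.65 but
integer-percent LR+ 37/10 = 3.70). Lead times average
(event date − first crossing date)/365.25 over detected cases only, with
a normal-approximation 95% CI — there is no standard convention for a
lead-time CI, and the normal approximation is the default a
biostatistician would reach for at these n.

## Synthetic cohort generator

The generator emulates a registry extract: per-patient gamma-distributed
follow-up (default mean 8.4 y, SD 4 y), Poisson background coding at
`events_per_year` (default 10/y) over a mixed DX/RX/LAB noise-code pool,
planted risk codes as independent Bernoulli ever-coded indicators, and a
demographics table (73% women, matching the motivating subpopulation's
sex ratio). Case status is a per-patient Bernoulli draw from a logistic
model whose linear predictor sums the true log-OR effects of the
patient's planted indicators — subpopulation-specific effects contribute
only for marker carriers — with the intercept solved numerically
(Brent's method) so the realized mean case probability equals the target
prevalence (default 1.3%). A logistic model over ever-coded indicators
is the generative family matched to the prevalence-based scorer, so
fitted PRS estimates the planted log-OR directly; a hazard/longitudinal
mechanism would be more realistic but would put the true marginal ORs
out of closed-form reach.

Event dating: one calendar epoch, whole days, every patient starting at
day 0. Case events are placed uniformly in the second half of follow-up
so pre-event history exists; all other case events are dated strictly
before the event, so the generated record already respects censoring.
Two toggles deliberately break that truncation to exercise the cohort
filters: `no_history_case_frac` forces a fraction of cases' events onto
day 0 with the record continuing afterwards (so the documentation filter,
not the visit filter, excludes them), and `marker_after_event_frac`
dates the subpopulation marker after the event (a marker diagnosis keeps
being recorded in real registries regardless of the outcome event). Both
default to 0, under which no case has any event after its event date.

What the generator does *not* emulate: a real code ontology and its
correlation structure (codes are independent given case status), visit
and encounter structure, time-varying coding rates, and the empirical
correlation between case status and longer follow-up (the latter can be
induced via config but is off by default). Consequently, passing tests
show that the pipeline's machinery is correct and that planted effects
are recovered under the stated conditions — not that any particular AUC
is attainable on real registry data, where performance depends on the
richness of truly informative codes.

### Parameter recovery and fixture scales

The recovery checks plant moderate effects (|log-OR| ≤ 1.5) at base
rates 0.10–0.30 and verify, at n = 50,000 and ~1.3% prevalence, that the
exact 2×2 truth oracle and the full extract-and-fit path both land
within ±0.2 of truth. Two numerical facts set these scales: the
sampling SE of a log odds ratio is dominated by 1/(case carriers), about
0.08 at 650 cases, and strong effects show visible non-collapsibility —
the *marginal* 2×2 OR of one code is attenuated relative to its
conditional (planted) value once other strong independent causes exist,
by roughly 0.05–0.1 log units at planted log-OR 2 under these
conditions. Moderate effects keep both inside the band with margin.

## Three-arm training-set comparison

Arm A trains on the subpopulation's training half, arm B on a uniform
random general-cohort sample of exactly |A| patients (excluding the
subpopulation validation half; by default subpopulation *training*
patients may appear at their natural rate, since they are a small share
of the general pool — a flag excludes them entirely), and arm C on the
full general cohort minus the validation half. All three are scored on
the identical subpopulation validation half. The experiment's conditions
are desk-scaled: a general cohort of 60,000 with an 8% subpopulation and
ten subpopulation-specific codes at log-OR 1.5, repeated over 20 seeds
with the split seed tied to the simulation seed. The product is the
qualitative ordering — median AUC(A) > median AUC(B), with arm C
recovering via sheer size — not any particular AUC value, which on
synthetic data depends mostly on how much planted signal the config
contains.

The dual-cohort OR table computes each feature's OR separately in the
subpopulation and the general cohort and Z-scales (sample SD) within
each cohort over the caller-supplied displayed feature set, because raw
OR scales differ systematically between cohorts of very different size.
Z-scaling takes the feature set as an explicit input rather than fixing
a universe. The optional between-cohort p-value is a chi-square test on
the 2×2 table of case carriers across cohorts; the choice of test is a
convention, flagged as such, and no downstream logic depends on it.

## Other design choices

- Code dialect: ICD-9-style codes are normalized by stripping dots
  before prefix matching, so `E950.0` and `E9500` are the same code and
  `965.*` matches both dialects.
- A "visit" is a distinct patient-date with at least one coded event —
  the most conservative reconstruction available from a coded-event
  table. The 30-day span criterion is inclusive.
- The age criterion uses event year − birth year (birth dates are not
  modeled below year resolution) and fails closed on a missing birth
  year.
- Same-day marker/event ties are retained as cases; the train/test split
  is unstratified by default (a flag enables stratification for
  synthetic experiments) and halves differ by at most one patient.
- Vocabulary floor `min_count` = 5 training patients: below that,
  odds ratios are dominated by the smoothing constant.
- Determinism: every stochastic step draws from a `numpy` generator
  seeded from the config, and generated tables are fully sorted, so a
  fixed config reproduces every table byte-for-byte.

## Known limitations

- The scorer ignores feature interactions and repeated coding intensity
  (a `count_repeats`-style sensitivity analysis would need event counts,
  which extraction discards by design).
- Ever-coded features make early and late mentions equally informative;
  there is no recency weighting.
- The synthetic validation AUCs are properties of the planted
  configurations, not estimates of real-world performance.
- The generator's independence assumptions understate both the
  redundancy and the richness of real coded vocabularies.
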