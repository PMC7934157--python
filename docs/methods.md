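# Methods

## The preference-elicitation problem

The package analyses questionnaires administered to people with
locked-in syndrome (LIS), split by aetiology into a progressive
neuromuscular-disease group (NMD, e.g. ALS) and a sudden-onset group
(SO, e.g. brain-stem stroke). Respondents rank six candidate cBCI
applications completely and the top four of eight mental control
strategies, rate each strategy on clarity, difficulty, and enjoyability
(Likert 1–5), report which of five residual-movement categories they
retain, and state their willingness to consider a cBCI (1–5).

## COM score

Rank-to-weight encoding gives the j-th ranked item weight K − j + 1
(K = 6 for applications, K = 4 for strategies) and unranked items 0.
The COM score of an item is the mean weight it receives over the T
respondents who answered the question; respondents who skip a ranking
question are excluded from T *for that question only*, which keeps
COM within [0, K] and makes Σ COM equal the mean distributed weight.
With no skips Σ COM = K(K+1)/2 exactly (21 / 10) — a conservation law
the tests enforce on every generated cohort. COM is computed by the
count-based formula (sum over weight values k of k times the number of
respondents assigning k, divided by T); its exact equality with the
direct per-item mean weight is verified exhaustively on small cohorts.

Strict total orders are required at ingest; the weight scheme has no
tie semantics.

## Monte Carlo chance calibration

Each COM value is a single number per item, so differences are
calibrated against a randomization null: every simulated respondent's
weight multiset {K, …, 1} ∪ {0, …} is permuted uniformly across the N
items, independently per respondent, 1000 replicates by default. This
reading — re-assigning the scores a respondent hands out, preserving
the top-K structure — keeps the null on the same scale as the data.
The chance SD pools the replicate-by-item COM values, since all items
are exchangeable under this null and pooling maximizes the effective
sample at 1000 replicates. A COM difference is flagged *meaningful*
iff it strictly exceeds the chance SD (strict ">", so a difference
exactly at the threshold is not flagged). The rule applies both to
item-vs-item comparisons within a cohort and to the NMD-vs-SO
comparison of a single item; no multiplicity correction is applied,
matching standard practice for this descriptive rule.

Under this null the weight a fixed item receives is an i.i.d. uniform
draw from the multiset across respondents, so the chance SD converges
to `sqrt(Var(multiset)/T)`: 0.2795 for strategies at T = 28 (Monte
Carlo ≈ 0.28) and 0.3227 for applications at T = 28 (≈ 0.32). The
calibration takes T explicitly, so callers can use the pooled T or a
per-group T; the pipeline uses the pooled non-skipped T per item set.
Calibration seeds are logged in the emitted JSON.

## Supporting statistics

* **Wilcoxon rank-sum** (unpaired): midranks for ties; z is the first
  group's rank sum standardized by the tie-corrected null moments;
  continuity correction off by default (toggleable) since the reported
  convention does not use one. For combined n ≤ 12 the two-sided p is
  exact, by enumerating all C(n, n_a) assignments of the pooled ranks.
  The normal approximation is *poor* at very small or very unbalanced
  n: exhaustive enumeration shows |p_normal − p_exact| up to 0.68
  without continuity correction (n = 2) and 0.13 with it (group sizes
  1 vs 3); it drops below 0.05 only when both groups have ≥ 3
  observations and the correction is on. Hence the exact method is the
  default whenever it is affordable.
* **Residual movements** are counted over the five fixed categories
  (0–5). **Willingness regression** is OLS of the 1–5 willingness score
  on that count, per group, reporting slope, intercept, r² (equal to
  the squared sample correlation) and the slope's standard error.
  Willingness is deliberately treated as numeric, not ordinal, for
  fidelity to common reporting practice. A constant predictor raises a
  typed error rather than returning NaN.
* **Descriptives**: frequencies and integer percentages (rounded half
  away from zero, so 72.5% → 73%), medians and ranges, per group and
  overall, as a tidy table.

## Synthetic cohorts

The generator emulates the schema and statistical structure the
analysis assumes, with defaults matching the study conditions: 13 NMD +
15 SO respondents; movement prevalences per group (eyes 100%/100%,
mouth/head 92%/93%, hand/arm 54%/53%, leg/feet/toes 46%/27%, residual
speech 38%/7%); ALSFRS-r and disease-duration distributions centred on
the reported group medians and ranges.

* **Rankings** follow a per-group Plackett–Luce model — items chosen
  sequentially with probability proportional to positive worths,
  truncated at depth K — sampled via the Gumbel-max representation.
  Plackett–Luce is the standard generative model for sequential top-K
  choice; the survey itself publishes no generative model, so the
  default worths are *illustrative*: their ordering mirrors the
  reported group preference orderings (direct communication and private
  writing on top; attempted movements above evoked-potential
  strategies, with the NMD group favouring attempted speech/hand more
  strongly), but the magnitudes are this package's choice.
* **Likert ratings** threshold latent standard normals at cutpoints
  (−1.5, −0.5, 0.5, 1.5), giving a symmetric unimodal 1–5 distribution.
  The three dimensions are drawn independently; inter-dimension
  correlation is deliberately not modelled.
* **Willingness** is a latent linear function of the residual-movement
  count (default intercept 5.0, slope −0.5 per category, Gaussian noise
  SD 1.0) rounded to the nearest integer and clamped to [1, 5]. The
  negative default slope encodes the observed moderate negative
  association; its magnitude is again illustrative.
* **Skips**: each ranking question is independently skipped with
  probability 0.05, mimicking the interview convention that any
  question may be skipped while keeping skips rare.

One RNG stream per cohort is consumed in fixed respondent order, so a
seed reproduces a cohort bit for bit. What passing tests on these
cohorts show is that the *pipeline* recovers the structure it was fed
(worth orderings, latent slopes, null flatness); they cannot show that
real LIS preference data satisfy Plackett–Luce, independence across
questions, or linearity of willingness — no such claim is made.

## Numerical and test-design choices

* Chance-SD estimates use the sample SD (ddof = 1) of the pooled
  replicate-by-item values; reproducibility is guaranteed by an
  explicit seed, and child seeds are derived from the master seed via
  `numpy.random.SeedSequence`.
* Equal-worth flatness: with all worths equal the generated rankings
  follow the permutation null exactly, so per-item COM deviations
  exceed 3 chance SDs with probability ≈ 0.2–0.25% each. Across 6–8
  items per set the chance that *some* item exceeds 3 SDs is ≈ 1–2% per
  cohort, so the test checks the pooled per-(seed, item) exceedance
  rate (< 1% over 100 seeds) and a 4-SD envelope per seed, rather than
  demanding every item stay within 3 SDs in 99% of seeds — the latter
  is miscalibrated once the union over items is accounted for.
* Recovery checks run at sizes where the signal is decisive but cheap:
  worth-ordering recovery on 50 cohorts of n = 1000 with worths
  separated by a factor 1.4; slope recovery on 100 cohorts of n = 200
  (latent slope −0.15, noise SD 0.5, chosen so that clamping and
  rounding bias are negligible relative to the slope's standard error).
* Floating-point output is rounded to 3 decimals in the markdown report
  only; machine-readable CSV/JSON keep full precision. All artifacts
  are timestamp-free so identical configurations produce byte-identical
  bundles.
* An empty contributing cohort (T = 0) is always a typed error, never a
  silent NaN.

## Limitations

* The meaningful-difference rule is a descriptive threshold, not a
  hypothesis test; it controls no error rate and applies no
  multiple-comparison correction.
* The generator does not model correlation between the two ranking
  questions, between Likert dimensions, or between preferences and
  demographics; group differences beyond the configured worths and
  prevalences are absent.
* Willingness-as-numeric OLS ignores the ordinal character of the
  scale; an ordinal model is out of scope by design.
* The exact Wilcoxon enumeration is limited to combined n ≤ 12; beyond
  that the tie-corrected normal approximation is used, whose small-n
  inaccuracy is quantified above.
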