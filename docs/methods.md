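# Methods

This note documents the models, reconstructions and numerical choices
behind `qtgp`, in the order the pipeline runs them.

## Virtual population

The original data — 10,360 records of 63 virtual patients across eight
trial arms (terfenadine alone plus clarithromycin, erythromycin,
itraconazole, ketoconazole, fluconazole, fluoxetine and paroxetine) — was
produced by proprietary PBPK and cardiomyocyte simulators and never
deposited.  What survives is a per-variable six-number summary (min, Q25,
median, mean, Q75, max) of the 48 covariates and the dQTc output.  The
generator therefore emulates **marginals only**:

* Continuous covariates are drawn from the piecewise-linear inverse CDF
  through the five quantile knots at cumulative probabilities
  (0, .25, .5, .75, 1).  This matches all five knots exactly in
  distribution and confines every draw to the observed range.  The
  printed *mean* is matched only approximately; where mean and quantiles
  disagree the quantiles win, because they define the inverse CDF.
* Seven cytochrome-isoform columns are identically zero in the summary
  and are generated as constants.
* The sex code is Bernoulli with success probability equal to the printed
  mean (0.7718).
* The published Gut_CYP2C9 row is internally inconsistent (its printed
  minimum, 8210, exceeds its printed Q25, 1430 — the values cannot all be
  order statistics of one distribution, presumably a transcription slip
  in the source table).  `load_reference_specs` returns the row verbatim;
  `build_sampler` rejects non-monotone knots unless asked to apply the
  minimal repair (sorting the five knots), which the population generator
  does for this single row.

Joint structure is not published and is not invented: covariates are
sampled independently by default.  A Gaussian-copula hook accepts a
user-supplied Spearman rank-correlation matrix for experiments that need
dependence (e.g. anthropometric consistency between weight, height and
BSA, which the default does **not** enforce).  Within-patient repeated
measures are likewise exchangeable: records carry patient and arm labels
from a deterministic near-equal allocation (floor division with the
remainder to the lowest ids), since no per-patient breakdown was
published.  Per-arm multiplicative shift factors on the four inhibition
columns are available but default to 1, as per-drug inhibition
distributions are also unpublished.

The dQTc output is either drawn from its own marginal ("marginal" mode)
or computed from the sampled covariates by the white-box equation
("mechanistic" mode).  Mechanistic mode makes the table a perfect oracle
for the downstream machinery — cross-validating the generating equation
itself must give zero error, which the tests assert.  Consequences for
interpretation: passing tests show the pipeline's arithmetic is right and
well-calibrated to the published marginals; they cannot certify behaviour
on the true joint distribution, which no one can reconstruct.

## Preprocessing

* **Noise replicas**: every numeric cell x is replaced by x·(1+u),
  u ~ Uniform(−0.05, +0.05) independently per cell, producing two replicas
  per record.  "±5% amplitude" is read as a bounded multiplicative band:
  it preserves zero-valued covariates and caps the relative perturbation
  exactly at the stated amplitude.  Both inputs and the output are noised
  by default (a flag exempts the output).  The noised set is used for
  stability *testing* by default, not training augmentation.
* **Scaling**: affine map per variable, scaled = 0.1 + 0.8·(x − min)/(max
  − min), with min/max taken from the published summary (reproducible and
  sample-independent) rather than per-fold empirical bounds (available as
  an option).  Out-of-range inputs extrapolate linearly — required by the
  channel comparison, which sweeps ICaL inhibition past its observed
  maximum of 0.5217.  Constant-zero variables pass through.
* **Folds**: leave-one-inhibitor-out — eight folds keyed by arm label
  (hence invariant to row order), each testing on every record of one arm.
  Group counts other than eight are rejected unless explicitly allowed.

## Feature ranking

The ranking stage defines the aggregation contract of a multi-learner
screen and ships one model-agnostic estimator (permutation importance:
mean metric increase over repeated column shuffles, negatives clipped to
zero) so it runs self-contained; any number of external learners can
contribute reports.  Each learner's importance vector is normalized to
sum 1 (scale invariance per learner), weighted by the inverse of its
global error (better learners count more; the exact historical weighting
is not printed, inverse-error is this package's choice), summed and
sorted.  The cut-off walks the descending ranking and discards the tail
after the **last** consecutive drop exceeding 5% of the total importance
sum; every qualifying drop also defines a candidate prefix
(`cutoff_candidates`), mirroring how a family of nested input vectors can
be read off one ranking.  An importance-share variant (keep shares ≥
threshold) is available by flag.

## GP engine

Expression trees over {add, mul, neg, sin, protected exp} — exactly the
operator set the white-box equation needs — with indexed constant slots
and node-count complexity capped by a hard size limit in [10, 100].
Protected exp clamps its argument to [−50, 50]; every evaluation is
finite.

Selection follows the age-fitness-complexity Pareto scheme: parents by
Pareto tournament (size 4) on minimizing (training RMSE, complexity,
age), survivors by non-dominated sorting at constant population size
(default 100), one fresh random individual injected per generation so
young lineages always re-enter.  The alternative "archive_tournament"
mode draws parents from population ∪ archive.  Both modes are
approximations of the two historical search heuristics whose internal
defaults were never printed.  The archive keeps all non-dominated
(fitness, complexity, age) individuals, deduplicated by expression.

Every 1000 × population-size fitness evaluations (configurable), the
current elite get their constants randomly reinitialized and refitted and
— when folds are supplied — a grouped cross-validation error, refitting
constants per training fold.  Constant refits use bounded Nelder-Mead
(bounds ±10× the initial magnitudes, or 10× the constant range), seeded
multi-start (default 5 starts), tight tolerances (xatol 1e-10, fatol
1e-12).  Optimizer objective calls are not counted against the evolution
budget; the budget counts fitness evaluations of individuals.  An
optional `terminate_fitness` stops a run early once the archive best
reaches a target training RMSE — useful when a planted target is known to
be exactly representable.

Final-model selection operationalizes the multivariate criterion:
restrict to the archive's (cv_error, complexity, constant-count) Pareto
front, treat candidates within 5% relative of the best cv error as
equivalent, then prefer minimal complexity, then fewest constants.

Desk-scale budgets (2×10⁴–2×10⁵ evaluations) replace the historical 10⁸
cluster-scale steps throughout the analysis scripts and tests; the
planted-target experiments show these budgets suffice for the search
spaces exercised here.

## The white-box equation: parse reconstruction

The equation's printed form lost its parentheses and does not state
whether inputs enter raw or on the ⟨0.1; 0.9⟩ training scale.  Four local
groupings are genuinely ambiguous (the leading sine, the calcium term,
the exponential factor inside the long sine, and whether C3·X11 sits
inside or outside that sine); together with the two input-scale
conventions this gives 48 candidate readings, all implemented.

Candidates are scored against the published behavioural findings: the
IKr/ICaL comparison should be strongly linear (R² > 0.95) with the ICaL
effect roughly twice the IKr effect (|slope| in [1.5, 2.5]), and
predictions should overlap the observed dQTc range (−15.707 to 78.142 ms).
The scaled-input readings fail decisively (canonical grouping: slope
0.064, R² 0.38 — the ICaL response is then a sub-2 ms ripple against the
46.69·X11 IKr term).  The **raw-input** reading with the
operator-precedence grouping sin(X14)·X9 reproduces the findings: slope
2.607, R² 0.995, and its median-record prediction (6.0 ms) sits next to
the observed dQTc median (6.591 ms).  That reading is packaged as
canonical.  Its slope is structural: the ICaL sweep is dominated by
Na·sin(X14) ≈ 140·sin(X14) ms and the IKr sweep by C3·X11 ≈ 46.7·X11 ms,
so the effect ratio is ≈ 122/47 ≈ 2.6 — "roughly twice", though above a
literal 2.5 cap, which is why the channel-ratio check in the acceptance
suite is expected to sit at 2.61.  No candidate reading satisfies all
three behavioural criteria simultaneously.

Response sweeps pin the seven non-swept inputs at the published joint
quantile scenarios Q1–Q5 (raw values, including the slightly
higher-precision Na bounds the scenarios print) and sweep the chosen
input across its observed raw range.  The channel comparison uses raw
medians for the fixed inputs.  Two structural facts are worth noting
when reading the curves: calcium enters only through 2·sin²(X10), so its
sweep can never move dQTc by more than 2 ms; and every INa term carries a
factor of ICaL inhibition, so INa sweeps are exactly flat in scenarios
where ICaL inhibition is zero.

## Evaluation

NRMSE divides the RMSE by the observed dQTc range of the evaluation split
(as the metric's definition states), ×100; an option pins the range to
the published global (−15.707, 78.142) for cross-fold comparability.
Grouped cross-validation reports per-fold NRMSE/R², the pooled NRMSE over
concatenated held-out predictions *and* the mean over folds (the printed
historical summary does not say which pooling was used, so both are
reported), plus the noised-set stability score.  The published headline
figures (8-fold NRMSE 3.97%, R² 0.923) required the original data set and
are not reproducible from marginals; the desk-scale mechanistic-mode runs
land in the same few-percent regime, which is a consistency observation,
not a reproduction.

## Pipeline

One root seed spawns independent per-stage substreams
(`numpy.random.SeedSequence`), so any stage can be re-run in isolation
with identical results; the manifest records the config and a SHA-256
checksum of every artifact, and reruns are checksum-identical.  The
built-in ranking learner in the pipeline is ordinary least squares —
deliberately simple, since on mechanistic data the signal is strong and
the point is the aggregation arithmetic, not the learner.

## Known limitations

* Marginal fidelity only; no joint structure, no within-patient
  correlation, no arm-specific inhibition distributions.
* The canonical equation reading is a reconstruction validated against
  behavioural criteria, not a recovered ground truth; alternates are a
  constructor argument away.
* The GP engine is single-process and desk-scale; no distributed
  execution.
* The historical multi-learner screen (tree ensembles, neural networks,
  spline models) is represented by its aggregation contract plus one
  built-in estimator, not by the original learner zoo.
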