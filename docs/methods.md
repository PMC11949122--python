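# Methods

This note documents the models, conventions and calibration choices behind
`cachetraj`, and what the synthetic experiments do and do not demonstrate.

## Consensus-criteria scoring

The weight-based consensus criteria are applied as printed inequalities,
which leaves boundary conventions to the implementer:

* the thresholds are strict: exactly 5% loss (or exactly 2% at BMI < 20) is
  pre-cachexia, exactly 1% loss is pre-cachexia;
* the pre-cachexia band for BMI < 20 patients is not defined by the
  criteria text; we mirror the 1% lower bound, so 1–2% loss maps to
  pre-cachexia in that branch;
* the longitudinal reference weight is the **fixed** pre-diagnosis maximum
  for every post-diagnosis measurement (a rolling reference is a plausible
  alternative; the fixed reference keeps categories comparable along a
  patient's sequence and matches how the baseline assessment is defined);
* the baseline anchor is the measurement closest in time to diagnosis,
  ties resolved toward the earlier (pre-diagnosis) record;
* BMI enters per measurement, so a patient can cross the BMI-20 boundary
  mid-series;
* Tukey fences use linear-interpolation quantiles (the common statistical
  default).  Fence placement depends on this convention, which is why it is
  pinned by tests.  Outlier flagging applies to baseline percent changes
  only, never to longitudinal sequences.  Flagged patients are excluded
  from the survival comparison entirely so both markers see the same risk
  set.

## Normalized DTW

Only the ordinal category values enter the alignment; timestamps are kept
for characterization but ignored by the distance, which therefore compares
trajectory shapes rather than calendars.  The recursion is the classic
three-direction dynamic program with +inf boundary conditions and no
warping-window constraint, and the terminal cost is divided by the sum of
the two sequence lengths.  The result is treated as a distance (smaller =
more similar) even though it does not satisfy the triangle inequality;
k-medoids and silhouette only require dissimilarities.  Distances are kept
condensed (upper triangle) and materialized to a dense view on demand.

The numba kernel is checked exhaustively against a memoization-free
recursive evaluation over the full space of short ordinal sequences, so
the dynamic program is pinned by an oracle that shares none of its code.

## k-medoids and model selection

PAM with greedy BUILD initialization and strict-improvement SWAP passes.
All ties (initial medoid, equal-gain additions, equal-cost swaps,
equidistant medoids) break toward the lowest index, making every run
deterministic without a seed; a seeded random initialization exists as an
option.  SWAP guarantees a single-swap local optimum, not a global one —
the tests assert local optimality on random instances and exact recovery on
separated block structures.  k is scanned over 2–10 and chosen by maximum
average silhouette width (scikit-learn's implementation; singleton clusters
contribute width 0), ties toward smaller k.  The null clustering reuses the
temporal solution's k rather than re-selecting it, so the ARI compares
partitions of equal granularity.

## Prevalence curves and archetype naming

A patient's category between measurements is the last observed category
(carry-forward); before the first post-diagnosis measurement it is
undefined and the patient is excluded from numerator and denominator.  The
risk set at week w is patients whose overall-survival channel time exceeds
7w days.  Archetype names are assigned post hoc from curve features (late
mean, peak, peak-to-late decline) by greedy best-score matching; the naming
never feeds back into clustering and is only a reporting convenience.

## Survival evaluation

Kaplan–Meier, log-rank and Cox fits delegate to lifelines; Cox uses the
Efron approximation for ties (day-resolution times make ties likely).  The
IPCW time-dependent AUC is the cumulative/dynamic variant: cases are
subjects with an event by the horizon, weighted 1/G(T⁻); controls are
subjects still event-free and under observation at the horizon, weighted
1/G(t), with G the Kaplan–Meier estimator of the censoring distribution.
G is evaluated with a left limit at case event times, avoiding the zero
weight a case would otherwise receive at its own censoring-curve jump; G is
floored at its smallest positive value so weights stay finite past the last
censoring time.  Binary markers are handled with half credit for ties.
With no censoring the estimator reduces *exactly* to the unweighted
case/control concordance, which the tests require to 1e-12.  Confidence
bands and the two-marker comparison use seeded patient-level percentile
bootstrap (default B = 500); the AUC grid runs at monthly intervals
(365.25/12 days) from month 1 to the floor of the median overall survival.

## Synthetic cohort: what it emulates

Each patient draws a latent archetype; weight follows a piecewise-linear
fractional trajectory (flat until onset, constant-rate loss to a nadir,
optional constant-rate regain capped at the reference) with multiplicative
lognormal noise.  Encounters are a homogeneous Poisson process (default 30
per follow-up year, emulating a densely measured oncology cohort) plus a
guaranteed diagnosis-day measurement; pre-diagnosis encounters run at one
fifth of that rate, reflecting how much sparser contact is before an
oncologic diagnosis.  Events, loss to follow-up and the administrative
horizon are competing exponential clocks; the disability-free and
hospitalization-free channels are independent clocks with hazard
multipliers 1.3 and 3.0, censored at death.  BMI is weight/height² with
height fixed at baseline; 5% of patients are assigned baseline BMI < 20 to
exercise the tightened threshold branch.

Default archetype parameters (onset, rates, nadir) are **calibration
choices**, not literature facts: the shapes target the three canonical
prevalence morphologies, and the hazards (0.80, 0.115, 0.20 per year for
persistent, smouldering, rapid-recovery) target median survivals of
roughly 0.9, 6 and 3.5 years.  Negative onsets for the persistent and
rapid-recovery archetypes give them pre-diagnosis weight loss, which makes
the baseline category a *noisy* correlate of the archetype — with the
rapid-recovery group showing the deepest loss at diagnosis, so a single
baseline measurement actively misranks the best-prognosis group.  That
structure is what makes the temporal-vs-baseline comparison informative
rather than rigged: the baseline marker is weak because of the data's
geometry, not because it is handicapped.

One subtle interaction is worth knowing: because the reference weight is
the *maximum* of noisy pre-diagnosis measurements, measured percent loss is
inflated by roughly the expected maximum of the noise draws.  With 1%
noise and dense pre-diagnosis sampling this bias exceeds the 1%
pre-cachexia boundary and blurs recovered patients into the smouldering
band; the defaults (noise sd 0.003, sparse pre-diagnosis sampling) keep the
bias below the boundary.  Real EHR scales are noisier than this, so the
archetype-recovery results characterize favourable, well-separated
conditions — they show the pipeline recovers structure that is present,
not that such structure is recoverable at arbitrary noise levels.

What the generator does **not** model: treatment-induced weight gain
(e.g., corticosteroids), covariate-dependent measurement intensity,
informative censoring, within-patient hazard change over time, or
correlation between the three endpoint channels beyond shared censoring.
Passing tests therefore say nothing about those phenomena.

## Problem sizes and numerical choices

The default cohort is 600 patients (mixture 40/25/35%), giving ~590
analyzable series and a ~590×590 distance matrix; the DTW and PAM kernels
are numba-compiled, so a full pipeline run takes a few seconds.  The
archetype-recovery experiment uses 20 cohorts (seeds 1–20); being fully
deterministic given seeds, its outcome is reproducible exactly.  Times are
integer days relative to diagnosis throughout, converted to years (365.25
d/yr) or months (365.25/12 d) only for reporting.  Distance-matrix files
round-trip through text at 17 significant digits.

## Known limitations

* The pairwise DTW stage is O(n² · L²) and, like any exact DTW pipeline,
  will not scale to very large cohorts without lower-bounding or
  subsampling (deliberately out of scope).
* PAM can return a non-global local optimum on unstructured distance
  matrices.
* The archetype-naming heuristic assumes at most one cluster per canonical
  shape; with k > 3 the extra clusters are left unlabeled.
* The silhouette-based k selection inherits silhouette's bias toward
  compact, balanced clusters; small genuine subgroups (e.g., underweight
  patients whose tightened threshold shifts their whole sequence) can tip
  the choice to k = 4.
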