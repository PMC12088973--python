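# Methods

## The model

The package treats an individual's yearly health profile as a binary vector
σ ∈ {0,1}⁶ over six checkup features (default order, most significant bit
first: HbA1c, PG, HDL-C, BMI, UA, ALT). The population distribution over the
64 patterns is modeled as a pairwise maximum-entropy (Ising) model

    P(σ) = exp(−E(σ)) / Z,   E(σ) = −Σᵢ hᵢσᵢ − Σ_{i<j} Jᵢⱼ σᵢ σⱼ,

the unique least-structured distribution matching the empirical
single-feature activation rates and pairwise co-activation rates. The
energy is a virtual quantity: lower energy means a more frequent pattern.
Stable health states are the basins of attraction of local energy minima on
the 6-cube (Hamming-distance-1 neighborhood), and the difficulty of moving
between states is summarized by minimax energy barriers.

Two codings are supported. The default `01` coding works directly on the
0/1 patterns; the alternative `spin` coding maps bits to ±1. They are
reparametrizations of the same distribution family, so all correctness
tests compare probabilities rather than parameters.

## Fitting

The log-likelihood gradient with respect to (h, J) is the difference
between empirical and model moments, and with only 64 states the model
moments are computed exactly by enumeration. Fitting is plain gradient
ascent: learning rate 0.1, convergence when every gradient component is
below 1e−6 in magnitude, hard cap 100 000 iterations. The convergence
criterion *is* the moment-matching certificate: at termination the model's
means and co-activations match the data within the tolerance, a property
the tests verify independently of the optimizer. A column observed in only
one state makes the maximum-likelihood bias diverge; the fit refuses such
input with an error suggesting regularization rather than silently
returning a boundary estimate.

Tighter tolerances (e.g. 1e−8) are available through the `tol` argument;
the infinite-sample recovery test uses one to confirm that fitting a known
model's exact distribution returns its probabilities to ~1e−6.

## Binarization

Thresholds are per-feature sample medians over the pooled records of the
analysis subset, recomputed for every subset analyzed (a sub-cohort re-run
gets its own medians). For even sample sizes the median is the midpoint of
the two central order statistics. Values ≤ threshold map to 0 (good) except
HDL-C, where the assignment is reversed because low HDL-C is the unhealthy
condition. A value exactly at the threshold is therefore always "good"
(bit 0; bit 1 for HDL-C). Patterns are indexed big-endian so `010111` → 23.

## Basins and barriers

Each pattern's descent edge points to its best Hamming-1 neighbor under the
lexicographic order (energy, pattern index); a pattern with no better
neighbor under that order is a local minimum. This resolves plateau ties
deterministically toward the lower index and reduces to plain steepest
descent whenever energies are distinct (the generic case for a fitted
model). States are labeled 1..K by ascending local-minimum index.

Barriers are computed by a threshold sweep: patterns are activated in
increasing (energy, index) order into a union-find structure, each new
pattern merging with active neighbors; the activation energy at which two
minima's components first meet equals the minimax path value between them.
The modified disconnectivity graph restricts activation to an allowed
pattern set (typically the patterns of the two states being compared);
restriction can only raise barriers, and a pair left disconnected is
reported as +inf. Both the basin decomposition and the barriers are checked
in the test suite against independent brute-force oracles (greedy descent;
sub-level-set BFS connectivity) on 100 random landscapes.

## Cohort processing choices

- Onset year: earliest year any diagnostic condition holds; within a year
  the conditions are checked in the order fasting-lab, non-fasting-lab,
  history flag, treatment flag. A questionnaire flag that toggles back to
  false later does not undo an earlier onset.
- Obesity: BMI at the earliest record with a non-missing BMI; the first
  measurement governs permanently.
- Feature exclusion: missingness fractions are computed over the records
  present at that step, which makes the filter idempotent; HbA1c is exempt
  from the 30% missingness cutoff as a clinically essential feature.
- Step-3 exclusions are counted once per record under the first matching
  criterion (non-fasting, then at/after onset, then incomplete), so the
  report's counts add up exactly to the records removed.
- Feature ranking: a 500-tree random forest (impurity importance, fixed
  seed) predicts whether onset occurs within three years of a record,
  with "within three years" meaning onset_year − record_year ∈ [1, 3] —
  filtered records are strictly pre-onset, so 0 cannot occur. Importance
  rankings are seed-dependent; the tests assert a planted signal wins by
  majority over seeds rather than at every seed.
- The pathway-preference test is Pearson's chi-squared with Yates
  continuity correction (df = 1). Pre-transition comparisons use the
  two-sided Mann-Whitney U with scipy's automatic exact/asymptotic method
  switch, summarized as mean ± sample SD (n−1). No multiple-testing
  adjustment is applied to the per-feature comparison table; its p-values
  are per-feature and should be read as descriptive.

## The synthetic generator

`CohortSpec` defines the study conditions: by default 600 individuals,
yearly visits 2012–2020 attended with probability 0.85, 30% females, 30%
obese, three latent health states (healthy / intermediate / unhealthy)
following a persistent yearly Markov chain, conditionally independent
Gaussian features given the latent state (with means and SDs on published
clinical scales for a male checkup cohort), missing-completely-at-random
cells (HbA1c at rate 0.37, reflecting its dominant missingness in real
panels), fasting with probability 0.9, and a diabetes hazard of 0.12 per
year confined to the unhealthy state. Obese individuals get a +4 kg/m²
BMI shift (+10 cm waist) and start tilted toward the intermediate state.
After onset, the questionnaire flags stay set, so the diagnosis stage can
recover onset from records alone; because the hazard is confined to the
designated high-risk state, no onset precedes the first entry into it.

What the generator does **not** emulate: within-individual feature
autocorrelation beyond what the shared latent state induces, medication and
treatment effects, seasonal patterns, female-specific physiology,
informative missingness, and measurement error structure. Passing tests on
synthetic cohorts therefore certify the pipeline's algorithmic correctness
and bookkeeping, not the clinical realism of any particular landscape.

## Numerical and size choices

- All 64-pattern computations are exact enumerations; no sampling enters
  the fit itself.
- The exact Ising sampler draws categorically from the enumerated
  distribution, giving i.i.d. samples suitable for round-trip tests
  (recovery within 3 binomial standard errors at n = 10⁵).
- Integration tests run cohorts of 150–600 individuals; the acceptance
  script uses the default 600-individual cohort and a 10⁵-sample
  round-trip, sizes at which every statistical check has comfortable power
  while a full run stays in seconds.
- Determinism: every stochastic component (generator, sampler, random
  forest) takes an explicit seed; re-running a pipeline with the same seed
  reproduces byte-identical CSV/JSON artifacts.

## Known limitations

- Six features are a hard design point: the landscape degrades in
  reliability as the pattern space grows, so the package does not support
  larger feature sets.
- Basin structure of a *fitted* landscape is a statistic of the model, not
  of the raw data; small cohorts can produce two-state or four-state
  landscapes from the same generating process depending on sampling noise.
- The transition counts condition on consecutive-year attendance; visit
  patterns correlated with health would bias them, and the generator's
  missed visits are independent by design.
- The preference test treats transitions as independent events although one
  individual can contribute several; this matches the method's standard
  usage but overstates effective sample size when sequences are long.
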