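# checkup-ela

Energy landscape analysis (ELA) of longitudinal health-checkup data, aimed at
mapping the pathways from a healthy state through pre-disease states toward
diabetes onset. The package takes yearly checkup records (one row per
individual-year: sex, fasting flag, diabetes-questionnaire answers, and a
panel of clinical features such as BMI, plasma glucose and HbA1c), labels
diabetes onset and obesity, filters the records, and characterizes the
cohort's health dynamics as movement on a discrete energy landscape.

It is written for epidemiologists and biostatisticians working with
workplace-checkup-style panels; because such data are usually
access-restricted, the package ships a synthetic cohort generator with known
ground truth so that every stage is testable end to end.

## The method

1. **Labeling and filtering.** Diabetes onset is the earliest year meeting
   any of: fasting PG ≥ 126 mg/dL with HbA1c ≥ 6.5%; non-fasting
   PG ≥ 200 mg/dL with HbA1c ≥ 6.5%; a self-reported diabetes history; or
   self-reported diabetes treatment. Obesity is BMI ≥ 25 kg/m² at the first
   measurement. Records are filtered in steps: unsuitable feature columns
   (height, weight, categoricals, >30% missing except HbA1c), females,
   non-fasting records, records at or after onset, incomplete records, and
   emptied-out individuals. A random forest predicting onset within three
   years ranks the remaining features; the top five plus HbA1c enter the
   landscape.

2. **Binarization.** Each of the 6 selected features is converted to a bit:
   value ≤ its sample median → 0 (good), otherwise 1 (bad); for HDL-C, where
   low is unhealthy, the assignment is reversed. A record becomes one of
   2⁶ = 64 binary patterns, indexed big-endian (pattern `010111` → 23).

3. **Pairwise maximum-entropy model.** The pattern distribution is modeled
   as P(σ) = exp(−E(σ))/Z with E(σ) = −Σᵢ hᵢσᵢ − Σ_{i<j} Jᵢⱼσᵢσⱼ — the
   least-structured distribution matching the observed single-feature means
   and pairwise co-activations. Fitting is exact-gradient ascent over the
   64 enumerated patterns; at convergence the moment-matching residual
   doubles as a correctness certificate.

4. **Basins and barriers.** Each pattern points to its lowest-energy
   one-bit neighbor; the connected components of this basin graph are the
   *states*, each anchored at a local-minimum pattern. The disconnectivity
   graph gives, for every pair of minima, the minimax energy barrier (the
   lowest maximum energy any one-bit path must cross), computed by an
   energy-ordered union-find sweep; a *modified* variant restricts paths to
   the two states being compared.

5. **Transition statistics.** State transitions are counted over pairs of
   visits in consecutive calendar years (gaps of ≥ 2 years are skipped,
   self-transitions included), optionally stratified by obesity, with a
   Yates-corrected chi-squared test for pathway preference between groups
   and Mann-Whitney comparisons of feature values in the year before each
   transition type.

## Worked example

```python
from checkup_ela import CohortSpec, RunConfig, generate_cohort, run_full_analysis

cohort = generate_cohort(CohortSpec(n_individuals=600, seed=1))   # 4595 records
art = run_full_analysis(RunConfig(output_dir="results/demo", seed=1), cohort.records)

print(art.filter_report.final_records)   # 1493 records from 389 individuals survive
print(art.thresholds.values)             # e.g. HbA1c 5.43 %, PG 90.4 mg/dL, BMI 24.7
print(art.basins.n_states)               # 4 states, local minima [0, 15, 48, 63]
print(art.transition_counts)
```

On this synthetic cohort the landscape splits into 4 states whose minima are
patterns 0 (all features good), 15, 48, and 63 (all bad); the transition
matrix shows heavy self-transitions (134 in state 1, 114 in state 4) with
asymmetric flow toward the unhealthy state. The same run writes
`thresholds.json`, `model.json`, `landscape.csv`, `barriers.csv`, transition
CSVs, a pre-transition comparison table, basin/disconnectivity figures and a
manifest into the output directory.

The pathway-preference test reproduces a published benchmark: for group
counts 78/191 (obese, indirect/direct pathway) versus 210/782 (non-obese),

```python
from checkup_ela import preference_test
preference_test([[78, 191], [210, 782]])
# chi2 = 6.919, dof = 1, p = 0.0085
```

## Command line

```bash
checkup-ela simulate --seed 1 --out data/
checkup-ela prepare --in data/cohort.csv --out data/filtered.csv --report data/report.json
checkup-ela run-all --in data/cohort.csv --seed 1 --out results/
```

Subcommands `ela`, `transitions`, and `compare` run individual stages;
`ela --restrict-states a,b` adds the modified disconnectivity barriers.

## Layout

- `src/checkup_ela/synthetic.py` — cohort generator and exact Ising sampler
- `src/checkup_ela/cohort.py` — diagnosis, obesity, filters, feature ranking
- `src/checkup_ela/ela.py` — binarization, model fit, basins, barriers
- `src/checkup_ela/transitions.py` — transition counting and preference test
- `src/checkup_ela/pretransition.py` — pre-transition feature comparisons
- `src/checkup_ela/report.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for modeling assumptions, parameter choices, and
limitations.
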