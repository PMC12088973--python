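"""Synthetic longitudinal checkup cohorts with known ground truth.

Real Specific-Health-Checkup data are access-restricted, so every stage of
the pipeline is exercised against cohorts generated here. Each individual
follows a latent Markov chain over health states across calendar years;
feature values are conditionally independent Gaussians given the latent
state (cross-feature correlation enters through the shared state), visits
are missed at random, cells are missing completely at random, and diabetes
onset is a per-year Bernoulli event whose hazard depends on the latent
state. After onset the questionnaire flags stay set, so the downstream
diagnosis can recover the onset from the records alone.

Default feature levels per latent state are seeded from published
pre-transition summary values for a male checkup cohort; they give clinical
scales, not individual-level physiology (see the methods note for what the
generator does and does not emulate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CANDIDATE_FEATURES
from .ela import IsingModel, N_BITS, N_PATTERNS, _PATTERNS

# mean, SD per feature for the three default latent states
# (healthy / intermediate-obese / unhealthy pre-diabetic).
_HEALTHY = {
    "BMI": (23.3, 2.3), "WC": (84.6, 6.7), "SBP": (126.1, 14.6), "DBP": (79.8, 10.6),
    "TG": (122.1, 83.7), "LDL-C": (129.9, 30.3), "HDL-C": (60.5, 12.9),
    "PG": (88.5, 6.3), "HbA1c": (5.37, 0.19), "UA": (6.02, 1.2), "Cre": (0.86, 0.25),
    "AST": (22.7, 7.6), "ALT": (21.2, 9.2), "GGT": (51.5, 52.6),
    "WBC": (6096, 1632), "RBC": (484.6, 37.5), "Hb": (15.0, 1.0), "Ht": (44.7, 2.8),
}
_INTERMEDIATE = {
    "BMI": (25.8, 2.7), "WC": (90.2, 7.6), "SBP": (129.2, 14.9), "DBP": (81.6, 11.3),
    "TG": (162.6, 111.3), "LDL-C": (132.0, 32.1), "HDL-C": (50.9, 11.3),
    "PG": (90.1, 4.4), "HbA1c": (5.47, 0.16), "UA": (6.81, 1.11), "Cre": (0.90, 0.15),
    "AST": (26.8, 9.7), "ALT": (32.8, 16.0), "GGT": (62.6, 53.7),
    "WBC": (6225, 1552), "RBC": (495.8, 37.8), "Hb": (15.4, 1.0), "Ht": (45.5, 2.7),
}
_UNHEALTHY = {
    "BMI": (24.0, 2.4), "WC": (86.0, 7.0), "SBP": (128.0, 15.0), "DBP": (80.5, 10.8),
    "TG": (135.0, 90.0), "LDL-C": (131.0, 31.0), "HDL-C": (55.0, 12.0),
    "PG": (108.0, 9.0), "HbA1c": (6.0, 0.35), "UA": (6.2, 1.2), "Cre": (0.88, 0.18),
    "AST": (24.5, 8.5), "ALT": (26.0, 13.0), "GGT": (58.0, 55.0),
    "WBC": (6150, 1600), "RBC": (488.0, 37.0), "Hb": (15.1, 1.0), "Ht": (45.0, 2.8),
}

DEFAULT_FEATURE_PARAMS = (_HEALTHY, _INTERMEDIATE, _UNHEALTHY)

#: Yearly latent transitions: mostly persistent, with modest worsening flow.
DEFAULT_TRANSITIONS = (
    (0.88, 0.06, 0.06),
    (0.10, 0.74, 0.16),
    (0.05, 0.05, 0.90),
)

#: Missing-completely-at-random cell rates; HbA1c mirrors its dominant
#: missingness in real checkup panels.
DEFAULT_MISSING_RATES = {"HbA1c": 0.37, "WC": 0.05, "LDL-C": 0.03}


@dataclass
class CohortSpec:
    """Generator parameters for a synthetic longitudinal checkup cohort."""

    n_individuals: int = 600
    year_range: tuple[int, int] = (2012, 2020)
    visit_probability: float = 0.85
    obese_fraction: float = 0.30
    female_fraction: float = 0.30
    latent_states: int = 3
    latent_transition_matrix: tuple = DEFAULT_TRANSITIONS
    feature_params: tuple = DEFAULT_FEATURE_PARAMS
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    fasting_probability: float = 0.90
    onset_hazard: tuple = (0.0, 0.0, 0.12)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be an increasing pair")
        for name in ("visit_probability", "obese_fraction", "female_fraction",
                     "fasting_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        K = self.latent_states
        if K < 2:
            raise ValueError("latent_states must be >= 2")
        T = np.asarray(self.latent_transition_matrix, dtype=float)
        if T.shape != (K, K):
            raise ValueError("latent_transition_matrix must be K x K")
        if (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0):
            raise ValueError("latent_transition_matrix rows must be stochastic")
        if len(self.feature_params) != K:
            raise ValueError("feature_params must give one profile per latent state")
        for prof in self.feature_params:
            for f, (_, sd) in prof.items():
                if sd <= 0:
                    raise ValueError(f"feature_params SD for {f!r} must be > 0")
        hz = np.asarray(self.onset_hazard, dtype=float)
        if hz.shape != (K,) or (hz < 0).any() or (hz > 1).any():
            raise ValueError("onset_hazard must be K probabilities in [0, 1]")
        for f, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing_rates[{f!r}] must be in [0, 1]")

    @property
    def high_risk_state(self) -> int:
        return int(np.argmax(self.onset_hazard))


@dataclass
class SyntheticCohort:
    """Generated records plus the latent ground truth behind them."""

    records: pd.DataFrame
    truth: dict  # individual_id -> {"states": {year: k}, "onset_year", "obese", "sex"}


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a cohort under ``spec``; deterministic for a given seed.

    Obese-designated individuals get a +4 kg/m^2 BMI shift (with matched
    waist shift) and start the latent chain tilted toward the intermediate
    state, emulating the obesity-linked pathway; everyone else starts
    healthy. Onset occurs with the per-state annual hazard; from the onset
    year onward the treatment-questionnaire flag is set on every record.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    years = list(range(spec.year_range[0], spec.year_range[1] + 1))
    K = spec.latent_states
    T = np.asarray(spec.latent_transition_matrix, dtype=float)
    features = [f for f in CANDIDATE_FEATURES if f in spec.feature_params[0]]

    rows, truth = [], {}
    for i in range(spec.n_individuals):
        ind = f"S{i:05d}"
        sex = "female" if rng.random() < spec.female_fraction else "male"
        obese = rng.random() < spec.obese_fraction
        height = rng.normal(170.0, 6.0)

        # latent path
        if obese and K >= 2:
            state = int(rng.choice([0, 1], p=[0.4, 0.6]))
        else:
            state = 0
        states, onset_year = {}, None
        for y in years:
            states[y] = state
            if onset_year is None and rng.random() < spec.onset_hazard[state]:
                onset_year = y
            state = int(rng.choice(K, p=T[state]))

        for y in years:
            if rng.random() >= spec.visit_probability:
                continue
            prof = spec.feature_params[states[y]]
            vals = {}
            for f in features:
                mu, sd = prof[f]
                if f == "BMI" and obese:
                    mu += 4.0
                if f == "WC" and obese:
                    mu += 10.0
                v = rng.normal(mu, sd)
                if rng.random() < spec.missing_rates.get(f, 0.0):
                    v = np.nan
                vals[f] = v
            bmi = vals.get("BMI", np.nan)
            weight = bmi * (height / 100.0) ** 2 if not np.isnan(bmi) else np.nan
            diagnosed = onset_year is not None and y >= onset_year
            rows.append({
                "individual_id": ind, "year": y, "sex": sex,
                "fasting": bool(rng.random() < spec.fasting_probability),
                "questionnaire_history": diagnosed,
                "questionnaire_treatment": diagnosed,
                "height": height, "weight": weight,
                "smoker": "yes" if rng.random() < 0.3 else "no",
                **vals,
            })
        truth[ind] = {"states": states, "onset_year": onset_year,
                      "obese": obese, "sex": sex}

    columns = list(
        ("individual_id", "year", "sex", "fasting", "questionnaire_history",
         "questionnaire_treatment", "height", "weight", "smoker")
    ) + features
    records = pd.DataFrame(rows, columns=columns)
    return SyntheticCohort(records, truth)


def sample_from_ising(model: IsingModel, n: int, seed: int) -> np.ndarray:
    """Draw n exact samples (rows of 6 bits) from a pairwise maximum-entropy model.

    The 64-pattern distribution is enumerated exactly and sampled
    categorically, so the draws carry no Monte-Carlo-chain bias.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(N_PATTERNS, size=n, p=model.probabilities())
    return _PATTERNS[idx].astype(int)
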