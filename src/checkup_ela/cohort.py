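"""Cohort construction: diabetes diagnosis, obesity grouping, record filtering,
and random-forest feature ranking for longitudinal checkup data.

A cohort is a tidy table with one row per individual-year:

===========================  =====================================================
column                       meaning
===========================  =====================================================
individual_id                opaque identifier
year                         calendar year of the visit (at most one per year)
sex                          "male" / "female"
fasting                      blood sample drawn fasting
questionnaire_history        self-reported history of diabetes
questionnaire_treatment      self-reported current diabetes treatment
<features>                   numeric measurements in clinical units (may be NaN)
===========================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

#: The 18 candidate features retained after the feature-exclusion step, in
#: conventional panel order. GGT denotes gamma-glutamyl transpeptidase.
CANDIDATE_FEATURES = (
    "BMI", "WC", "SBP", "DBP", "TG", "LDL-C", "HDL-C", "PG", "HbA1c",
    "UA", "Cre", "AST", "ALT", "GGT", "WBC", "RBC", "Hb", "Ht",
)

METADATA_COLUMNS = (
    "individual_id", "year", "sex", "fasting",
    "questionnaire_history", "questionnaire_treatment",
)

#: Fraction of missing values above which a feature is dropped (HbA1c exempt:
#: it is kept as clinically important despite high missingness).
MISSINGNESS_CUTOFF = 0.30
MISSINGNESS_EXEMPT = ("HbA1c",)

#: Diagnostic thresholds: fasting PG >= 126 mg/dL with HbA1c >= 6.5 %, or
#: non-fasting PG >= 200 mg/dL with HbA1c >= 6.5 %.
FASTING_PG_CUTOFF = 126.0
NONFASTING_PG_CUTOFF = 200.0
HBA1C_CUTOFF = 6.5

#: Obesity cutoff on BMI at the first measurement (kg/m^2).
OBESITY_BMI_CUTOFF = 25.0


@dataclass(frozen=True)
class DiagnosisResult:
    """Earliest year an individual meets a diabetes criterion, if any.

    ``triggering_condition``: "a" fasting PG/HbA1c, "b" non-fasting PG/HbA1c,
    "c" questionnaire history, "d" questionnaire treatment.
    """

    individual_id: object
    onset_year: int | None
    triggering_condition: str | None


def _is_true(v) -> bool:
    return bool(v) and not (isinstance(v, float) and np.isnan(v))


def diagnose_diabetes(records_of_individual: pd.DataFrame) -> DiagnosisResult:
    """Apply the four diagnostic conditions year by year; return the first hit.

    Conditions: (a) fasting PG >= 126 and HbA1c >= 6.5; (b) non-fasting
    PG >= 200 and HbA1c >= 6.5; (c) questionnaire reports a diabetes history;
    (d) questionnaire reports diabetes treatment. The earliest qualifying
    year is the onset; within a year, condition letters are checked in order.
    Missing lab values never trigger a condition.
    """
    if len(records_of_individual) == 0:
        raise ValueError("at least one record is required")
    df = records_of_individual.sort_values("year")
    ind = df["individual_id"].iloc[0]
    for _, r in df.iterrows():
        pg, a1c = r.get("PG", np.nan), r.get("HbA1c", np.nan)
        labs_ok = pd.notna(pg) and pd.notna(a1c)
        if labs_ok and r["fasting"] and pg >= FASTING_PG_CUTOFF and a1c >= HBA1C_CUTOFF:
            return DiagnosisResult(ind, int(r["year"]), "a")
        if labs_ok and not r["fasting"] and pg >= NONFASTING_PG_CUTOFF and a1c >= HBA1C_CUTOFF:
            return DiagnosisResult(ind, int(r["year"]), "b")
        if _is_true(r.get("questionnaire_history", False)):
            return DiagnosisResult(ind, int(r["year"]), "c")
        if _is_true(r.get("questionnaire_treatment", False)):
            return DiagnosisResult(ind, int(r["year"]), "d")
    return DiagnosisResult(ind, None, None)


def diagnose_all(records: pd.DataFrame) -> dict:
    """Onset year per individual (None if never diagnosed)."""
    return {
        ind: diagnose_diabetes(g).onset_year
        for ind, g in records.groupby("individual_id", sort=False)
    }


def classify_obesity(records_of_individual: pd.DataFrame) -> str:
    """"obese" if BMI at the earliest measurement is >= 25 kg/m^2, else "non_obese".

    The first measurement governs even if BMI later crosses the cutoff.
    """
    df = records_of_individual.sort_values("year")
    bmi = df["BMI"].dropna()
    if bmi.empty:
        raise ValueError("no non-missing BMI; cannot classify obesity")
    return "obese" if bmi.iloc[0] >= OBESITY_BMI_CUTOFF else "non_obese"


def classify_all_obesity(records: pd.DataFrame) -> dict:
    return {
        ind: classify_obesity(g)
        for ind, g in records.groupby("individual_id", sort=False)
    }


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class CohortFilterReport:
    """Per-step exclusion counts for the record-filtering flow."""

    initial_records: int = 0
    initial_individuals: int = 0
    dropped_features: list = field(default_factory=list)
    retained_features: list = field(default_factory=list)
    female_individuals: int = 0
    female_records: int = 0
    nonfasting_records: int = 0
    post_onset_records: int = 0
    incomplete_records: int = 0
    empty_individuals: int = 0
    final_records: int = 0
    final_individuals: int = 0

    def records_excluded(self) -> int:
        return (self.female_records + self.nonfasting_records
                + self.post_onset_records + self.incomplete_records)


def apply_filters(dataset: pd.DataFrame, onset_map: dict) -> tuple[pd.DataFrame, CohortFilterReport]:
    """The four record-level exclusion steps preceding feature ranking.

    1. Drop unsuitable feature columns: height, weight, categorical (non-
       numeric) variables, and features missing in more than 30% of records
       (HbA1c exempt).
    2. Drop females and all their records.
    3. Drop records that are (a) non-fasting, (b) in or after the
       individual's diabetes-onset year, or (c) missing any retained feature.
       Each record is counted once, under the first matching criterion.
    4. Drop individuals left with no records.

    Missingness fractions are computed over the records present when step 1
    runs, so re-applying the filters to already-filtered data is a no-op.
    """
    rep = CohortFilterReport(
        initial_records=len(dataset),
        initial_individuals=dataset["individual_id"].nunique() if len(dataset) else 0,
    )
    if len(dataset) == 0:
        return dataset.copy(), rep

    # step 1: feature exclusion
    feature_cols = [c for c in dataset.columns if c not in METADATA_COLUMNS]
    dropped = []
    for c in feature_cols:
        if c in ("height", "weight"):
            dropped.append(c)
        elif not pd.api.types.is_numeric_dtype(dataset[c]):
            dropped.append(c)
        elif c not in MISSINGNESS_EXEMPT and dataset[c].isna().mean() > MISSINGNESS_CUTOFF:
            dropped.append(c)
    retained = [c for c in feature_cols if c not in dropped]
    rep.dropped_features = dropped
    rep.retained_features = retained
    df = dataset[list(METADATA_COLUMNS) + retained]

    # step 2: females
    is_female = df["sex"] == "female"
    rep.female_individuals = df.loc[is_female, "individual_id"].nunique()
    rep.female_records = int(is_female.sum())
    df = df[~is_female]

    # step 3: record exclusions, counted under the first matching criterion
    onset = pd.to_numeric(df["individual_id"].map(lambda i: onset_map.get(i)), errors="coerce")
    nonfasting = ~df["fasting"].astype(bool)
    post_onset = df["year"] >= onset  # NaN onset compares False
    incomplete = df[retained].isna().any(axis=1)
    rep.nonfasting_records = int(nonfasting.sum())
    rep.post_onset_records = int((post_onset & ~nonfasting).sum())
    rep.incomplete_records = int((incomplete & ~nonfasting & ~post_onset).sum())
    df = df[~(nonfasting | post_onset | incomplete)]

    # step 4: individuals with nothing left
    rep.empty_individuals = (
        rep.initial_individuals - rep.female_individuals - df["individual_id"].nunique()
    )
    rep.final_records = len(df)
    rep.final_individuals = df["individual_id"].nunique()
    return df.reset_index(drop=True), rep


# ---------------------------------------------------------------------------
# Feature ranking
# ---------------------------------------------------------------------------

def rank_features(
    filtered: pd.DataFrame,
    onset_map: dict,
    seed: int = 0,
    horizon: int = 3,
    n_estimators: int = 500,
    n_top: int = 5,
    forced: tuple[str, ...] = MISSINGNESS_EXEMPT,
) -> tuple[list[str], list[str]]:
    """Rank features by random-forest importance for near-term diabetes onset.

    Each single-year record is labeled positive when the individual's onset
    falls within the following ``horizon`` years (onset_year - record_year in
    [1, horizon]; filtered records are all pre-onset). The candidate set is
    every retained feature except the forced ones (HbA1c), which are excluded
    from ranking but appended to the selection on clinical grounds.

    Returns ``(ranking, selected)`` where ``ranking`` is all candidates in
    decreasing impurity importance and ``selected`` is the top ``n_top``
    plus the forced features.
    """
    candidates = [c for c in filtered.columns
                  if c not in METADATA_COLUMNS and c not in forced]
    onset = pd.to_numeric(filtered["individual_id"].map(lambda i: onset_map.get(i)), errors="coerce")
    y = (onset - filtered["year"]).between(1, horizon).to_numpy()
    if y.all() or not y.any():
        raise ValueError("labels are single-class; the ranking model is untrainable")
    X = filtered[candidates].to_numpy(dtype=float)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    order = np.argsort(rf.feature_importances_)[::-1]
    ranking = [candidates[i] for i in order]
    return ranking, ranking[:n_top] + list(forced)
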