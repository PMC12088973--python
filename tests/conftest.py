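import numpy as np
import pandas as pd
import pytest

from checkup_ela import CohortSpec, IsingModel, generate_cohort
from checkup_ela.ela import _neighbors


def random_ising(seed: int, h_scale: float = 0.5, j_scale: float = 0.3) -> IsingModel:
    rng = np.random.default_rng(seed)
    h = rng.normal(0, h_scale, 6)
    J = rng.normal(0, j_scale, (6, 6))
    J = (J + J.T) / 2
    np.fill_diagonal(J, 0)
    return IsingModel(h, J)


def brute_force_basins(E):
    """Independent basin oracle: strict local minima plus greedy descent."""
    minima = sorted(p for p in range(64) if all(E[p] < E[q] for q in _neighbors(p)))

    def descend(p):
        while True:
            best = min(_neighbors(p), key=lambda q: E[q])
            if E[best] >= E[p]:
                return p
            p = best

    label = {m: i + 1 for i, m in enumerate(minima)}
    return minima, np.array([label[descend(p)] for p in range(64)])


def brute_force_barriers(E, minima, allowed=None):
    """Independent minimax oracle: smallest sub-level set connecting each pair."""
    from collections import deque

    allowed = set(range(64)) if allowed is None else set(allowed)
    k = len(minima)
    B = np.full((k, k), np.inf)
    levels = sorted(E[p] for p in allowed)
    for i in range(k):
        for j in range(i + 1, k):
            for t in levels:
                sub = {p for p in allowed if E[p] <= t}
                if minima[i] not in sub or minima[j] not in sub:
                    continue
                seen, dq = {minima[i]}, deque([minima[i]])
                while dq:
                    p = dq.popleft()
                    for q in _neighbors(p):
                        if q in sub and q not in seen:
                            seen.add(q)
                            dq.append(q)
                if minima[j] in seen:
                    B[i, j] = B[j, i] = t
                    break
    return B


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic synthetic cohort used across integration tests."""
    return generate_cohort(CohortSpec(n_individuals=150, seed=11))


def make_record(ind, year, sex="male", fasting=True, history=False,
                treatment=False, **features):
    base = {
        "individual_id": ind, "year": year, "sex": sex, "fasting": fasting,
        "questionnaire_history": history, "questionnaire_treatment": treatment,
    }
    base.update(features)
    return base


@pytest.fixture()
def filter_fixture():
    """20 hand-written records with known violations of every filter rule.

    Individual F01 is female (3 records). M01 is healthy and complete
    (4 records). M02 has one non-fasting record (of 3). M03 develops
    diabetes in 2014 via treatment flag: 2 pre-onset records, 2 at/after
    onset. M04 has a missing PG in one record (of 3). M05 has all 3 records
    non-fasting, so is dropped entirely at step 4. Feature columns beyond
    PG/HbA1c/BMI are complete constants; height/weight/smoker exercise the
    step-1 column drop. 'junk' is missing in 60% of records and must be
    dropped at step 1.
    """
    rows = []
    full = dict(PG=90.0, HbA1c=5.4, BMI=23.0, height=170.0, weight=66.0,
                smoker="no", junk=np.nan)
    for y in (2012, 2013, 2014):
        rows.append(make_record("F01", y, sex="female", **full))
    for y in (2012, 2013, 2014, 2015):
        rows.append(make_record("M01", y, **{**full, "junk": 1.0}))
    rows.append(make_record("M02", 2012, fasting=False, **full))
    for y in (2013, 2014):
        rows.append(make_record("M02", y, **{**full, "junk": 1.0}))
    rows.append(make_record("M03", 2012, **full))
    rows.append(make_record("M03", 2013, **{**full, "junk": 1.0}))
    rows.append(make_record("M03", 2014, treatment=True, **full))
    rows.append(make_record("M03", 2015, treatment=True, **full))
    rows.append(make_record("M04", 2012, **{**full, "PG": np.nan}))
    for y in (2013, 2014):
        rows.append(make_record("M04", y, **full))
    for y in (2012, 2013, 2014):
        rows.append(make_record("M05", y, fasting=False, **full))
    return pd.DataFrame(rows)
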