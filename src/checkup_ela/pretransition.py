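"""Feature comparisons in the year before a state transition.

For each transition type (e.g. healthy -> intermediate), the from-year
record of every counted transition contributes that record's feature value;
transition types are then compared feature by feature with a two-sided
Mann-Whitney U test. Values are summarized as mean +/- sample standard
deviation (n - 1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


def collect_pretransition_values(
    records: pd.DataFrame,
    sequences,
    transition_type: tuple[int, int],
    feature: str,
) -> list[float]:
    """Feature values at the from-year of every counted transition of one type.

    One value per transition (an individual with two qualifying transitions
    contributes twice); missing values are dropped per feature.
    """
    s_from, s_to = transition_type
    lookup = dict(zip(zip(records["individual_id"], records["year"]),
                      records[feature].astype(float)))
    out = []
    for seq in sequences:
        for (y0, a), (y1, b) in zip(seq.pairs, seq.pairs[1:]):
            if y1 - y0 == 1 and a == s_from and b == s_to:
                v = lookup.get((seq.individual_id, y0), np.nan)
                if v is not None and not (isinstance(v, float) and np.isnan(v)):
                    out.append(float(v))
    return out


@dataclass
class FeatureComparison:
    """Mean +/- SD per group plus the two-sided Mann-Whitney p-value."""

    n_a: int
    mean_a: float
    sd_a: float
    n_b: int
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float


def compare_feature(values_a, values_b) -> FeatureComparison:
    """Two-sided Mann-Whitney U comparison of two value lists.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's automatic rule).
    Raises on an empty group: the comparison is undefined there.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return FeatureComparison(
        n_a=len(a), mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        n_b=len(b), mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
    )


def pretransition_table(
    records: pd.DataFrame,
    sequences,
    transition_types,
    features,
    comparisons,
) -> pd.DataFrame:
    """Table of per-transition-type mean +/- SD and pairwise p-values.

    ``comparisons`` is a list of transition-type pairs, e.g.
    ``[((1, 2), (1, 3))]``. Comparisons with an empty group are reported
    with a NaN p-value rather than failing the whole table.
    """
    rows = []
    for f in features:
        vals = {t: collect_pretransition_values(records, sequences, t, f)
                for t in transition_types}
        row = {"feature": f}
        for t in transition_types:
            v = np.asarray(vals[t], dtype=float)
            key = f"{t[0]}to{t[1]}"
            row[f"n_{key}"] = len(v)
            row[f"mean_{key}"] = float(v.mean()) if len(v) else np.nan
            row[f"sd_{key}"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        for ta, tb in comparisons:
            key = f"p_{ta[0]}to{ta[1]}_vs_{tb[0]}to{tb[1]}"
            try:
                row[key] = compare_feature(vals[ta], vals[tb]).p_value
            except ValueError:
                row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
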