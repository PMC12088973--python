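"""Year-to-year state transitions on the energy landscape, and the
chi-squared test for pathway preference between groups.

A transition is a pair of visits by the same individual in consecutive
calendar years (gap exactly one); visits separated by two or more years are
never paired. Remaining in the same state counts as a self-transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .ela import BasinGraph, Thresholds, binarize_frame


@dataclass
class StateSequence:
    """One individual's (year, state-label) visit sequence, years increasing."""

    individual_id: object
    pairs: list  # [(year, state), ...]

    def __post_init__(self):
        years = [y for y, _ in self.pairs]
        if sorted(set(years)) != years:
            raise ValueError("years must be strictly increasing")


def assign_states(
    records: pd.DataFrame, thresholds: Thresholds, basins: BasinGraph
) -> list[StateSequence]:
    """Map each record to its basin state via its binary pattern."""
    bits = binarize_frame(records, thresholds)
    idx = bits @ (1 << np.arange(bits.shape[1] - 1, -1, -1))
    states = basins.state_of[idx]
    out = []
    frame = records[["individual_id", "year"]].copy()
    frame["state"] = states
    for ind, g in frame.groupby("individual_id", sort=False):
        g = g.sort_values("year")
        out.append(StateSequence(ind, list(zip(g["year"].astype(int), g["state"].astype(int)))))
    return out


def count_transitions(sequences, n_states: int) -> np.ndarray:
    """K x K matrix of from-state x to-state counts over consecutive-year pairs.

    Only pairs with a year difference of exactly 1 are counted;
    self-transitions are included.
    """
    counts = np.zeros((n_states, n_states), dtype=int)
    for seq in sequences:
        for (y0, s0), (y1, s1) in zip(seq.pairs, seq.pairs[1:]):
            if y1 - y0 == 1:
                counts[s0 - 1, s1 - 1] += 1
    return counts


def count_transitions_by_group(sequences, n_states: int, group_of: dict) -> dict:
    """Transition counts stratified by a per-individual group label.

    Group matrices sum entrywise to the whole-cohort matrix.
    """
    by_group: dict = {}
    for seq in sequences:
        g = group_of[seq.individual_id]
        if g not in by_group:
            by_group[g] = []
        by_group[g].append(seq)
    return {g: count_transitions(seqs, n_states) for g, seqs in by_group.items()}


@dataclass
class PreferenceTest:
    """Chi-squared test of pathway preference on a 2x2 contingency table.

    Rows are groups (e.g. obese / non-obese), columns are competing
    transition types; Pearson chi-squared with Yates continuity correction,
    one degree of freedom.
    """

    table: np.ndarray
    statistic: float
    dof: int
    p_value: float


def preference_test(table) -> PreferenceTest:
    """Yates-corrected chi-squared test on a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; use an exact test instead")
    res = chi2_contingency(t, correction=True)
    return PreferenceTest(t.astype(int), float(res.statistic), int(res.dof), float(res.pvalue))
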