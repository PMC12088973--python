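"""Unit and property tests for the energy-landscape core: encoding,
binarization, pairwise maximum-entropy fitting, basins, and barriers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from checkup_ela import (
    FitError,
    IsingModel,
    binarize,
    binarize_frame,
    build_basin_graph,
    compute_thresholds,
    disconnectivity,
    fit_pairwise_maxent,
    landscape,
    pattern_bits,
    pattern_index,
)
from checkup_ela.ela import ELA_FEATURES, EnergyLandscape, _PATTERNS, _neighbors

from conftest import brute_force_barriers, brute_force_basins, random_ising


# ---------------------------------------------------------------------------
# Pattern encoding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bits, index", [
    ([0, 1, 0, 1, 1, 1], 23),  # worked example: 0+16+0+4+2+1
    ([0, 0, 0, 0, 0, 0], 0),
    ([1, 1, 1, 1, 1, 1], 63),
    ([1, 0, 0, 0, 0, 0], 32),  # first feature is the most significant bit
])
def test_pattern_index_big_endian(bits, index):
    assert pattern_index(bits) == index


@given(st.integers(min_value=0, max_value=63))
@settings(deadline=None, derandomize=True)
def test_pattern_encoding_round_trip(idx):
    assert pattern_index(pattern_bits(idx)) == idx


def test_pattern_index_rejects_wrong_length_and_values():
    with pytest.raises(ValueError):
        pattern_index([0, 1, 0])
    with pytest.raises(ValueError):
        pattern_index([0, 1, 2, 0, 0, 0])


# ---------------------------------------------------------------------------
# Thresholds and binarization
# ---------------------------------------------------------------------------

def _frame(values_per_feature):
    n = max(len(v) for v in values_per_feature.values())
    return pd.DataFrame({f: list(v) + [v[-1]] * (n - len(v))
                         for f, v in values_per_feature.items()})


def test_median_thresholds_match_sorting_oracle():
    """Sample medians: middle order statistic (odd n), midpoint (even n)."""
    rng = np.random.default_rng(5)
    for n in (3, 4, 7, 10):
        df = pd.DataFrame(rng.normal(size=(n, 6)), columns=ELA_FEATURES)
        th = compute_thresholds(df)
        for f in ELA_FEATURES:
            v = np.sort(df[f].to_numpy())
            expect = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
            assert th.values[f] == pytest.approx(expect)


def test_simple_medians():
    df = _frame({f: [1.0, 2.0, 3.0] for f in ELA_FEATURES})
    assert compute_thresholds(df).values["PG"] == 2.0
    df4 = _frame({f: [1.0, 2.0, 3.0, 4.0] for f in ELA_FEATURES})
    assert compute_thresholds(df4).values["PG"] == 2.5


def test_thresholds_require_data():
    with pytest.raises(ValueError):
        compute_thresholds(pd.DataFrame(columns=list(ELA_FEATURES)))


def test_binarize_boundary_and_reversal():
    """Value equal to the threshold is the good side: bit 0, except HDL-C
    where low values are unhealthy so the assignment is reversed."""
    df = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (6, 1)).T, columns=ELA_FEATURES)
    th = compute_thresholds(df)  # all thresholds 2.0
    rec = {f: 2.0 for f in ELA_FEATURES}
    bits = binarize(rec, th)
    expected = [1 if f == "HDL-C" else 0 for f in ELA_FEATURES]
    assert list(bits) == expected


def test_binarize_all_bad_and_all_good():
    df = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (6, 1)).T, columns=ELA_FEATURES)
    th = compute_thresholds(df)
    worst = {f: (1.0 if f == "HDL-C" else 3.0) for f in ELA_FEATURES}
    assert pattern_index(binarize(worst, th)) == 63
    best = {f: (3.0 if f == "HDL-C" else 1.0) for f in ELA_FEATURES}
    assert pattern_index(binarize(best, th)) == 0


def test_binarize_rejects_missing():
    df = pd.DataFrame(np.ones((3, 6)), columns=ELA_FEATURES)
    th = compute_thresholds(df)
    rec = {f: 1.0 for f in ELA_FEATURES}
    rec["PG"] = np.nan
    with pytest.raises(ValueError, match="PG"):
        binarize(rec, th)


def test_binarize_frame_matches_rowwise():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(size=(40, 6)), columns=ELA_FEATURES)
    th = compute_thresholds(df)
    X = binarize_frame(df, th)
    for i in range(len(df)):
        assert list(X[i]) == list(binarize(df.iloc[i], th))


# ---------------------------------------------------------------------------
# Pairwise maximum-entropy fit
# ---------------------------------------------------------------------------

def test_uniform_data_gives_uniform_model():
    """Independent fair-coin columns are maximum entropy: all 64 patterns 1/64."""
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, size=(50_000, 6))
    model = fit_pairwise_maxent(X)
    assert np.abs(model.probabilities() - 1 / 64).max() < 0.005


@pytest.mark.parametrize("coding", ["01", "spin"])
def test_weighted_fit_recovers_exact_distribution(coding):
    """Fitting the exact 64-pattern distribution of a known model (the
    infinite-sample limit) recovers its probabilities; the check compares
    probabilities so it is coding-invariant."""
    true = random_ising(3)
    p_true = true.probabilities()
    fit = fit_pairwise_maxent(_PATTERNS.astype(int), weights=p_true,
                              coding=coding, tol=1e-8)
    assert np.abs(fit.probabilities() - p_true).max() < 1e-6


def test_fit_moment_matching_certificate():
    """At convergence, model first and second moments match the data within
    the gradient tolerance (the stationarity condition of the likelihood)."""
    true = random_ising(9)
    p_true = true.probabilities()
    fit = fit_pairwise_maxent(_PATTERNS.astype(int), weights=p_true, tol=1e-6)
    p_fit = fit.probabilities()
    emp1, mod1 = p_true @ _PATTERNS, p_fit @ _PATTERNS
    emp2 = _PATTERNS.T @ (p_true[:, None] * _PATTERNS)
    mod2 = _PATTERNS.T @ (p_fit[:, None] * _PATTERNS)
    assert np.abs(emp1 - mod1).max() < 1e-6
    off = ~np.eye(6, dtype=bool)
    assert np.abs(emp2 - mod2)[off].max() < 1e-6


def test_round_trip_sampling_recovery():
    """Exact samples from a known model, re-fitted, recover each pattern
    probability within 3 Monte-Carlo standard errors."""
    from checkup_ela import sample_from_ising

    true = random_ising(0)
    p_true = true.probabilities()
    n = 100_000
    X = sample_from_ising(true, n, seed=42)
    fit = fit_pairwise_maxent(X)
    se = np.sqrt(p_true * (1 - p_true) / n)
    assert (np.abs(fit.probabilities() - p_true) <= 3 * se).all()


def test_degenerate_column_raises():
    X = np.zeros((100, 6), dtype=int)
    X[:, 1:] = np.random.default_rng(0).integers(0, 2, (100, 5))
    with pytest.raises(FitError, match="regulariz"):
        fit_pairwise_maxent(X)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def test_zero_model_is_flat():
    model = IsingModel(np.zeros(6), np.zeros((6, 6)))
    scape = landscape(model)
    assert np.allclose(scape.energies, scape.energies[0])
    assert np.allclose(scape.probabilities, 1 / 64)


def test_energies_match_brute_force():
    """E(sigma) = -h.sigma - sum_{i<j} J_ij sigma_i sigma_j, pattern by pattern."""
    model = random_ising(4)
    scape = landscape(model)
    for p in range(64):
        s = pattern_bits(p)
        e = -(model.h @ s) - sum(model.J[i, j] * s[i] * s[j]
                                 for i in range(6) for j in range(i + 1, 6))
        assert scape.energies[p] == pytest.approx(e)


@pytest.mark.parametrize("seed", range(5))
def test_probabilities_normalized(seed):
    assert landscape(random_ising(seed)).probabilities.sum() == pytest.approx(1.0, abs=1e-12)


def test_lower_energy_means_higher_probability():
    scape = landscape(random_ising(8))
    order = np.argsort(scape.energies)
    assert (np.diff(scape.probabilities[order]) <= 1e-15).all()


# ---------------------------------------------------------------------------
# Basin graph
# ---------------------------------------------------------------------------

def test_monotone_landscape_single_basin():
    """E = popcount has a unique minimum at pattern 0 and one state."""
    E = np.array([bin(p).count("1") for p in range(64)], dtype=float)
    basins = build_basin_graph(EnergyLandscape(E, np.ones(64) / 64))
    assert basins.local_minima == [0]
    assert (basins.state_of == 1).all()


def test_double_well_partition_matches_exhaustive_descent():
    """E = min(popcount, 6-popcount) is a symmetric double well with minima
    0 and 63; the plateau at popcount 3 is split by the lower-index tie rule,
    verified by exhaustive descent under the same lexicographic order."""
    pc = np.array([bin(p).count("1") for p in range(64)])
    E = np.minimum(pc, 6 - pc).astype(float)
    basins = build_basin_graph(EnergyLandscape(E, np.ones(64) / 64))
    assert basins.local_minima == [0, 63]

    def descend(p):
        while True:
            best = min(_neighbors(p), key=lambda q: (E[q], q))
            if (E[best], best) >= (E[p], p):
                return p
            p = best

    for p in range(64):
        assert basins.state_of[p] == (1 if descend(p) == 0 else 2)


def test_descent_terminates_at_state_minimum():
    """Following descent edges from any pattern reaches its state's local
    minimum in at most 63 steps."""
    scape = landscape(random_ising(12))
    basins = build_basin_graph(scape)
    minima = {i + 1: m for i, m in enumerate(basins.local_minima)}
    for p in range(64):
        q, steps = p, 0
        while basins.descent_edge[q] != -1:
            q = basins.descent_edge[q]
            steps += 1
            assert steps <= 63
        assert q == minima[basins.state_of[p]]


@pytest.mark.parametrize("seed", range(20))
def test_basins_match_brute_force_on_random_landscapes(seed):
    E = np.random.default_rng(seed).normal(size=64)
    basins = build_basin_graph(EnergyLandscape(E, np.ones(64) / 64))
    minima, states = brute_force_basins(E)
    assert basins.local_minima == minima
    assert (basins.state_of == states).all()


def test_minima_not_above_neighbors():
    scape = landscape(random_ising(6))
    basins = build_basin_graph(scape)
    for m in basins.local_minima:
        assert all(scape.energies[m] <= scape.energies[q] for q in _neighbors(m))


# ---------------------------------------------------------------------------
# Disconnectivity
# ---------------------------------------------------------------------------

def test_single_minimum_has_no_barriers():
    E = np.array([bin(p).count("1") for p in range(64)], dtype=float)
    scape = EnergyLandscape(E, np.ones(64) / 64)
    basins = build_basin_graph(scape)
    res = disconnectivity(scape, basins)
    assert res.barrier.shape == (1, 1)


def test_double_well_barrier_value():
    """Every 0 -> 63 path crosses popcount 3, so the minimax barrier is 3;
    confirmed against the sub-level-set connectivity oracle."""
    pc = np.array([bin(p).count("1") for p in range(64)])
    E = np.minimum(pc, 6 - pc).astype(float)
    scape = EnergyLandscape(E, np.ones(64) / 64)
    basins = build_basin_graph(scape)
    res = disconnectivity(scape, basins)
    assert res.barrier[0, 1] == 3.0
    B = brute_force_barriers(E, basins.local_minima)
    assert B[0, 1] == 3.0


@pytest.mark.parametrize("seed", range(15))
def test_barriers_match_brute_force_on_random_landscapes(seed):
    E = np.random.default_rng(100 + seed).normal(size=64)
    scape = EnergyLandscape(E, np.ones(64) / 64)
    basins = build_basin_graph(scape)
    res = disconnectivity(scape, basins)
    B = brute_force_barriers(E, basins.local_minima)
    off = ~np.eye(len(basins.local_minima), dtype=bool)
    assert np.allclose(res.barrier[off], B[off])


def test_barrier_dominates_both_minima():
    scape = landscape(random_ising(21))
    basins = build_basin_graph(scape)
    res = disconnectivity(scape, basins)
    E = scape.energies
    k = len(basins.local_minima)
    for i in range(k):
        for j in range(k):
            if i != j:
                assert res.barrier[i, j] >= max(E[basins.local_minima[i]],
                                                E[basins.local_minima[j]])


@pytest.mark.parametrize("seed", range(10))
def test_restricting_allowed_set_never_lowers_barriers(seed):
    """Prohibiting visits outside two target states (the modified
    disconnectivity graph) can only raise the barrier between them."""
    E = np.random.default_rng(200 + seed).normal(size=64)
    scape = EnergyLandscape(E, np.ones(64) / 64)
    basins = build_basin_graph(scape)
    full = disconnectivity(scape, basins)
    k = len(basins.local_minima)
    for i in range(k):
        for j in range(i + 1, k):
            allowed = np.flatnonzero(np.isin(basins.state_of, [i + 1, j + 1]))
            mod = disconnectivity(scape, basins, allowed)
            assert mod.barrier[i, j] >= full.barrier[i, j] - 1e-12


def test_restriction_raises_barrier_when_saddle_path_uses_third_state():
    """On a landscape where the optimal saddle path between two minima runs
    through a third basin, the restricted barrier is strictly higher."""
    found = False
    for seed in range(60):
        E = np.random.default_rng(300 + seed).normal(size=64)
        scape = EnergyLandscape(E, np.ones(64) / 64)
        basins = build_basin_graph(scape)
        k = len(basins.local_minima)
        if k < 3:
            continue
        full = disconnectivity(scape, basins)
        for i in range(k):
            for j in range(i + 1, k):
                allowed = np.flatnonzero(np.isin(basins.state_of, [i + 1, j + 1]))
                mod = disconnectivity(scape, basins, allowed)
                if mod.barrier[i, j] > full.barrier[i, j] + 1e-9:
                    found = True
                    # cross-check the raised value against the oracle
                    B = brute_force_barriers(E, basins.local_minima, allowed)
                    assert np.isclose(mod.barrier[i, j], B[i, j]) or (
                        np.isinf(mod.barrier[i, j]) and np.isinf(B[i, j]))
    assert found, "no third-state saddle found across trial landscapes"


def test_disconnected_pair_reports_infinity():
    """If the allowed set leaves two minima in separate components the
    barrier is +inf."""
    pc = np.array([bin(p).count("1") for p in range(64)])
    E = np.minimum(pc, 6 - pc).astype(float)
    scape = EnergyLandscape(E, np.ones(64) / 64)
    basins = build_basin_graph(scape)
    res = disconnectivity(scape, basins, allowed_patterns=[0, 63])
    assert np.isinf(res.barrier[0, 1])
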