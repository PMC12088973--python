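"""Energy landscape analysis over six binarized checkup features.

The analysis pipeline is: median binarization of the selected features,
maximum-likelihood fitting of a pairwise maximum-entropy (Ising) model over
the 2^6 = 64 binary patterns, assignment of a virtual energy to each pattern,
decomposition of pattern space into basins of attraction (states) via
steepest-descent edges on the 6-dimensional hypercube, and computation of
minimax energy barriers between local minima (the disconnectivity graph),
optionally with the path restricted to an allowed pattern set (the modified
disconnectivity graph).

Patterns are encoded big-endian: the first feature in ``feature_order`` is
the most significant bit, so the bit string ``010111`` has index
0 + 16 + 0 + 4 + 2 + 1 = 23.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default feature set entering the landscape, in bit order (MSB first).
ELA_FEATURES = ("HbA1c", "PG", "HDL-C", "BMI", "UA", "ALT")

#: Features for which a *high* value is the good condition, so the
#: binarization is reversed (value <= median -> 1).
REVERSED_FEATURES = frozenset({"HDL-C"})

N_BITS = 6
N_PATTERNS = 1 << N_BITS


class FitError(RuntimeError):
    """Raised when the pairwise maximum-entropy fit cannot proceed or converge."""


# ---------------------------------------------------------------------------
# Pattern encoding
# ---------------------------------------------------------------------------

def pattern_index(bits) -> int:
    """Decimal index of a binary pattern, first bit most significant.

    ``pattern_index([0, 1, 0, 1, 1, 1]) == 23``.
    """
    bits = np.asarray(list(bits), dtype=int)
    if bits.shape != (N_BITS,):
        raise ValueError(f"expected {N_BITS} bits, got shape {bits.shape}")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bits must be 0 or 1")
    return int(bits @ (1 << np.arange(N_BITS - 1, -1, -1)))


def pattern_bits(index: int) -> np.ndarray:
    """Inverse of :func:`pattern_index`: the 6-bit vector of a pattern index."""
    if not 0 <= index < N_PATTERNS:
        raise ValueError(f"pattern index must be in [0, {N_PATTERNS - 1}]")
    return np.array([(index >> k) & 1 for k in range(N_BITS - 1, -1, -1)], dtype=int)


def _all_patterns() -> np.ndarray:
    """(64, 6) matrix of all binary patterns, row p = bits of pattern p."""
    return np.array([pattern_bits(p) for p in range(N_PATTERNS)], dtype=float)


_PATTERNS = _all_patterns()


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Per-feature binarization thresholds (sample medians, clinical units).

    Standard features map ``value <= threshold -> 0`` (good); features in
    ``reversed_features`` map ``value <= threshold -> 1`` (bad), because a
    low value is the unhealthy condition for them (HDL-C).
    """

    feature_order: tuple[str, ...]
    values: dict[str, float]
    reversed_features: frozenset[str] = REVERSED_FEATURES

    def __post_init__(self):
        if len(self.feature_order) != N_BITS:
            raise ValueError(f"exactly {N_BITS} features required")
        missing = set(self.feature_order) - set(self.values)
        if missing:
            raise ValueError(f"missing thresholds for {sorted(missing)}")


def compute_thresholds(
    records: pd.DataFrame,
    feature_order=ELA_FEATURES,
    reversed_features: frozenset = REVERSED_FEATURES,
) -> Thresholds:
    """Sample median of each selected feature over the pooled analysis records.

    Medians are recomputed per analysis subset, so a sub-cohort re-run
    (e.g. restricted to individuals who later develop the disease) gets its
    own thresholds. Even-length samples use the midpoint of the two central
    order statistics.
    """
    if len(records) == 0:
        raise ValueError("cannot compute thresholds from an empty dataset")
    feature_order = tuple(feature_order)
    values = {}
    for f in feature_order:
        col = records[f]
        if col.isna().any():
            raise ValueError(f"feature {f!r} has missing values in the analysis subset")
        values[f] = float(col.median())
    return Thresholds(feature_order, values, frozenset(reversed_features))


def binarize(record, thresholds: Thresholds) -> np.ndarray:
    """Binarize one record (mapping or Series) to its 6-bit pattern.

    0 encodes the good condition: ``value <= median`` for standard features,
    ``value > median`` for reversed (HDL-C) features.
    """
    bits = np.empty(N_BITS, dtype=int)
    for k, f in enumerate(thresholds.feature_order):
        v = record[f]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"feature {f!r} is missing; cannot binarize")
        low = v <= thresholds.values[f]
        bits[k] = int(low) if f in thresholds.reversed_features else int(not low)
    return bits


def binarize_frame(records: pd.DataFrame, thresholds: Thresholds) -> np.ndarray:
    """Vectorized binarization of a record table; returns an (n, 6) 0/1 matrix."""
    cols = []
    for f in thresholds.feature_order:
        v = records[f].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"feature {f!r} has missing values; cannot binarize")
        low = v <= thresholds.values[f]
        cols.append(low if f in thresholds.reversed_features else ~low)
    return np.column_stack(cols).astype(int)


# ---------------------------------------------------------------------------
# Pairwise maximum-entropy (Ising) model
# ---------------------------------------------------------------------------

@dataclass
class IsingModel:
    """Pairwise maximum-entropy model: biases h_i and couplings J_ij.

    With the default {0,1} coding the energy of a pattern sigma is
    E(sigma) = -sum_i h_i sigma_i - sum_{i<j} J_ij sigma_i sigma_j and the
    pattern probability is P(sigma) = exp(-E(sigma)) / Z. The alternative
    {-1,+1} spin coding maps bit b to 2b - 1 in the energy; the two codings
    are reparametrizations of the same distribution family.
    """

    h: np.ndarray
    J: np.ndarray
    feature_order: tuple[str, ...] = ELA_FEATURES
    coding: str = "01"

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.shape != (N_BITS,) or self.J.shape != (N_BITS, N_BITS):
            raise ValueError("h must be length 6 and J 6x6")
        if not np.allclose(self.J, self.J.T) or np.any(np.diag(self.J) != 0):
            raise ValueError("J must be symmetric with zero diagonal")
        if self.coding not in ("01", "spin"):
            raise ValueError("coding must be '01' or 'spin'")

    def _states(self) -> np.ndarray:
        return 2.0 * _PATTERNS - 1.0 if self.coding == "spin" else _PATTERNS

    def energies(self) -> np.ndarray:
        """Energy of every pattern 0..63."""
        s = self._states()
        return -(s @ self.h) - 0.5 * np.einsum("pi,ij,pj->p", s, self.J, s)

    def probabilities(self) -> np.ndarray:
        e = self.energies()
        w = np.exp(-(e - e.min()))
        return w / w.sum()


def _pattern_weights(binary_matrix: np.ndarray, weights=None) -> np.ndarray:
    """Aggregate rows of an (n, 6) 0/1 matrix into 64 pattern weights summing to 1."""
    X = np.asarray(binary_matrix)
    if X.ndim != 2 or X.shape[1] != N_BITS:
        raise ValueError(f"binary matrix must have {N_BITS} columns")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("binary matrix entries must be 0 or 1")
    idx = X @ (1 << np.arange(N_BITS - 1, -1, -1))
    if weights is None:
        weights = np.ones(len(X))
    w = np.bincount(idx, weights=np.asarray(weights, dtype=float), minlength=N_PATTERNS)
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive total")
    return w / total


def fit_pairwise_maxent(
    binary_matrix: np.ndarray,
    weights=None,
    coding: str = "01",
    feature_order=ELA_FEATURES,
    learning_rate: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> IsingModel:
    """Maximum-likelihood pairwise maximum-entropy fit by exact gradient ascent.

    The gradient of the average log-likelihood with respect to (h, J) is the
    difference between empirical and model first/second moments, computed
    exactly by enumerating all 64 patterns, so convergence (max gradient
    component below ``tol``) certifies moment matching at the same tolerance.

    ``weights`` allows fitting directly to a known pattern distribution (the
    infinite-sample limit). Rows may be the 64 patterns with their exact
    probabilities as weights.

    Raises
    ------
    FitError
        If a column is degenerate (all 0 or all 1; the corresponding bias
        diverges — regularize or drop the feature), or if the gradient norm
        does not reach ``tol`` within ``max_iter`` iterations.
    """
    pw = _pattern_weights(binary_matrix, weights)
    S = 2.0 * _PATTERNS - 1.0 if coding == "spin" else _PATTERNS

    emp1 = pw @ S
    emp2 = S.T @ (pw[:, None] * S)
    off = ~np.eye(N_BITS, dtype=bool)
    lim = S.min(), S.max()
    if np.any(emp1 <= lim[0]) or np.any(emp1 >= lim[1]):
        bad = [feature_order[i] for i in range(N_BITS) if emp1[i] <= lim[0] or emp1[i] >= lim[1]]
        raise FitError(
            f"degenerate column(s) {bad}: observed in only one state; "
            "the maximum-likelihood bias diverges (consider regularization)"
        )

    h = np.zeros(N_BITS)
    J = np.zeros((N_BITS, N_BITS))
    for _ in range(max_iter):
        e = -(S @ h) - 0.5 * np.einsum("pi,ij,pj->p", S, J, S)
        w = np.exp(-(e - e.min()))
        p = w / w.sum()
        mod1 = p @ S
        mod2 = S.T @ (p[:, None] * S)
        g_h = emp1 - mod1
        g_J = np.where(off, emp2 - mod2, 0.0)
        gmax = max(np.abs(g_h).max(), np.abs(g_J).max())
        if gmax < tol:
            return IsingModel(h, J, tuple(feature_order), coding)
        h += learning_rate * g_h
        J += learning_rate * g_J
    raise FitError(f"no convergence in {max_iter} iterations; last max gradient {gmax:.3e}")


# ---------------------------------------------------------------------------
# Energy landscape
# ---------------------------------------------------------------------------

@dataclass
class EnergyLandscape:
    """Virtual energy and model probability for each of the 64 patterns."""

    energies: np.ndarray
    probabilities: np.ndarray
    model: IsingModel | None = None

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.energies.shape != (N_PATTERNS,):
            raise ValueError(f"need {N_PATTERNS} energies")


def landscape(model: IsingModel) -> EnergyLandscape:
    """Evaluate E(sigma) for all 64 patterns and P(sigma) = exp(-E)/Z."""
    return EnergyLandscape(model.energies(), model.probabilities(), model)


# ---------------------------------------------------------------------------
# Basin graph
# ---------------------------------------------------------------------------

def _neighbors(p: int) -> list[int]:
    return [p ^ (1 << b) for b in range(N_BITS)]


@dataclass
class BasinGraph:
    """Steepest-descent decomposition of pattern space into states.

    Each non-minimum pattern has one directed edge toward its lowest-energy
    Hamming-1 neighbor; connected components are the states. ``state_of``
    holds 1-based state labels ordered by the local minimum's pattern index
    (the state whose minimum has the smallest index is state 1).
    """

    descent_edge: np.ndarray  # target pattern per pattern; -1 for local minima
    local_minima: list[int]
    state_of: np.ndarray  # length 64, labels 1..K

    @property
    def n_states(self) -> int:
        return len(self.local_minima)

    def patterns_of_state(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.state_of == label)


def build_basin_graph(scape: EnergyLandscape) -> BasinGraph:
    """Basin decomposition by steepest descent on the 6-cube.

    Descent compares neighbors lexicographically by (energy, pattern index):
    a pattern points to its smallest neighbor under that order provided the
    neighbor is smaller than the pattern itself; otherwise the pattern is a
    local minimum. Plateau ties therefore resolve toward the lower pattern
    index, keeping the decomposition deterministic, and the rule reduces to
    plain steepest descent when all energies are distinct.
    """
    E = scape.energies
    edge = np.full(N_PATTERNS, -1, dtype=int)
    for p in range(N_PATTERNS):
        best = min(_neighbors(p), key=lambda q: (E[q], q))
        if (E[best], best) < (E[p], p):
            edge[p] = best
    minima = [p for p in range(N_PATTERNS) if edge[p] == -1]

    root = np.full(N_PATTERNS, -1, dtype=int)

    def _root(p: int) -> int:
        chain = []
        while root[p] == -1 and edge[p] != -1:
            chain.append(p)
            p = edge[p]
        r = p if edge[p] == -1 else root[p]
        for q in chain:
            root[q] = r
        return r

    label_of_min = {m: i + 1 for i, m in enumerate(sorted(minima))}
    state = np.array([label_of_min[_root(p)] for p in range(N_PATTERNS)])
    return BasinGraph(edge, sorted(minima), state)


# ---------------------------------------------------------------------------
# Disconnectivity graph (minimax barriers)
# ---------------------------------------------------------------------------

@dataclass
class DisconnectivityResult:
    """Minimax energy barriers between local minima.

    ``barrier[a, b]`` (indexed by position in ``minima``) is the minimum over
    Hamming-1 paths from minimum a to minimum b — restricted to
    ``allowed_patterns`` if given — of the maximum energy along the path.
    Unreachable pairs carry +inf. ``relative_barrier`` subtracts the row
    minimum's own energy, giving the climb height out of that state.
    """

    minima: list[int]
    barrier: np.ndarray
    energies: np.ndarray = field(repr=False)

    def relative_barrier(self) -> np.ndarray:
        return self.barrier - self.energies[self.minima][:, None]


def disconnectivity(
    scape: EnergyLandscape,
    basins: BasinGraph,
    allowed_patterns=None,
) -> DisconnectivityResult:
    """Minimax barriers by a threshold sweep with union-find.

    Patterns are activated in increasing (energy, index) order; each new
    pattern is unioned with already-active Hamming-1 neighbors. The energy at
    which two minima's components first merge is exactly the minimax path
    value between them. Restricting ``allowed_patterns`` (the modified
    disconnectivity graph, e.g. to the patterns of two states only) can only
    raise barriers.
    """
    E = scape.energies
    minima = basins.local_minima
    k = len(minima)
    allowed = set(range(N_PATTERNS)) if allowed_patterns is None else set(int(p) for p in allowed_patterns)

    parent = {}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    barrier = np.full((k, k), np.inf)
    np.fill_diagonal(barrier, E[minima] if k else 0.0)
    pos = {m: i for i, m in enumerate(minima)}
    members: dict[int, set] = {}  # union-find root -> minima positions inside

    for p in sorted(allowed, key=lambda q: (E[q], q)):
        parent[p] = p
        members[p] = {pos[p]} if p in pos else set()
        for q in _neighbors(p):
            if q in parent:
                rp, rq = find(p), find(q)
                if rp != rq:
                    for a in members[rp]:
                        for b in members[rq]:
                            barrier[a, b] = barrier[b, a] = E[p]
                    parent[rq] = rp
                    members[rp] |= members.pop(rq)
    return DisconnectivityResult(minima, barrier, E)
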