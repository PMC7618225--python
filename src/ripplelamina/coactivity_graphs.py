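"""Signed coactivity graphs and structural metrics of population patterns.

Coactivity between units is estimated from z-scored event spike counts with
two estimators: *population-conditioned* (pairwise regression controlling
for the summed activity of all other units, symmetrised into an undirected
graph) and *fully-conditioned* (per-target ridge regression on all other
units, directed). The resulting signed weighted graphs are characterised by
node strength, structural balance over triads, and the population vectors
themselves by Gini sparsity, angle-based intrinsic dimensionality (ABID),
participation ratio and asymmetric Jaccard inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.neighbors import NearestNeighbors

from ripplelamina.population_activity import margin_preserving_shuffle, zscore_rows


@dataclass
class CoactivityGraph:
    """Signed weighted adjacency over units with estimation metadata."""

    weights: np.ndarray
    estimator: str  # "population-conditioned" | "fully-conditioned"
    symmetric: bool
    event_class: str | None = None
    epoch: str | None = None

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]


def population_conditioned_coactivity(
    pvs, *, event_class=None, epoch=None, zscore: bool = True
) -> CoactivityGraph:
    """Pairwise coactivity conditioned on the population rate.

    For each ordered pair (i, j) the weight is the regression coefficient of
    unit i in ``x_j ~ beta_ij * x_i + alpha_ij * P`` where ``P`` is the
    summed activity of the other N-2 units. The matrix is symmetrised as
    ``(A + A.T) / 2`` with a zero diagonal. Constant units get NaN edges.
    """
    X = np.asarray(pvs, dtype=float)
    n_units, n_events = X.shape
    if n_units < 3:
        raise ValueError("need at least 3 units")
    Z = zscore_rows(X) if zscore else X
    constant = np.asarray(X.std(axis=1) == 0)
    total = Z.sum(axis=0)
    A = np.zeros((n_units, n_units))
    for i in range(n_units):
        xi = Z[i]
        for j in range(n_units):
            if i == j:
                continue
            if constant[i] or constant[j]:
                A[i, j] = np.nan
                continue
            P = total - xi - Z[j]
            D = np.column_stack([xi, P, np.ones(n_events)])
            beta, *_ = np.linalg.lstsq(D, Z[j], rcond=None)
            A[i, j] = beta[0]
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return CoactivityGraph(
        weights=A,
        estimator="population-conditioned",
        symmetric=True,
        event_class=event_class,
        epoch=epoch,
    )


def fully_conditioned_coactivity(
    pvs, penalty: float = 1.0, *, event_class=None, epoch=None, zscore: bool = True
) -> CoactivityGraph:
    """Per-target ridge regression on all other units (directed graph).

    Row i holds the coefficients predicting unit i from every other unit.
    """
    X = np.asarray(pvs, dtype=float)
    n_units = X.shape[0]
    if n_units < 3:
        raise ValueError("need at least 3 units")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    Z = zscore_rows(X) if zscore else X
    C = np.zeros((n_units, n_units))
    idx = np.arange(n_units)
    for i in range(n_units):
        others = idx[idx != i]
        if penalty == 0:
            D = Z[others].T
            if np.linalg.matrix_rank(D) < D.shape[1]:
                raise np.linalg.LinAlgError("singular design with zero penalty")
            beta, *_ = np.linalg.lstsq(D, Z[i], rcond=None)
        else:
            beta = Ridge(alpha=penalty, fit_intercept=False).fit(Z[others].T, Z[i]).coef_
        C[i, others] = beta
    np.fill_diagonal(C, 0.0)
    return CoactivityGraph(
        weights=C,
        estimator="fully-conditioned",
        symmetric=False,
        event_class=event_class,
        epoch=epoch,
    )


def node_strength(graph: CoactivityGraph | np.ndarray) -> np.ndarray:
    """Mean off-diagonal edge weight per node."""
    W = graph.weights if isinstance(graph, CoactivityGraph) else np.asarray(graph, float)
    n = W.shape[0]
    off = W.copy().astype(float)
    np.fill_diagonal(off, np.nan)
    return np.nanmean(off, axis=1) if n > 1 else np.zeros(n)


def structural_balance(
    graph: CoactivityGraph | np.ndarray, zero_tol: float = 1e-12
) -> float:
    """Proportion of balanced triads (0 or 2 negative edges) in a signed graph.

    Triads with any absent edge (|weight| <= ``zero_tol``) are excluded;
    NaN when the graph has no closed triads. Uses trace identities over the
    positive/negative sign adjacencies.
    """
    W = graph.weights if isinstance(graph, CoactivityGraph) else np.asarray(graph, float)
    W = (W + W.T) / 2.0
    P = (W > zero_tol).astype(float)
    Q = (W < -zero_tol).astype(float)
    np.fill_diagonal(P, 0)
    np.fill_diagonal(Q, 0)
    t0 = np.trace(P @ P @ P) / 6.0
    t1 = np.trace(Q @ P @ P) / 2.0
    t2 = np.trace(P @ Q @ Q) / 2.0
    t3 = np.trace(Q @ Q @ Q) / 6.0
    total = t0 + t1 + t2 + t3
    if total == 0:
        return float("nan")
    return float((t0 + t2) / total)


def structural_balance_census(weights, zero_tol: float = 1e-12) -> float:
    """Brute-force triad census (independent cross-check of the trace form)."""
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    balanced = total = 0
    for i, j, k in combinations(range(n), 3):
        e = (W[i, j], W[j, k], W[i, k])
        if any(abs(w) <= zero_tol for w in e):
            continue
        total += 1
        if sum(w < 0 for w in e) in (0, 2):
            balanced += 1
    return float("nan") if total == 0 else balanced / total


def gini_sparsity(pv) -> float:
    """Gini index of a nonnegative population vector (ascending sort).

    ``S = sum_i (2i - N - 1) x_(i) / (N * sum_i x_i)`` with x sorted
    ascending and i the 1-based rank; 0 for perfectly even vectors,
    (N-1)/N for a single active unit. Undefined (ValueError) for all-zero
    input.
    """
    x = np.sort(np.asarray(pv, dtype=float))
    if np.any(x < 0):
        raise ValueError("population vector must be nonnegative")
    n = x.size
    s = x.sum()
    if s == 0:
        raise ValueError("all-zero population vector")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * s))


def abid_dimensionality(pvs, k: int = 50, *, zscore: bool = True):
    """Angle-based intrinsic dimensionality per event and its mean.

    Events are points in unit space (columns of the z-scored PV matrix).
    For each event the difference vectors to its ``k`` nearest neighbours
    are normalised and ``D = k^2 / sum_ij S_ij^2`` computed from their
    pairwise cosine similarities. Returns ``(per_event_D, mean_D)``.
    """
    X = np.asarray(pvs, dtype=float)
    Z = zscore_rows(X) if zscore else X
    pts = Z.T  # events x units
    n = pts.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} events, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    _, idx = nn.kneighbors(pts)
    D = np.empty(n)
    for m in range(n):
        diffs = pts[idx[m, 1:]] - pts[m]
        norms = np.linalg.norm(diffs, axis=1)
        norms[norms == 0] = 1.0
        U = diffs / norms[:, None]
        S = U @ U.T
        D[m] = k**2 / np.sum(S**2)
    return D, float(D.mean())


def abid_balanced(
    pvs_by_class: dict,
    *,
    k: int = 50,
    subsample: int = 100,
    n_perm: int = 1000,
    seed=None,
) -> dict:
    """Class-balanced ABID: mean over random subsamples of 100 PVs per class.

    ``k`` is capped at ``subsample - 1``. Returns class -> mean D across
    permutations.
    """
    rng = np.random.default_rng(seed)
    k_eff = min(k, subsample - 1)
    out = {}
    for klass, pvs in pvs_by_class.items():
        Z = zscore_rows(np.asarray(pvs, dtype=float))
        n_ev = Z.shape[1]
        take = min(subsample, n_ev)
        means = np.empty(n_perm)
        for p in range(n_perm):
            cols = rng.choice(n_ev, size=take, replace=False)
            _, means[p] = abid_dimensionality(
                Z[:, cols], k=min(k_eff, take - 1), zscore=False
            )
        out[klass] = float(means.mean())
    return out


def normalized_dimensionality(pvs, *, k: int = 50, n_surrogates: int = 10, seed=None) -> float:
    """True ABID divided by the ABID of identity-shuffled surrogates.

    Surrogates shuffle unit identities within each event, preserving each
    event's count multiset (sparsity) while destroying coactivity. Ratios
    below 1 indicate structure (planted low-dimensional motifs).
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(pvs, dtype=float)
    _, d_true = abid_dimensionality(X, k=k)
    d_surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        Xs = np.empty_like(X)
        for e in range(X.shape[1]):
            Xs[:, e] = rng.permutation(X[:, e])
        _, d_surr[s] = abid_dimensionality(Xs, k=k)
    return float(d_true / d_surr.mean())


def participation_ratio(pvs, *, zscore: bool = True) -> float:
    """Linear dimensionality ``(sum lambda)^2 / sum lambda^2``.

    Eigenvalues come from the covariance spectrum (squared singular values)
    of the z-scored unit x event matrix.
    """
    X = np.asarray(pvs, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 events")
    Z = zscore_rows(X) if zscore else X
    s = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), compute_uv=False)
    lam = s**2
    denom = np.sum(lam**2)
    if denom == 0:
        return float("nan")
    return float(np.sum(lam) ** 2 / denom)


def asymmetric_inclusion(pv_m, pv_q) -> float:
    """Fraction of m's active cells also active in q, ``|m ∩ q| / |m|``.

    Inputs are binarised (any spike counts as active). Undefined (NaN) for
    an empty m.
    """
    m = np.asarray(pv_m) > 0
    q = np.asarray(pv_q) > 0
    nm = m.sum()
    if nm == 0:
        return float("nan")
    return float(np.sum(m & q) / nm)


def inclusion_resampled(
    pvs_lm, pvs_rad, n_iter: int = 1000, *, seed=None
) -> np.ndarray:
    """Mean LM-into-Rad inclusion over class-balanced resamples.

    Per iteration the larger class is subsampled to the smaller's size D and
    the mean pairwise ``I_{LM->Rad}`` over the D x D pairs is recorded.
    """
    L = np.asarray(pvs_lm) > 0
    R = np.asarray(pvs_rad) > 0
    n_l, n_r = L.shape[1], R.shape[1]
    if n_l == 0 or n_r == 0:
        raise ValueError("both classes must be non-empty")
    d = min(n_l, n_r)
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    sizes_l = L.sum(axis=0).astype(float)
    for it in range(n_iter):
        li = rng.choice(n_l, size=d, replace=False) if n_l > d else np.arange(n_l)
        ri = rng.choice(n_r, size=d, replace=False) if n_r > d else np.arange(n_r)
        inter = L[:, li].T.astype(float) @ R[:, ri].astype(float)
        denom = sizes_l[li][:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = inter / denom
        out[it] = np.nanmean(vals)
    return out


def excitability_control_pc1(
    pvs, *, n_surrogates: int = 200, seed=None
) -> tuple[float, np.ndarray]:
    """Correlation of PC1 weights with mean rates, against margin surrogates.

    PC1 is taken from the z-scored unit x event matrix; the observed Pearson
    r between its unit weights and mean firing counts is compared with the
    same statistic on margin-preserving surrogates. An observed |r| below
    the surrogate band indicates coactivity structure beyond excitability.
    """
    X = np.asarray(pvs, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 units")
    rng = np.random.default_rng(seed)

    def pc1_rate_corr(counts):
        Z = zscore_rows(counts)
        u, s, _ = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), full_matrices=False)
        w = u[:, 0] if u[:, 0].sum() >= 0 else -u[:, 0]  # orient along coactivation
        rates = counts.mean(axis=1)
        if rates.std() == 0 or w.std() == 0:
            return 0.0
        return float(np.corrcoef(w, rates)[0, 1])

    observed = pc1_rate_corr(X)
    surr = np.empty(n_surrogates)
    Xi = X.astype(int)
    for s_ in range(n_surrogates):
        surr[s_] = pc1_rate_corr(margin_preserving_shuffle(Xi, rng=rng).astype(float))
    return observed, surr


def graph_to_edgelist(graph: CoactivityGraph):
    """Edge-list DataFrame (i, j, weight) of the upper triangle / all pairs."""
    import pandas as pd

    W = graph.weights
    n = W.shape[0]
    rows = []
    for i in range(n):
        js = range(i + 1, n) if graph.symmetric else (j for j in range(n) if j != i)
        for j in js:
            rows.append({"i": i, "j": j, "weight": W[i, j]})
    return pd.DataFrame(rows)
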