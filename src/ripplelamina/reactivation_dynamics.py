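"""Offline reactivation measures and their dynamics across post-sleep.

Reactivation is the above-chance re-expression, during sleep ripples, of
coactivity estimated in another epoch (waking theta cycles or pre-sleep
ripples). Three complementary measures are implemented:

* **GLM peer prediction** — linear models trained on theta-cycle activity
  predict each cell from four peers (different tetrodes, optionally the
  same sublayer); their accuracy on pre- versus post-sleep ripple activity
  quantifies reactivation of waking patterns.
* **Recent-to-prior balance** — ``W_recent = A_theta @ inv(A_pre)`` maps
  pre-sleep coactivity onto waking coactivity; the quadratic form
  ``v.T @ W_recent @ v`` on a ripple population vector scores whether its
  pattern aligns with wake-gained versus pre-existing motifs.
* **Pre-sleep coactivity reactivation** — per-cell linear models trained on
  pre-sleep ripple population vectors, applied in 10-minute post-sleep
  windows, with cell-identity-shuffle chance normalisation.

Time-binned series are compared between a flat model and an exponential
decay ``a * exp(-t / tau) + c`` with the Bayesian information criterion
``BIC = k * log(n) + n * log(SSE / n)`` (k = 1 flat, k = 3 exponential);
bootstrap over sessions gives the tau confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ripplelamina.population_activity import zscore_rows
from ripplelamina.stats import bootstrap_test


# ---------------------------------------------------------------- GLM peer prediction
def glm_reactivation(
    counts_theta,
    counts_pre,
    counts_post,
    tetrodes,
    *,
    sublayers=None,
    sublayer_filter: bool = False,
    n_predictors: int = 4,
    n_draws: int = 100,
    seed=None,
) -> dict:
    """Peer-prediction reactivation of waking theta coactivity.

    For each target cell, linear models predict its (z-scored) theta-cycle
    activity from ``n_predictors`` peers recorded on other tetrodes
    (``n_draws`` random draws); each model is then applied to the z-scored
    ripple-nested counts of pre- and post-sleep, and accuracy is the Pearson
    r between predicted and actual activity. With ``sublayer_filter``,
    predictors must share the target's sublayer. Units with fewer than
    ``n_predictors + 1`` eligible peers are skipped. Returns per-unit
    ``acc_pre``/``acc_post`` arrays (NaN for skipped units) and the
    one-tailed paired bootstrap test of post > pre.
    """
    Zt = zscore_rows(np.asarray(counts_theta, dtype=float))
    Zpre = zscore_rows(np.asarray(counts_pre, dtype=float))
    Zpost = zscore_rows(np.asarray(counts_post, dtype=float))
    tetrodes = np.asarray(tetrodes)
    n_units = Zt.shape[0]
    rng = np.random.default_rng(seed)

    acc_pre = np.full(n_units, np.nan)
    acc_post = np.full(n_units, np.nan)
    for u in range(n_units):
        eligible = np.flatnonzero(tetrodes != tetrodes[u])
        eligible = eligible[eligible != u]
        if sublayer_filter and sublayers is not None:
            sub = np.asarray(sublayers)
            eligible = eligible[sub[eligible] == sub[u]]
        if eligible.size < n_predictors + 1:
            continue
        r_pre = np.empty(n_draws)
        r_post = np.empty(n_draws)
        for d in range(n_draws):
            pred = rng.choice(eligible, size=n_predictors, replace=False)
            D = Zt[pred].T
            beta, *_ = np.linalg.lstsq(
                np.column_stack([D, np.ones(D.shape[0])]), Zt[u], rcond=None
            )
            r_pre[d] = _safe_corr(Zpre[pred].T @ beta[:-1] + beta[-1], Zpre[u])
            r_post[d] = _safe_corr(Zpost[pred].T @ beta[:-1] + beta[-1], Zpost[u])
        acc_pre[u] = np.nanmean(r_pre)
        acc_post[u] = np.nanmean(r_post)

    ok = np.isfinite(acc_pre) & np.isfinite(acc_post)
    test = (
        bootstrap_test(
            acc_post[ok], acc_pre[ok], paired=True, sided="greater", n=10_000, seed=seed
        )
        if ok.sum() >= 2
        else None
    )
    return {"acc_pre": acc_pre, "acc_post": acc_post, "test": test}


def _safe_corr(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------- recent-to-prior balance
def recent_prior_transform(
    A_pre, A_theta, *, cond_limit: float = 1e8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """``W_recent = A_theta @ inv(A_pre)`` and ``W_prior = A_pre @ inv(A_theta)``.

    Ill-conditioned matrices (condition number above ``cond_limit``) are
    regularised by adding ``1e-6 * trace / N`` to the diagonal before
    inversion; the returned flag reports whether regularisation was
    triggered for either inverse.
    """
    A_pre = np.asarray(A_pre, dtype=float)
    A_theta = np.asarray(A_theta, dtype=float)
    if A_pre.shape != A_theta.shape or A_pre.shape[0] != A_pre.shape[1]:
        raise ValueError("coactivity matrices must be square and matched")

    def safe_inv(M):
        if np.linalg.cond(M) > cond_limit:
            eps = 1e-6 * abs(np.trace(M)) / M.shape[0]
            eps = eps if eps > 0 else 1e-6
            return np.linalg.inv(M + eps * np.eye(M.shape[0])), True
        return np.linalg.inv(M), False

    inv_pre, f1 = safe_inv(A_pre)
    inv_theta, f2 = safe_inv(A_theta)
    return A_theta @ inv_pre, A_pre @ inv_theta, bool(f1 or f2)


def balance_score(W, pvs, *, pair_mask=None) -> np.ndarray:
    """Quadratic form ``v.T @ W @ v`` per z-scored population vector.

    ``pvs`` is a unit x event matrix (or a single vector). ``pair_mask``
    restricts the matrix to selected unit pairs (e.g. CA3 x CA1) by zeroing
    all other entries.
    """
    W = np.asarray(W, dtype=float)
    V = np.atleast_2d(np.asarray(pvs, dtype=float))
    if V.shape[0] != W.shape[0]:
        if V.shape[1] == W.shape[0]:  # single vector passed as row
            V = V.T
        else:
            raise ValueError("population vectors do not match matrix dimension")
    if pair_mask is not None:
        W = W * np.asarray(pair_mask, dtype=float)
    scores = np.einsum("ue,uv,ve->e", V, W, V)
    return scores if scores.size > 1 else scores


def region_pair_mask(regions, region_a: str, region_b: str) -> np.ndarray:
    """Mask keeping only entries connecting ``region_a`` and ``region_b``."""
    r = np.asarray(regions)
    a = (r == region_a)[:, None] & (r == region_b)[None, :]
    return (a | a.T).astype(float)


# ---------------------------------------------------------------- drift series and fits
@dataclass
class DriftSeries:
    """Time-binned reactivation or balance values for one ripple class."""

    bin_centres_min: np.ndarray
    values: np.ndarray
    ripple_class: str | None = None
    offset: float = 0.0
    session_ids: np.ndarray | None = None


def drift_timecourse(
    times_min_by_class: dict,
    values_by_class: dict,
    *,
    bin_min: float = 10.0,
    t_start_min: float = 10.0,
    t_end_min: float = 70.0,
) -> dict:
    """Per-class 10-minute binned means, normalised by the grand mean.

    Event times are minutes into post-sleep; the first ``t_start_min``
    minutes are excluded and bins are non-overlapping ``bin_min`` windows
    covering ``(t_start_min, t_end_min]``. The normalisation offset — the
    grand mean across all bins and classes — is subtracted from every bin,
    so a constant input maps to all-zero series.
    """
    edges = np.arange(t_start_min, t_end_min + bin_min / 2, bin_min)
    centres = (edges[:-1] + edges[1:]) / 2.0
    per_class = {}
    for klass in times_min_by_class:
        t = np.asarray(times_min_by_class[klass], dtype=float)
        v = np.asarray(values_by_class[klass], dtype=float)
        means = np.full(centres.size, np.nan)
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            m = (t > lo) & (t <= hi) & np.isfinite(v)
            if m.any():
                means[i] = v[m].mean()
        per_class[klass] = means
    grand = np.nanmean(np.concatenate(list(per_class.values())))
    return {
        klass: DriftSeries(
            bin_centres_min=centres,
            values=means - grand,
            ripple_class=str(klass),
            offset=float(grand),
        )
        for klass, means in per_class.items()
    }


@dataclass
class FitResult:
    """Flat-versus-exponential model comparison for a drift series."""

    model: str  # "flat" | "exponential"
    params: dict
    bic_flat: float
    bic_exp: float
    tau_samples: np.ndarray = field(default=None)
    r_samples: np.ndarray = field(default=None)

    @property
    def tau_ci(self) -> tuple[float, float]:
        lo, hi = np.nanpercentile(self.tau_samples, [2.5, 97.5])
        return float(lo), float(hi)


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _fit_exponential(t, y):
    """Least-squares exponential fit with a grid of initial values."""
    spans = max(y.max() - y.min(), 1e-12)
    best, best_sse = None, np.inf
    for tau0 in (5.0, 13.0, 30.0, 60.0):
        for a0 in (spans, -spans):
            try:
                popt, _ = curve_fit(
                    _exp_model,
                    t,
                    y,
                    p0=(a0, tau0, y.mean()),
                    bounds=([-np.inf, 0.5, -np.inf], [np.inf, 1e4, np.inf]),
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            sse = np.sum((y - _exp_model(t, *popt)) ** 2)
            if sse < best_sse:
                best, best_sse = popt, sse
    return best, best_sse


def _bic(k, n, sse):
    sse = max(sse, 1e-300)
    return k * np.log(n) + n * np.log(sse / n)


def fit_flat_vs_exponential(
    times_min,
    values,
    *,
    session_ids=None,
    n_boot: int = 10_000,
    seed=None,
) -> FitResult:
    """Select flat versus exponential dynamics by BIC, with bootstrap CIs.

    ``times_min`` / ``values`` are the concatenated time-binned series of
    all sessions (NaN bins dropped). ``BIC = k log(n) + n log(SSE / n)``
    with k = 1 for the flat model (the mean) and k = 3 for
    ``a * exp(-t/tau) + c``. When ``session_ids`` are given, sessions are
    resampled with replacement ``n_boot`` times to produce tau and
    goodness-of-fit (Pearson r) distributions.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 4:
        raise ValueError("need at least 4 points")
    n = t.size
    sse_flat = float(np.sum((y - y.mean()) ** 2))
    popt, sse_exp = _fit_exponential(t, y)
    if popt is None:
        popt, sse_exp = (0.0, np.inf, y.mean()), sse_flat
    bic_flat = _bic(1, n, sse_flat)
    bic_exp = _bic(3, n, sse_exp)
    model = "exponential" if bic_exp < bic_flat else "flat"

    tau_samples = r_samples = np.asarray([np.nan])
    if session_ids is not None and n_boot > 0:
        sid = np.asarray(session_ids)[ok]
        sessions = np.unique(sid)
        rng = np.random.default_rng(seed)
        tau_samples = np.full(n_boot, np.nan)
        r_samples = np.full(n_boot, np.nan)
        by_session = {s: np.flatnonzero(sid == s) for s in sessions}
        for b in range(n_boot):
            pick = rng.choice(sessions, size=sessions.size, replace=True)
            idx = np.concatenate([by_session[s] for s in pick])
            pb, _ = _fit_exponential(t[idx], y[idx])
            if pb is None:
                continue
            tau_samples[b] = pb[1]
            pred = _exp_model(t[idx], *pb)
            r_samples[b] = _safe_corr(pred, y[idx])
    return FitResult(
        model=model,
        params={"a": float(popt[0]), "tau_min": float(popt[1]), "c": float(popt[2]),
                "flat_mean": float(y.mean())},
        bic_flat=float(bic_flat),
        bic_exp=float(bic_exp),
        tau_samples=tau_samples,
        r_samples=r_samples,
    )


# ---------------------------------------------------------------- pre-sleep reactivation
def presleep_reactivation_decay(
    counts_pre,
    counts_post,
    post_times_min,
    *,
    bin_min: float = 10.0,
    t_start_min: float = 10.0,
    t_end_min: float = 70.0,
    n_shuffles: int = 100,
    unit_mask=None,
    seed=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reactivation strength of pre-sleep coactivity per post-sleep window.

    Each cell's linear model is trained on the z-scored pre-sleep ripple
    population vectors (predicting it from all other cells) and applied to
    the post-sleep events of each 10-minute window; the mean Pearson
    accuracy across cells, chance-normalised by subtracting the mean
    accuracy of models trained on cell-identity-shuffled pre-sleep PVs, is
    the window's reactivation strength. Returns ``(bin_centres_min,
    strength, per_unit)`` where ``per_unit`` is a unit x bin matrix (for
    sublayer-restricted slope comparisons, pass ``unit_mask``).
    """
    pre = np.asarray(counts_pre, dtype=float)
    post = np.asarray(counts_post, dtype=float)
    t_post = np.asarray(post_times_min, dtype=float)
    n_units = pre.shape[0]
    if unit_mask is None:
        unit_mask = np.ones(n_units, dtype=bool)
    unit_mask = np.asarray(unit_mask, dtype=bool)
    rng = np.random.default_rng(seed)

    Zpre = zscore_rows(pre)
    Zpost = zscore_rows(post)
    idx = np.arange(n_units)

    def fit_betas(Z):
        betas = {}
        for u in idx[unit_mask]:
            others = idx[(idx != u) & unit_mask]
            D = np.column_stack([Z[others].T, np.ones(Z.shape[1])])
            beta, *_ = np.linalg.lstsq(D, Z[u], rcond=None)
            betas[u] = (others, beta)
        return betas

    betas = fit_betas(Zpre)
    # chance: cell identities shuffled within each pre-sleep PV
    chance_acc = np.zeros(n_units)
    sub = idx[unit_mask]
    for s in range(n_shuffles):
        Zs = np.array(Zpre)
        for e in range(Zs.shape[1]):
            Zs[np.ix_(sub, [e])] = Zs[rng.permutation(sub), e][:, None]
        bs = fit_betas(Zs)
        for u, (others, beta) in bs.items():
            pred = Zpost[others].T @ beta[:-1] + beta[-1]
            r = _safe_corr(pred, Zpost[u])
            chance_acc[u] += 0.0 if np.isnan(r) else r
    chance_acc /= max(n_shuffles, 1)

    edges = np.arange(t_start_min, t_end_min + bin_min / 2, bin_min)
    centres = (edges[:-1] + edges[1:]) / 2.0
    per_unit = np.full((n_units, centres.size), np.nan)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        m = (t_post > lo) & (t_post <= hi)
        if m.sum() < 3:
            continue
        Zw = Zpost[:, m]
        for u, (others, beta) in betas.items():
            pred = Zw[others].T @ beta[:-1] + beta[-1]
            r = _safe_corr(pred, Zw[u])
            if not np.isnan(r):
                per_unit[u, i] = r - chance_acc[u]
    strength = np.nanmean(per_unit[unit_mask], axis=0)
    return centres, strength, per_unit


def wake_reactivation_partial(
    counts_pre,
    counts_theta,
    counts_post,
    post_times_min,
    *,
    bin_min: float = 10.0,
    t_start_min: float = 10.0,
    t_end_min: float = 70.0,
    min_pairs: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Wake-coactivity reactivation with pre-sleep cofiring regressed out.

    Pairwise cofiring (Pearson correlation over events) is computed for
    pre-sleep, exploration theta and each 10-minute post-sleep window; per
    window, post cofiring is regressed on wake cofiring with pre-sleep
    cofiring as a covariate and the wake beta is the reactivation strength.
    Windows with fewer than ``min_pairs`` valid pairs return NaN.
    """
    def cofiring(counts):
        Z = zscore_rows(np.asarray(counts, dtype=float))
        C = np.corrcoef(Z)
        iu = np.triu_indices(C.shape[0], k=1)
        return C[iu]

    co_pre = cofiring(counts_pre)
    co_theta = cofiring(counts_theta)
    post = np.asarray(counts_post, dtype=float)
    t_post = np.asarray(post_times_min, dtype=float)

    edges = np.arange(t_start_min, t_end_min + bin_min / 2, bin_min)
    centres = (edges[:-1] + edges[1:]) / 2.0
    betas = np.full(centres.size, np.nan)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        m = (t_post > lo) & (t_post <= hi)
        if m.sum() < 3:
            continue
        co_post = cofiring(post[:, m])
        ok = np.isfinite(co_post) & np.isfinite(co_theta) & np.isfinite(co_pre)
        if ok.sum() < min_pairs:
            continue
        D = np.column_stack([co_theta[ok], co_pre[ok], np.ones(ok.sum())])
        beta, *_ = np.linalg.lstsq(D, co_post[ok], rcond=None)
        betas[i] = beta[0]
    return centres, betas


def stability_score(acc_pre, acc_post):
    """``1 - (r_pre - r_post)`` on chance-normalised accuracies."""
    return 1.0 - (np.asarray(acc_pre, dtype=float) - np.asarray(acc_post, dtype=float))


# ---------------------------------------------------------------- attribution and slopes
def feature_attribution(
    balance,
    times_min,
    occurrence_freq,
    sparsity,
    *,
    n_shuffles: int = 25_000,
    n_cv: int = 20,
    test_frac: float = 0.2,
    seed=None,
) -> dict:
    """Attribute drift to log-time versus occurrence frequency and sparsity.

    A linear model predicts the per-bin balance from {log time, mean
    ripples/min, mean active-cell proportion} with 20x 80/20 cross-validated
    Pearson-r accuracy. For each feature, ``n_shuffles`` models with that
    feature shuffled give an accuracy-gain distribution
    (original - shuffled); the p-value is the proportion of shuffles with
    gain < 0. Collinear features trigger a condition warning.
    """
    y = np.asarray(balance, dtype=float)
    feats = {
        "log_time": np.log(np.asarray(times_min, dtype=float)),
        "occurrence_freq": np.asarray(occurrence_freq, dtype=float),
        "sparsity": np.asarray(sparsity, dtype=float),
    }
    X = np.column_stack(list(feats.values()))
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok]
    n = y.size
    if n < 8:
        raise ValueError("too few bins for attribution")
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    if np.linalg.cond(Xs.T @ Xs) > 1e8:
        import warnings

        warnings.warn("collinear features; attribution unstable")
    rng = np.random.default_rng(seed)
    n_test = max(2, int(round(test_frac * n)))
    splits = [rng.permutation(n) for _ in range(n_cv)]

    def cv_acc(design):
        rs = []
        D = np.column_stack([design, np.ones(n)])
        for perm in splits:
            te, tr = perm[:n_test], perm[n_test:]
            beta, *_ = np.linalg.lstsq(D[tr], y[tr], rcond=None)
            r = _safe_corr(D[te] @ beta, y[te])
            if not np.isnan(r):
                rs.append(r)
        return float(np.mean(rs)) if rs else np.nan

    acc_full = cv_acc(Xs)
    out = {"accuracy": acc_full, "features": {}}
    for f_i, name in enumerate(feats):
        gains = np.empty(n_shuffles)
        for s in range(n_shuffles):
            Xp = Xs.copy()
            Xp[:, f_i] = rng.permutation(Xp[:, f_i])
            gains[s] = acc_full - cv_acc(Xp)
        out["features"][name] = {
            "gain": float(np.nanmean(gains)),
            "p": float(np.mean(gains < 0)),
        }
    return out


def sublayer_decay_compare(
    per_unit_series: np.ndarray,
    bin_centres_min: np.ndarray,
    sublayer_labels,
    session_ids=None,
    *,
    n_boot: int = 10_000,
    min_units: int = 5,
    seed=None,
) -> dict:
    """Z-scored decay slopes of reactivation strength per CA1 sublayer.

    Per sublayer, reactivation strength is regressed on log time pooling
    unit series (bootstrap over units, or sessions when ``session_ids``
    map units to sessions); the chance distribution circularly shifts the
    time bins of every series, preserving autocorrelation. Sublayers with
    fewer than ``min_units`` units are excluded (NaN).
    """
    S = np.asarray(per_unit_series, dtype=float)
    t = np.log(np.asarray(bin_centres_min, dtype=float))
    labels = np.asarray(sublayer_labels)
    rng = np.random.default_rng(seed)

    def slope(series_block, shift=None):
        ys, xs = [], []
        for row in series_block:
            y = row if shift is None else np.roll(row, shift)
            m = np.isfinite(y)
            ys.append(y[m])
            xs.append(t[m])
        y = np.concatenate(ys)
        x = np.concatenate(xs)
        if y.size < 3 or x.std() == 0:
            return np.nan
        D = np.column_stack([x, np.ones(x.size)])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        return beta[0]

    out = {}
    for sub in np.unique(labels):
        rows = np.flatnonzero(labels == sub)
        rows = rows[np.isfinite(S[rows]).any(axis=1)]
        if rows.size < min_units:
            out[str(sub)] = {"z": float("nan"), "slope": float("nan")}
            continue
        obs = np.empty(n_boot)
        null = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(rows, size=rows.size, replace=True)
            obs[b] = slope(S[pick])
            null[b] = slope(S[pick], shift=int(rng.integers(1, t.size)))
        mu, sd = np.nanmean(null), np.nanstd(null)
        z = (np.nanmean(obs) - mu) / sd if sd > 0 else np.nan
        out[str(sub)] = {"z": float(z), "slope": float(np.nanmean(obs))}
    return out
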