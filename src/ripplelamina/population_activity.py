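"""Ripple-locked firing analyses and ripple-type decoding from populations.

The central object is the population-vector matrix: per-event spike counts
of each unit within the 50-ms window centred on the ripple-envelope peak
(``[peak - 25 ms, peak + 25 ms)``). Decoding analyses are controlled with a
margin-preserving shuffle that conserves each unit's total spike count and
each event's population count exactly while destroying coactivity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

PV_WINDOW_S = 0.050


def population_vectors(spikes, unit_ids, event_times, window_s: float = PV_WINDOW_S):
    """Unit x event spike-count matrix in peak-centred half-open windows.

    ``spikes`` is a DataFrame with columns ``unit_id, spike_time_s`` (or a
    tuple of arrays). Row order follows ``unit_ids``.
    """
    if hasattr(spikes, "columns"):
        s_u = spikes["unit_id"].to_numpy()
        s_t = spikes["spike_time_s"].to_numpy()
    else:
        s_u, s_t = spikes
    unit_ids = np.asarray(unit_ids)
    events = np.asarray(event_times, dtype=float)
    half = window_s / 2.0
    counts = np.zeros((unit_ids.size, events.size), dtype=int)
    order = np.argsort(s_t, kind="stable")
    s_t = s_t[order]
    s_u = s_u[order]
    uid_to_row = {u: i for i, u in enumerate(unit_ids)}
    lo = np.searchsorted(s_t, events - half, side="left")
    hi = np.searchsorted(s_t, events + half, side="left")
    for e, (a, b) in enumerate(zip(lo, hi)):
        for u in s_u[a:b]:
            row = uid_to_row.get(u)
            if row is not None:
                counts[row, e] += 1
    return counts


def zscore_rows(counts) -> np.ndarray:
    """Z-score each unit's counts across events (constant rows -> zeros)."""
    X = np.asarray(counts, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def compute_peth(
    spikes,
    unit_ids,
    event_times,
    *,
    window_s: float = 0.200,
    bin_ms: float = 0.8,
    smoothing_sd_ms: float = 5.0,
):
    """Peri-event time histograms of firing rate around ripple peaks.

    Returns ``(rates, lags_s)`` where ``rates`` is a unit x lag matrix in
    Hz, built over +/- ``window_s`` with ``bin_ms`` bins and smoothed with a
    Gaussian kernel (sigma ``smoothing_sd_ms``). Callers should pass
    isolated events only.
    """
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("no events")
    if hasattr(spikes, "columns"):
        s_u = spikes["unit_id"].to_numpy()
        s_t = spikes["spike_time_s"].to_numpy()
    else:
        s_u, s_t = spikes
    unit_ids = np.asarray(unit_ids)
    bin_s = bin_ms * 1e-3
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    lags = (edges[:-1] + edges[1:]) / 2.0
    rates = np.zeros((unit_ids.size, lags.size))
    order = np.argsort(s_t, kind="stable")
    s_t, s_u = s_t[order], s_u[order]
    for i, u in enumerate(unit_ids):
        ut = s_t[s_u == u]
        rel = []
        lo = np.searchsorted(ut, events - window_s)
        hi = np.searchsorted(ut, events + window_s)
        for t0, a, b in zip(events, lo, hi):
            rel.append(ut[a:b] - t0)
        rel = np.concatenate(rel) if rel else np.empty(0)
        hist, _ = np.histogram(rel, bins=edges)
        rates[i] = hist / (events.size * bin_s)
    if smoothing_sd_ms > 0:
        rates = ndimage.gaussian_filter1d(rates, smoothing_sd_ms / bin_ms, axis=1)
    return rates, lags


def peak_rate(rates, lags_s, half_window_s: float = 0.025) -> np.ndarray:
    """Maximum PETH rate within +/- 25 ms of the event peak, per unit."""
    m = np.abs(lags_s) <= half_window_s
    return np.asarray(rates)[:, m].max(axis=1)


def zscore_peth(rates, reference_rates) -> np.ndarray:
    """Z-score PETHs by each unit's mean/SD in the reference condition.

    The reference is conventionally the Rad-event PETH of the same unit.
    """
    ref = np.asarray(reference_rates, dtype=float)
    mu = ref.mean(axis=1, keepdims=True)
    sd = ref.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (np.asarray(rates, dtype=float) - mu) / sd


def delta_log_rate(rate_ripple, rate_baseline):
    """log10 ratio of in-ripple to pre-ripple baseline rate.

    The baseline window is conventionally -200 to -100 ms before the peak.
    Zero baselines map to NaN (unit excluded from group statistics).
    """
    r = np.asarray(rate_ripple, dtype=float)
    b = np.asarray(rate_baseline, dtype=float)
    ratio = np.full(np.broadcast(r, b).shape, np.nan)
    np.divide(r, b, out=ratio, where=b > 0)
    out = np.full_like(ratio, np.nan)
    np.log10(ratio, out=out, where=ratio > 0)
    return out if out.ndim else float(out)


def ripple_phase_coupling(spike_phases, n_bins: int = 24):
    """Preferred ripple phase and coherence from binned spike phases.

    The phase range [0, 2*pi) is divided into ``n_bins`` bins; the circular
    mean of the binned distribution gives the preferred phase and the
    resultant length the coherence. Returns ``(preferred_phase,
    coherence)``; NaNs when no spikes.
    """
    ph = np.asarray(spike_phases, dtype=float)
    ph = ph[np.isfinite(ph)] % (2 * np.pi)
    if ph.size == 0:
        return float("nan"), float("nan")
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    hist, _ = np.histogram(ph, bins=edges)
    p = hist / hist.sum()
    centres = (edges[:-1] + edges[1:]) / 2
    vec = np.sum(p * np.exp(1j * centres))
    return float(np.angle(vec) % (2 * np.pi)), float(np.abs(vec))


def int_to_pyr_ratio(rates_int, rates_pyr) -> float:
    """log10 of mean interneuron rate over mean principal-cell rate."""
    ri = np.asarray(rates_int, dtype=float)
    rp = np.asarray(rates_pyr, dtype=float)
    if ri.size == 0 or rp.size == 0:
        raise ValueError("both groups must be non-empty")
    mi, mp = ri.mean(), rp.mean()
    if mi <= 0 or mp <= 0:
        return float("nan")
    return float(np.log10(mi / mp))


def margin_preserving_shuffle(counts, seed=None, rng=None) -> np.ndarray:
    """Shuffle a unit x event count matrix preserving both margins exactly.

    Every spike is expanded to its unit index; the index list is randomly
    permuted and reassigned event by event, so each unit keeps its total
    spike count and each event keeps its population count, while
    within-event unit identities (coactivity) are randomised.
    """
    X = np.asarray(counts)
    if np.any(X < 0) or not np.issubdtype(X.dtype, np.integer):
        X = X.astype(int)
        if np.any(X < 0):
            raise ValueError("counts must be nonnegative integers")
    if rng is None:
        rng = np.random.default_rng(seed)
    unit_of_spike = np.repeat(np.arange(X.shape[0]), X.sum(axis=1))
    rng.shuffle(unit_of_spike)
    col_sums = X.sum(axis=0)
    out = np.zeros_like(X)
    i = 0
    for e, c in enumerate(col_sums):
        np.add.at(out[:, e], unit_of_spike[i : i + c], 1)
        i += c
    return out


def _plugin_mi_bits(confusion) -> float:
    """Plug-in mutual information (base 2) of a confusion table."""
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    if n == 0:
        return 0.0
    p = c / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def decode_ripple_type(
    pvs,
    labels,
    *,
    n_cells: int = 15,
    n_perm: int = 200,
    n_cv: int = 20,
    test_frac: float = 0.2,
    min_events_per_class: int = 250,
    with_shuffle_control: bool = True,
    C: float = 1.0,
    seed=None,
) -> dict:
    """Mutual-information accuracy of ripple-type decoding from PVs.

    Per permutation a random subset of ``n_cells`` units is drawn, classes
    are balanced by downsampling the larger one, and an L2 logistic
    regression is evaluated over ``n_cv`` random 80/20 splits; accuracy is
    the plug-in mutual information of the pooled test confusion table
    (0 bit = chance, 1 bit = perfect for two balanced classes). The control
    repeats the procedure on margin-shuffled count matrices. Returns
    ``{"mi_bits", "mi_null_bits", "per_perm", "per_perm_null"}``.
    """
    X = np.asarray(pvs)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("decoding expects exactly 2 classes")
    counts = [np.sum(y == c) for c in classes]
    if min(counts) < min_events_per_class:
        raise ValueError(
            f"need at least {min_events_per_class} events per class, got {counts}"
        )
    if X.shape[0] < n_cells:
        raise ValueError("not enough units")
    rng = np.random.default_rng(seed)

    def run(matrix):
        mis = np.empty(n_perm)
        for pidx in range(n_perm):
            cells = rng.choice(matrix.shape[0], size=n_cells, replace=False)
            m = min(np.sum(y == c) for c in classes)
            idx = np.concatenate(
                [rng.choice(np.flatnonzero(y == c), size=m, replace=False) for c in classes]
            )
            Xp = zscore_rows(matrix[np.ix_(cells, idx)]).T
            yp = y[idx]
            conf = np.zeros((2, 2))
            n_ev = yp.size
            n_test = max(2, int(round(test_frac * n_ev)))
            for _ in range(n_cv):
                perm = rng.permutation(n_ev)
                te, tr = perm[:n_test], perm[n_test:]
                if np.unique(yp[tr]).size < 2:
                    continue
                clf = LogisticRegression(C=C, max_iter=1000).fit(Xp[tr], yp[tr])
                pred = clf.predict(Xp[te])
                for a, b in zip(yp[te], pred):
                    conf[int(a == classes[1]), int(b == classes[1])] += 1
            mis[pidx] = _plugin_mi_bits(conf)
        return mis

    per_perm = run(X)
    out = {"mi_bits": float(per_perm.mean()), "per_perm": per_perm}
    if with_shuffle_control:
        shuffled = margin_preserving_shuffle(X, rng=rng)
        per_null = run(shuffled)
        out["mi_null_bits"] = float(per_null.mean())
        out["per_perm_null"] = per_null
    return out


def temporal_pattern_features(
    spikes,
    unit_ids,
    event_times,
    *,
    window_s: float = 0.200,
    bin_ms: float = 0.8,
    smoothing_sd_ms: float = 3.0,
    n_components: int = 2,
):
    """Per-unit PCA of peri-event firing patterns, concatenated as features.

    For each unit, its event x lag matrix (+/- 200 ms, sigma = 3 ms
    smoothing) is reduced to ``n_components`` principal components; the
    per-event component strengths of all units are concatenated into an
    event x (n_components * n_units) matrix and z-scored per column. Silent
    units contribute zero columns and are flagged. Returns ``(features,
    flagged_units)``.
    """
    events = np.asarray(event_times, dtype=float)
    if hasattr(spikes, "columns"):
        s_u = spikes["unit_id"].to_numpy()
        s_t = spikes["spike_time_s"].to_numpy()
    else:
        s_u, s_t = spikes
    unit_ids = np.asarray(unit_ids)
    bin_s = bin_ms * 1e-3
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    n_bins = edges.size - 1
    feats = np.zeros((events.size, n_components * unit_ids.size))
    flagged = []
    for i, u in enumerate(unit_ids):
        ut = np.sort(s_t[s_u == u])
        M = np.zeros((events.size, n_bins))
        lo = np.searchsorted(ut, events - window_s)
        hi = np.searchsorted(ut, events + window_s)
        for e, (t0, a, b) in enumerate(zip(events, lo, hi)):
            if b > a:
                M[e], _ = np.histogram(ut[a:b] - t0, bins=edges)
        if not M.any():
            flagged.append(u)
            continue
        M = ndimage.gaussian_filter1d(M, smoothing_sd_ms / bin_ms, axis=1)
        Mc = M - M.mean(axis=0, keepdims=True)
        u_svd, s_svd, _ = np.linalg.svd(Mc, full_matrices=False)
        k = min(n_components, s_svd.size)
        feats[:, i * n_components : i * n_components + k] = u_svd[:, :k] * s_svd[:k]
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    degenerate = sd == 0
    flagged.extend(
        np.unique(unit_ids[np.unique(np.flatnonzero(degenerate) // n_components)]).tolist()
    )
    sd[degenerate] = 1.0
    return (feats - mu) / sd, sorted(set(flagged))
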