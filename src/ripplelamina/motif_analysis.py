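"""ICA coactivity-motif extraction and cross-class contribution gains.

Assemblies ("motifs") are extracted from the z-scored unit x event count
matrix with the PCA/ICA method: the number of significant motifs is the
number of correlation-matrix eigenvalues above the Marcenko-Pastur upper
edge ``(1 + sqrt(N_units / N_events))**2``, and FastICA is applied to the
data projected onto that significant subspace. Motif weight vectors are
unit length with the largest-magnitude weight positive.

The *contribution gain* asks whether a unit participates more in a motif
during Rad events than during the LM events the motif was extracted from,
using leave-that-unit-out motif activations and margin-preserving
surrogates to control for rate and sparsity differences between classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA

from ripplelamina.population_activity import margin_preserving_shuffle, zscore_rows


def marchenko_pastur_threshold(n_units: int, n_events: int) -> float:
    """Upper eigenvalue edge ``(1 + sqrt(q))^2`` with q = n_units / n_events."""
    if n_units <= 0 or n_events <= 0:
        raise ValueError("counts must be positive")
    return (1.0 + np.sqrt(n_units / n_events)) ** 2


@dataclass
class MotifSet:
    """Unit-weight motif vectors with the significance threshold used."""

    weights: np.ndarray  # n_motifs x n_units, rows unit-norm
    threshold: float
    eigenvalues: np.ndarray
    event_class: str | None = None

    @property
    def n_motifs(self) -> int:
        return self.weights.shape[0]

    def memberships(self, sd_mult: float = 2.0) -> list[np.ndarray]:
        """Units whose |weight| exceeds ``sd_mult`` SD of that motif's weights."""
        out = []
        for w in self.weights:
            out.append(np.flatnonzero(np.abs(w) > sd_mult * w.std()))
        return out


def extract_motifs(
    pvs, *, event_class=None, seed=None, n_restarts: int = 10, zscore: bool = True
) -> MotifSet:
    """Extract significant coactivity motifs from a unit x event matrix.

    Eigenvalues of the correlation matrix of the z-scored counts are
    compared with the Marcenko-Pastur edge; FastICA (best of ``n_restarts``
    seeds by negentropy) runs on the data projected onto the significant
    PCA subspace. Component signs are fixed so the largest-magnitude weight
    is positive. Zero significant eigenvalues yields an empty motif set.
    """
    X = np.asarray(pvs, dtype=float)
    n_units, n_events = X.shape
    if n_units < 10:
        raise ValueError("need at least 10 units")
    if n_events <= n_units:
        warnings.warn("fewer events than units; Marcenko-Pastur threshold unreliable")
    Z = zscore_rows(X) if zscore else np.asarray(X, dtype=float)
    corr = (Z @ Z.T) / n_events
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam_max = marchenko_pastur_threshold(n_units, n_events)
    n_sig = int(np.sum(evals > lam_max))
    if n_sig == 0:
        return MotifSet(
            weights=np.empty((0, n_units)),
            threshold=lam_max,
            eigenvalues=evals,
            event_class=event_class,
        )

    basis = evecs[:, :n_sig]  # n_units x n_sig
    proj = basis.T @ Z  # n_sig x n_events
    if n_sig == 1:
        w = basis[:, 0]
        weights = (w / np.linalg.norm(w))[None, :]
    else:
        rng = np.random.default_rng(seed)
        best_W, best_score = None, -np.inf
        for _ in range(n_restarts):
            ica = FastICA(
                n_components=n_sig,
                random_state=int(rng.integers(0, 2**31 - 1)),
                max_iter=1000,
                whiten="unit-variance",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sources = ica.fit_transform(proj.T)  # events x n_sig
            # negentropy proxy: mean |kurtosis| of the recovered sources
            k = np.mean(np.abs(_kurtosis(sources)))
            if k > best_score:
                best_score, best_W = k, ica.components_ @ basis.T
        weights = best_W
        weights = weights / np.linalg.norm(weights, axis=1, keepdims=True)
    # sign convention: largest-magnitude weight positive
    for w in weights:
        if w[np.argmax(np.abs(w))] < 0:
            w *= -1.0
    return MotifSet(
        weights=weights, threshold=lam_max, eigenvalues=evals, event_class=event_class
    )


def _kurtosis(sources) -> np.ndarray:
    s = (sources - sources.mean(axis=0)) / np.maximum(sources.std(axis=0), 1e-12)
    return (s**4).mean(axis=0) - 3.0


def motif_activation(motif_weights, z_pvs, exclude_unit: int | None = None) -> np.ndarray:
    """Per-event motif activation: inner product of weights and z-scored PV.

    ``exclude_unit`` zeroes that unit's weight first (leave-one-neuron-out),
    making the activation independent of the excluded unit's own count.
    """
    w = np.array(motif_weights, dtype=float, copy=True)
    Z = np.atleast_2d(np.asarray(z_pvs, dtype=float))
    if w.size != Z.shape[0]:
        raise ValueError("weight vector and PV unit dimension mismatch")
    if exclude_unit is not None:
        w[exclude_unit] = 0.0
    return w @ Z


def _unit_motif_correlations(weights, Z) -> np.ndarray:
    """corr(unit activity, leave-that-unit-out activation), unit x motif."""
    n_units = Z.shape[0]
    n_motifs = weights.shape[0]
    out = np.full((n_units, n_motifs), np.nan)
    for m in range(n_motifs):
        for u in range(n_units):
            act = motif_activation(weights[m], Z, exclude_unit=u)
            x = Z[u]
            if x.std() == 0 or act.std() == 0:
                continue
            out[u, m] = np.corrcoef(x, act)[0, 1]
    return out


def contribution_gain(
    motifs: MotifSet,
    pvs_lm,
    pvs_rad,
    n_surrogates: int = 500,
    *,
    seed=None,
) -> dict:
    """Per-(unit, motif) contribution gain from LM to Rad events.

    The gain is the unit's correlation with the leave-that-unit-out motif
    activation in Rad events minus the same correlation in LM events
    (motifs extracted from LM events). The surrogate distribution repeats
    the computation on margin-preserving shuffles of each class, so rate
    and sparsity differences are controlled. Returns a dict with ``gain``
    (unit x motif), ``z`` (surrogate z-score), ``lo``/``hi`` (surrogate 2.5
    / 97.5 percentiles) and ``significant`` (gain above the 97.5th
    percentile).
    """
    L = np.asarray(pvs_lm, dtype=float)
    R = np.asarray(pvs_rad, dtype=float)
    if motifs.n_motifs == 0:
        raise ValueError("no motifs to evaluate")
    rng = np.random.default_rng(seed)
    ZL, ZR = zscore_rows(L), zscore_rows(R)
    silent = (L.std(axis=1) == 0) | (R.std(axis=1) == 0)

    gain = _unit_motif_correlations(motifs.weights, ZR) - _unit_motif_correlations(
        motifs.weights, ZL
    )
    gain[silent] = np.nan

    Li, Ri = L.astype(int), R.astype(int)
    surr = np.empty((n_surrogates,) + gain.shape)
    for s in range(n_surrogates):
        Ls = zscore_rows(margin_preserving_shuffle(Li, rng=rng).astype(float))
        Rs = zscore_rows(margin_preserving_shuffle(Ri, rng=rng).astype(float))
        surr[s] = _unit_motif_correlations(motifs.weights, Rs) - _unit_motif_correlations(
            motifs.weights, Ls
        )
    lo, hi = np.nanpercentile(surr, [2.5, 97.5], axis=0)
    mu = np.nanmean(surr, axis=0)
    sd = np.nanstd(surr, axis=0)
    sd[sd == 0] = np.nan
    return {
        "gain": gain,
        "z": (gain - mu) / sd,
        "lo": lo,
        "hi": hi,
        "significant": gain > hi,
    }


def aggregated_count(
    gain_result: dict,
    motifs: MotifSet | None = None,
    *,
    seed=None,
    n_draws: int = 1000,
) -> dict:
    """Observed count of aggregated units vs the surrogate expectation.

    A unit is "aggregated" onto a motif when it is *not* a member of that
    motif (membership by the 2-SD weight rule, when ``motifs`` is given)
    yet its contribution gain exceeds the surrogate 97.5th percentile.
    Under the surrogate null each tested (unit, motif) cell is significant
    with probability 2.5%, so the expected-count distribution is binomial
    over the tested cells; the p-value is the binomial tail probability of
    the observed count.
    """
    sig = gain_result["significant"]
    tested = np.isfinite(gain_result["gain"])
    if motifs is not None:
        for m, members in enumerate(motifs.memberships()):
            tested[members, m] = False
    n_cells = int(tested.sum())
    observed = int(np.sum(sig & tested))
    from scipy import stats as sstats

    p_null = 0.025
    expected = sstats.binom(n_cells, p_null)
    rng = np.random.default_rng(seed)
    return {
        "observed": observed,
        "expected_mean": float(expected.mean()),
        "expected_draws": rng.binomial(n_cells, p_null, size=n_draws),
        "p": float(expected.sf(observed - 1)) if n_cells else float("nan"),
        "n_tested": n_cells,
    }
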