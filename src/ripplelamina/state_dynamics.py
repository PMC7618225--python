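"""Up/Down state inference and the temporal organisation of ripple types.

The dentate-gyrus molecular-layer CSD energy (a proxy for entorhinal drive)
is bimodal during sleep; a two-component Gaussian mixture initialises a
two-state hidden Markov model whose Viterbi path segments the session into
Up and Down epochs. Ripple types are then related to that state sequence,
to chains of closely spaced ripples (Markov transition matrices with
label-shuffle normalisation), and to normalised time within NREM bouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import ndimage, stats
from sklearn.mixture import GaussianMixture

RIPPLE_CLASSES = ("Rad", "intermediate", "LM")


def dg_energy(csd, dg_channels, fs: float, out_fs: float = 5.0) -> np.ndarray:
    """Z-scored DG molecular-layer CSD energy series at 5 Hz.

    Mean rectified CSD over the molecular-layer channels, smoothed with a
    1-s median filter, block-averaged down to ``out_fs`` and z-scored.
    """
    csd = np.asarray(csd, dtype=float)
    dg_channels = np.asarray(dg_channels, dtype=int)
    if dg_channels.size == 0:
        raise ValueError("no DG molecular channels")
    energy = np.abs(csd[dg_channels]).mean(axis=0)
    k = int(round(fs))
    energy = ndimage.median_filter(energy, size=k, mode="nearest")
    step = int(round(fs / out_fs))
    n = energy.size // step
    energy = energy[: n * step].reshape(n, step).mean(axis=1)
    sd = energy.std()
    if sd == 0:
        import warnings

        warnings.warn("constant energy series; z-score degenerate")
        return np.zeros_like(energy)
    return (energy - energy.mean()) / sd


@dataclass
class StateSequence:
    """Per-sample Up/Down decoding with its epoch table."""

    states: np.ndarray  # 1 = Up, 0 = Down, per 5-Hz sample
    fs_hz: float
    epochs: pd.DataFrame  # state, start_s, end_s, duration_s
    low_confidence: bool
    separation_sd: float

    def n_epochs(self, state: str) -> int:
        return int((self.epochs["state"] == state).sum())

    def usable(self, min_epochs: int = 100) -> bool:
        """Session inclusion rule: at least ``min_epochs`` Up and Down epochs."""
        return self.n_epochs("Up") >= min_epochs and self.n_epochs("Down") >= min_epochs

    def state_at(self, times_s) -> np.ndarray:
        idx = np.clip(
            (np.asarray(times_s, dtype=float) * self.fs_hz).astype(int),
            0,
            self.states.size - 1,
        )
        return self.states[idx]


def _epochs_from_states(states, fs) -> pd.DataFrame:
    edges = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [states.size]])
    df = pd.DataFrame(
        {
            "state": np.where(states[starts] == 1, "Up", "Down"),
            "start_s": starts / fs,
            "end_s": ends / fs,
        }
    )
    df["duration_s"] = df["end_s"] - df["start_s"]
    return df


def infer_updown(
    energy, fs_hz: float = 5.0, *, seed: int = 0, n_restarts: int = 10
) -> StateSequence:
    """Infer Up/Down states from the DG energy series (GMM-initialised HMM).

    A two-component Gaussian mixture on the energy distribution initialises
    the emission model of a two-state Gaussian HMM; the Viterbi path is
    decoded and the higher-mean state labelled Up. The HMM transition matrix
    is initialised uniformly with ``n_restarts`` random restarts, keeping
    the best likelihood. A mixture separation below 0.5 pooled SD flags the
    segmentation as low confidence. Labels are invariant to affine
    rescaling of the energy (up to the shared z-scoring convention).
    """
    energy = np.asarray(energy, dtype=float).reshape(-1, 1)
    if energy.size < 100:
        raise ValueError("need at least 100 samples")
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(energy)
    mu = gmm.means_.ravel()
    sd = np.sqrt(gmm.covariances_).ravel()
    separation = abs(mu[0] - mu[1]) / sd.mean()
    # a 2-component fit on unimodal data splits it into overlapping halves
    # that can look separated; require the mixture to beat one component
    gmm1 = GaussianMixture(n_components=1, random_state=seed).fit(energy)
    low_conf = separation < 0.5 or gmm1.bic(energy) <= gmm.bic(energy)

    best = None
    best_ll = -np.inf
    for r in range(n_restarts):
        hmm = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=50,
            random_state=seed + r,
        )
        hmm.startprob_ = np.array([0.5, 0.5])
        jitter = 0.1 * np.random.default_rng(seed + r).random()
        hmm.transmat_ = np.array(
            [[0.5 + jitter, 0.5 - jitter], [0.5 - jitter, 0.5 + jitter]]
        )
        hmm.means_ = gmm.means_.copy()
        hmm.covars_ = np.maximum(gmm.covariances_.reshape(2, 1), 1e-6)
        try:
            hmm.fit(energy)
            ll = hmm.score(energy)
        except ValueError:
            continue
        if ll > best_ll:
            best_ll, best = ll, hmm
    if best is None:
        raise RuntimeError("HMM fitting failed on all restarts")
    path = best.predict(energy)
    up_state = int(np.argmax(best.means_.ravel()))
    states = (path == up_state).astype(int)
    return StateSequence(
        states=states,
        fs_hz=fs_hz,
        epochs=_epochs_from_states(states, fs_hz),
        low_confidence=bool(low_conf),
        separation_sd=float(separation),
    )


def lm_proportion_by_state(
    ripple_times,
    ripple_labels,
    seq: StateSequence,
    energy=None,
    *,
    n_bins: int = 10,
    energy_range: tuple[float, float] = (-2.5, 2.5),
    min_epoch_s: float = 0.5,
    include_intermediate: bool = False,
) -> dict:
    """Proportion of LM ripples per Up/Down state and per energy bin.

    Each ripple is assigned the state (and optionally the z-scored energy
    bin) at its peak. The proportion is LM / (LM + Rad) unless
    ``include_intermediate`` adds intermediate events to the denominator.
    Only ripples falling in state epochs of at least ``min_epoch_s`` count.
    Empty bins return NaN.
    """
    t = np.asarray(ripple_times, dtype=float)
    labels = np.asarray(ripple_labels)
    denom_mask = (
        np.isin(labels, ("Rad", "LM", "intermediate"))
        if include_intermediate
        else np.isin(labels, ("Rad", "LM"))
    )

    # epoch duration per ripple
    ep = seq.epochs
    ep_idx = np.searchsorted(ep["start_s"].to_numpy(), t, side="right") - 1
    ep_idx = np.clip(ep_idx, 0, len(ep) - 1)
    long_enough = ep["duration_s"].to_numpy()[ep_idx] >= min_epoch_s
    use = denom_mask & long_enough
    state = seq.state_at(t)

    def prop(mask):
        n_den = int(np.sum(mask))
        if n_den == 0:
            return float("nan")
        return float(np.sum(labels[mask] == "LM") / n_den)

    out = {
        "Up": prop(use & (state == 1)),
        "Down": prop(use & (state == 0)),
    }
    if energy is not None:
        energy = np.asarray(energy, dtype=float)
        idx = np.clip((t * seq.fs_hz).astype(int), 0, energy.size - 1)
        e_at = energy[idx]
        edges = np.linspace(*energy_range, n_bins + 1)
        props = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            props.append(prop(use & (e_at >= lo) & (e_at < hi)))
        out["energy_bin_edges"] = edges
        out["energy_bin_proportion"] = np.asarray(props)
    return out


def ripple_chains(ripple_times, max_gap_ms: float = 250.0) -> list[np.ndarray]:
    """Maximal runs of ripples with inter-event gaps below ``max_gap_ms``.

    Returns a list of index arrays into the (sorted) input times.
    """
    t = np.asarray(ripple_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("ripple times must be sorted")
    if t.size == 0:
        return []
    gaps = np.diff(t)
    breaks = np.flatnonzero(gaps >= max_gap_ms * 1e-3) + 1
    return [np.arange(a, b) for a, b in zip(np.r_[0, breaks], np.r_[breaks, t.size])]


def chain_length_histogram(chains) -> pd.DataFrame:
    lengths = np.array([len(c) for c in chains])
    vals, counts = np.unique(lengths, return_counts=True)
    return pd.DataFrame({"chain_length": vals, "count": counts})


@dataclass
class TransitionMatrix:
    """Raw and shuffle-normalised ripple-type transition probabilities."""

    classes: tuple
    raw: np.ndarray  # P(next | previous), rows = previous
    normalized: np.ndarray  # raw minus label-shuffle mean
    counts: np.ndarray


def transition_matrix(
    chain_labels: list,
    *,
    classes: tuple = RIPPLE_CLASSES,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> TransitionMatrix:
    """Markov transition matrix over within-chain consecutive ripple pairs.

    ``chain_labels`` is a list of label sequences, one per chain. Raw rows
    (with observations) sum to 1. The normalised matrix subtracts the mean
    over ``n_shuffles`` label shuffles that preserve the per-class totals.
    """
    pairs = []
    flat = []
    for labs in chain_labels:
        labs = list(labs)
        flat.extend(labs)
        pairs.extend(zip(labs[:-1], labs[1:]))
    if not pairs:
        raise ValueError("no consecutive pairs in chains")
    cls_idx = {c: i for i, c in enumerate(classes)}

    def count_matrix(pair_list):
        m = np.zeros((len(classes), len(classes)))
        for a, b in pair_list:
            m[cls_idx[a], cls_idx[b]] += 1
        return m

    def to_prob(m):
        rs = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rs > 0, m / rs, np.nan)
        return p

    counts = count_matrix(pairs)
    raw = to_prob(counts)

    rng = np.random.default_rng(seed)
    flat = np.asarray(flat, dtype=object)
    lengths = [len(labs) for labs in chain_labels]
    shuffled_sum = np.zeros_like(counts)
    for _ in range(n_shuffles):
        perm = rng.permutation(flat)
        sp = []
        i = 0
        for ln in lengths:
            seg = perm[i : i + ln]
            sp.extend(zip(seg[:-1], seg[1:]))
            i += ln
        shuffled_sum += to_prob(count_matrix(sp))
    normalized = raw - shuffled_sum / n_shuffles
    return TransitionMatrix(classes=tuple(classes), raw=raw, normalized=normalized, counts=counts)


def nrem_occurrence_profile(
    ripple_times,
    ripple_labels,
    nrem_bouts: pd.DataFrame,
    *,
    n_bins: int = 5,
    n_shuffles: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Ripple-type occurrence over normalised NREM time.

    Each NREM bout (>= 10 s) is divided into ``n_bins`` equal bins; per bout
    and ripple type the proportion of that type's events per bin is
    computed (rows sum to 1). The concatenated per-bout profiles are
    correlated with the bin index and tested against ``n_shuffles`` shuffles
    of the time-bin assignment. Returns per-type mean profiles,
    correlations and permutation p-values.
    """
    t = np.asarray(ripple_times, dtype=float)
    labels = np.asarray(ripple_labels)
    rng = np.random.default_rng(seed)
    bouts = nrem_bouts[nrem_bouts["duration_s"] >= 10.0] if "duration_s" in nrem_bouts else nrem_bouts

    out = {}
    for klass in np.unique(labels):
        profiles = []
        for _, b in bouts.iterrows():
            m = (labels == klass) & (t >= b["start_s"]) & (t < b["end_s"])
            if not m.any():
                continue
            frac = (t[m] - b["start_s"]) / (b["end_s"] - b["start_s"])
            hist, _ = np.histogram(frac, bins=n_bins, range=(0, 1))
            profiles.append(hist / hist.sum())
        if not profiles:
            out[str(klass)] = {"profile": np.full(n_bins, np.nan), "r": np.nan, "p": np.nan}
            continue
        prof = np.asarray(profiles)
        y = prof.ravel()
        x = np.tile(np.arange(n_bins), prof.shape[0]).astype(float)
        r_obs = stats.pearsonr(x, y).statistic
        # permutation null: only the x-y pairing changes, so r reduces to a
        # dot product of the permuted centred x with the centred y
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            null[i] = np.dot(rng.permutation(xc), yc) / denom
        p = float(np.mean(np.abs(null) >= abs(r_obs)))
        out[str(klass)] = {"profile": prof.mean(axis=0), "r": float(r_obs), "p": p}
    return out
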