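"""Predicting the laminar CSD class of a ripple from its pyramidal-layer LFP.

The 200-ms peri-peak pyramidal-layer trace of each ripple is low-pass
filtered at 30 Hz (isolating the sharp-wave component), z-scored per trace
and reduced to a 6-component PCA embedding. Those features support (a)
per-layer linear regressions quantifying how much of the laminar CSD the
waveform explains (cross-validated R^2 against a CSD-shuffle chance level)
and (b) a three-class LDA classifier (Rad / intermediate / LM, ground truth
from the normalised lacunosum-moleculare CSD) validated with
leave-one-subject-out cross-validation, class balancing and label-shuffled
null models. All preprocessing statistics (z-score is per trace; the PCA
basis) are fit on training data only within each fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LinearRegression

from ripplelamina.signal_processing import lowpass

N_WAVEFORM_COMPONENTS = 6


class WaveformPreprocessor:
    """Low-pass (30 Hz) -> per-trace z-score -> PCA to 6 components."""

    def __init__(self, fs: float, cutoff_hz: float = 30.0, n_components: int = N_WAVEFORM_COMPONENTS):
        self.fs = fs
        self.cutoff_hz = cutoff_hz
        self.n_components = n_components
        self.pca_: PCA | None = None

    def _filter_zscore(self, traces) -> np.ndarray:
        X = np.atleast_2d(np.asarray(traces, dtype=float))
        if X.ndim != 2:
            raise ValueError("traces must be a ripple x time matrix of equal lengths")
        X = lowpass(X, self.cutoff_hz, self.fs)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    def fit(self, traces) -> "WaveformPreprocessor":
        Z = self._filter_zscore(traces)
        self.pca_ = PCA(n_components=min(self.n_components, *Z.shape)).fit(Z)
        return self

    def transform(self, traces) -> np.ndarray:
        if self.pca_ is None:
            raise RuntimeError("preprocessor not fitted")
        return self.pca_.transform(self._filter_zscore(traces))

    def fit_transform(self, traces) -> np.ndarray:
        return self.fit(traces).transform(traces)


def preprocess_waveforms(ripple_lfp_traces, fs: float) -> np.ndarray:
    """Six-component PCA embedding of low-passed, z-scored peri-peak traces."""
    return WaveformPreprocessor(fs).fit_transform(ripple_lfp_traces)


def extract_peri_peak_traces(lfp, fs: float, peak_times, window_s: float = 0.200):
    """Fixed-length peri-peak LFP traces; returns (traces, kept indices)."""
    lfp = np.asarray(lfp, dtype=float)
    half = int(round(window_s / 2 * fs))
    traces, kept = [], []
    for i, t in enumerate(np.asarray(peak_times, dtype=float)):
        c = int(round(t * fs))
        if c - half < 0 or c + half > lfp.size:
            continue
        traces.append(lfp[c - half : c + half])
        kept.append(i)
    return np.asarray(traces), np.asarray(kept, dtype=int)


def explain_csd_from_lfp(
    features,
    csd_by_layer: dict,
    *,
    n_splits: int = 20,
    test_frac: float = 0.2,
    n_shuffles: int = 500,
    seed: int | None = None,
) -> dict:
    """Cross-validated R^2 of per-layer CSD predicted from waveform features.

    ``csd_by_layer`` maps layer name to a per-ripple scalar (unit-variance
    normalised CSD). For each layer, a linear regression is evaluated on
    ``n_splits`` random 80/20 splits; chance comes from refitting on
    CSD-shuffled targets. Returns a dict layer -> {"r2", "chance_mean",
    "chance_hi"} where ``chance_hi`` is the 97.5th percentile of the shuffle
    distribution.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 ripples")
    rng = np.random.default_rng(seed)
    splits = []
    n_test = max(1, int(round(test_frac * n)))
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append((perm[n_test:], perm[:n_test]))

    def cv_r2(y, split_list):
        scores = []
        for tr, te in split_list:
            model = LinearRegression().fit(X[tr], y[tr])
            pred = model.predict(X[te])
            sst = np.sum((y[te] - y[te].mean()) ** 2)
            if sst == 0:
                continue
            scores.append(1.0 - np.sum((y[te] - pred) ** 2) / sst)
        return float(np.mean(scores))

    out = {}
    for layer, y in csd_by_layer.items():
        y = np.asarray(y, dtype=float)
        r2 = cv_r2(y, splits)
        chance = np.empty(n_shuffles)
        for s in range(n_shuffles):
            ys = rng.permutation(y)
            tr, te = splits[s % n_splits]
            model = LinearRegression().fit(X[tr], ys[tr])
            pred = model.predict(X[te])
            sst = np.sum((ys[te] - ys[te].mean()) ** 2)
            chance[s] = 1.0 - np.sum((ys[te] - pred) ** 2) / sst if sst > 0 else 0.0
        out[layer] = {
            "r2": r2,
            "chance_mean": float(chance.mean()),
            "chance_hi": float(np.percentile(chance, 97.5)),
        }
    return out


@dataclass
class ClassifierReport:
    """Leave-one-subject-out LDA validation summary.

    ``gain_pct`` is the chance-normalised accuracy gain per fold,
    ``100 * (mean true accuracy - mean null accuracy) / mean null accuracy``.
    """

    fold_subjects: list = field(default_factory=list)
    true_accuracy: np.ndarray = None
    null_accuracy: np.ndarray = None
    gain_pct: np.ndarray = None
    final_model: "RippleLDAModel | None" = None

    @property
    def mean_gain_pct(self) -> float:
        return float(np.mean(self.gain_pct))


@dataclass
class RippleLDAModel:
    """Portable LDA classifier over waveform features (no pickled code)."""

    preprocessor: WaveformPreprocessor
    lda: LinearDiscriminantAnalysis

    def predict(self, traces) -> np.ndarray:
        return self.lda.predict(self.preprocessor.transform(traces))

    def to_json(self, path) -> None:
        payload = {
            "fs": self.preprocessor.fs,
            "cutoff_hz": self.preprocessor.cutoff_hz,
            "pca_mean": self.preprocessor.pca_.mean_.tolist(),
            "pca_components": self.preprocessor.pca_.components_.tolist(),
            "classes": list(self.lda.classes_),
            "coef": self.lda.coef_.tolist(),
            "intercept": self.lda.intercept_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _balanced_indices(labels, rng) -> np.ndarray:
    classes, counts = np.unique(labels, return_counts=True)
    m = counts.min()
    idx = [rng.choice(np.flatnonzero(labels == c), size=m, replace=False) for c in classes]
    return np.concatenate(idx)


def train_ripple_lda(
    traces,
    labels,
    subject_ids,
    fs: float,
    *,
    n_repeats: int = 100,
    seed: int | None = None,
    fit_final: bool = True,
) -> ClassifierReport:
    """Leave-one-subject-out LDA with class balancing and shuffled nulls.

    For each left-out subject the preprocessor and classifier are fit on the
    remaining subjects; training classes are downsampled to the smallest
    class, ``n_repeats`` times; each repeat also trains a label-shuffled null
    model. Subjects missing a class in their training set are skipped with a
    warning. When ``fit_final`` is true, a model trained on all subjects
    (balanced once) is attached for downstream use.
    """
    traces = np.asarray(traces, dtype=float)
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if subjects.size < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)

    fold_subjects, acc_true, acc_null = [], [], []
    for s in subjects:
        test = subject_ids == s
        train = ~test
        if np.unique(labels[train]).size < classes.size:
            warnings.warn(f"subject {s!r}: training folds missing a class; skipped")
            continue
        pre = WaveformPreprocessor(fs).fit(traces[train])
        Xtr = pre.transform(traces[train])
        Xte = pre.transform(traces[test])
        ytr, yte = labels[train], labels[test]
        t_acc = np.empty(n_repeats)
        n_acc = np.empty(n_repeats)
        for r in range(n_repeats):
            idx = _balanced_indices(ytr, rng)
            lda = LinearDiscriminantAnalysis().fit(Xtr[idx], ytr[idx])
            t_acc[r] = np.mean(lda.predict(Xte) == yte)
            y_shuf = rng.permutation(ytr[idx])
            lda0 = LinearDiscriminantAnalysis().fit(Xtr[idx], y_shuf)
            n_acc[r] = np.mean(lda0.predict(Xte) == yte)
        fold_subjects.append(s)
        acc_true.append(t_acc.mean())
        acc_null.append(n_acc.mean())

    acc_true = np.asarray(acc_true)
    acc_null = np.asarray(acc_null)
    gain = 100.0 * (acc_true - acc_null) / acc_null

    final = None
    if fit_final:
        pre = WaveformPreprocessor(fs).fit(traces)
        X = pre.transform(traces)
        idx = _balanced_indices(labels, rng)
        final = RippleLDAModel(
            preprocessor=pre,
            lda=LinearDiscriminantAnalysis().fit(X[idx], labels[idx]),
        )
    return ClassifierReport(
        fold_subjects=fold_subjects,
        true_accuracy=acc_true,
        null_accuracy=acc_null,
        gain_pct=gain,
        final_model=final,
    )


def validate_predicted_csd(
    csd_windows_train,
    pred_train,
    csd_windows_test,
    pred_test,
    layer_map,
    fs: float,
    *,
    window_s: float = 0.010,
) -> dict:
    """Per-class mean CSD at sink-optimal lags on held-out ripples.

    ``csd_windows_*`` are event x interior-channel x time arrays centred on
    the ripple peak (unit-variance CSD). Sink lags are estimated on the
    training set: the LM class is aligned to the deepest lacunosum-moleculare
    sink, other classes to the deepest radiatum sink. Returns a dict
    ``class -> {"radiatum": mean, "lacunosum-moleculare": mean}`` using 10-ms
    windows at those lags; classes with no test members map to NaN.
    """
    from ripplelamina.csd_profiles import interior_layer_map

    tr = np.asarray(csd_windows_train, dtype=float)
    te = np.asarray(csd_windows_test, dtype=float)
    pred_train = np.asarray(pred_train)
    pred_test = np.asarray(pred_test)
    inner = interior_layer_map(layer_map)
    rad = np.flatnonzero(inner == "radiatum")
    lm = np.flatnonzero(inner == "lacunosum-moleculare")
    n_t = tr.shape[2]
    half = max(1, int(round(window_s / 2 * fs)))

    def sink_lag(klass, chans):
        m = pred_train == klass
        if not m.any():
            return n_t // 2
        prof = tr[m][:, chans, :].mean(axis=(0, 1))
        return int(np.argmin(prof))

    out = {}
    for klass in np.unique(np.concatenate([pred_train, pred_test])):
        chans = lm if klass == "LM" else rad
        lag = sink_lag(klass, chans)
        sl = slice(max(0, lag - half), min(n_t, lag + half))
        m = pred_test == klass
        if not m.any():
            out[str(klass)] = {"radiatum": float("nan"), "lacunosum-moleculare": float("nan")}
            continue
        out[str(klass)] = {
            "radiatum": float(te[m][:, rad, sl].mean()),
            "lacunosum-moleculare": float(te[m][:, lm, sl].mean()),
        }
    return out


def discrimination_index(predictions, truth) -> float:
    """Conservative Rad/LM discrimination ratio.

    For each of the two extreme classes, the ratio of correctly classified
    events to events misclassified as the opposite class; the smaller of the
    two ratios is returned. ``inf`` when neither class has opposite-type
    errors.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    ratios = []
    for klass, other in (("Rad", "LM"), ("LM", "Rad")):
        m = truth == klass
        correct = np.sum(predictions[m] == klass)
        swapped = np.sum(predictions[m] == other)
        ratios.append(np.inf if swapped == 0 else correct / swapped)
    return float(min(ratios))
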