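"""Per-ripple CSD signatures and Rad/intermediate/LM laminar classes.

The current source density (CSD) at channel *n* is the negated second
spatial difference of the laminar LFP, ``-(LFP[n-1] - 2*LFP[n] + LFP[n+1])``;
negative values mark current sinks. Each ripple's *CSD signature* is the
time-mean CSD per interior channel over the 50-ms window centred on the
ripple-envelope peak (computed on Gaussian-smoothed CSD so that probes with
different channel spacing have matched spatial resolution). Ripples are
labelled along the laminar continuum either by the dominant-sink layer, by
the first principal component of the signatures (30th/70th percentile rule),
or by the normalised lacunosum-moleculare CSD (the ground truth used by the
waveform classifier).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

CLASS_RAD = "Rad"
CLASS_INT = "intermediate"
CLASS_LM = "LM"
SINK_LAYERS = ("oriens", "pyramidale", "radiatum", "lacunosum-moleculare")


def compute_csd(lfp_window) -> np.ndarray:
    """Negated second spatial difference; interior channels only.

    Input is a channel x time matrix (>= 3 channels); the output has
    ``n_channels - 2`` rows, one per interior channel. Negative = sink.
    """
    lfp = np.atleast_2d(np.asarray(lfp_window, dtype=float))
    if lfp.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    return -(lfp[:-2] - 2.0 * lfp[1:-1] + lfp[2:])


def smooth_laminar(csd, spacing_um: float, sigma_um: float = 50.0) -> np.ndarray:
    """Gaussian smoothing along the channel axis (sigma in micrometres).

    The kernel standard deviation is expressed in channel units as
    ``sigma_um / spacing_um``; boundaries are handled by reflection. Equalises
    the spatial resolution of probes with different channel spacing.
    """
    csd = np.asarray(csd, dtype=float)
    if sigma_um <= 0:
        return csd.copy()
    sigma_ch = sigma_um / spacing_um
    if csd.ndim == 1:
        return ndimage.gaussian_filter1d(csd, sigma_ch, mode="reflect")
    return ndimage.gaussian_filter1d(csd, sigma_ch, axis=0, mode="reflect")


def signature(
    csd,
    fs: float,
    peak_time_s: float,
    window_s: float = 0.050,
) -> np.ndarray:
    """Time-mean CSD per interior channel over the peak-centred window.

    The window is half-open, ``[peak - window/2, peak + window/2)``. Events
    whose window exceeds the record edge are skipped (returns None with a
    warning).
    """
    csd = np.asarray(csd, dtype=float)
    i0 = int(round((peak_time_s - window_s / 2) * fs))
    i1 = i0 + int(round(window_s * fs))
    if i0 < 0 or i1 > csd.shape[1]:
        warnings.warn(f"event at {peak_time_s:.3f}s too close to record edge; skipped")
        return None
    return csd[:, i0:i1].mean(axis=1)


def event_signatures(
    recording,
    peak_times,
    *,
    window_s: float = 0.050,
    sigma_um: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """CSD signatures for a set of ripple peaks on a laminar recording.

    Computes the full-session CSD, smooths it along the laminar axis and
    averages the peak-centred window per event. Returns ``(signatures,
    kept)`` where ``signatures`` is an event x interior-channel matrix and
    ``kept`` indexes the events that fit within the record.
    """
    csd = compute_csd(recording.data)
    csd = smooth_laminar(csd, recording.spacing_um, sigma_um)
    sigs, kept = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, t in enumerate(np.asarray(peak_times, dtype=float)):
            sig = signature(csd, recording.fs_hz, t, window_s)
            if sig is not None:
                sigs.append(sig)
                kept.append(i)
    return np.asarray(sigs), np.asarray(kept, dtype=int)


def interior_layer_map(layer_map) -> np.ndarray:
    """Layer labels of the interior channels (channel 1 .. n-2)."""
    return np.asarray(layer_map)[1:-1]


def dominant_sink_layer(sig, layer_map) -> str:
    """Layer of the most negative signature value among the CA1 strata.

    ``layer_map`` is the full channel layer map; only interior channels
    belonging to the CA1 strata (oriens, pyramidale, radiatum,
    lacunosum-moleculare) compete. Returns ``"no sink"`` when the minimum is
    non-negative.
    """
    sig = np.asarray(sig, dtype=float)
    inner = interior_layer_map(layer_map)
    if sig.shape[0] != inner.shape[0]:
        raise ValueError("signature length must equal n_channels - 2")
    mask = np.isin(inner, SINK_LAYERS)
    if not mask.any():
        raise ValueError("layer_map contains no CA1 strata")
    vals = np.where(mask, sig, np.inf)
    i = int(np.argmin(vals))
    if sig[i] >= 0:
        return "no sink"
    return str(inner[i])


def pca_signatures(
    signatures, layer_map=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the ripple x channel signature matrix with a fixed sign rule.

    Returns ``(components, variance_explained, pc1_strengths)``. Components
    are rows (channel loadings); ``variance_explained_i = s_i^2 / sum s_j^2``
    sums to 1. When ``layer_map`` is given, the sign of PC1 is flipped if
    needed so that its mean weight over stratum-radiatum channels is
    negative (a larger PC1 strength then means a stronger radiatum sink).
    """
    X = np.asarray(signatures, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 ripples")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("rank-0 signature matrix")
    var = s**2 / np.sum(s**2)
    strengths = u[:, 0] * s[0]
    if layer_map is not None:
        vt, strengths = orient_pc1(vt, strengths, layer_map)
    return vt, var, strengths


def orient_pc1(components, pc1_strengths, layer_map) -> tuple[np.ndarray, np.ndarray]:
    """Fix the PC1 sign so its mean stratum-radiatum weight is negative.

    With this convention a larger PC1 strength means a stronger radiatum
    sink. Returns the (possibly flipped) components and strengths.
    """
    components = np.array(components, dtype=float, copy=True)
    strengths = np.array(pc1_strengths, dtype=float, copy=True)
    inner = interior_layer_map(layer_map)
    rad = inner == "radiatum"
    if not rad.any():
        raise ValueError("no radiatum channels in layer_map")
    if components[0, rad].mean() > 0:
        components[0] *= -1.0
        strengths *= -1.0
    return components, strengths


def pca_signature_labels(signatures, layer_map):
    """Convenience: oriented PC1 strengths and percentile class labels."""
    comps, var, strengths = pca_signatures(signatures, layer_map)
    return label_by_pc1(strengths), strengths, comps, var


def label_by_pc1(pc1_strengths) -> np.ndarray:
    """30th/70th percentile labels on oriented PC1 strengths.

    Strictly above the 70th percentile -> Rad; strictly below the 30th ->
    LM; boundary ties and the middle of the distribution -> intermediate.
    """
    s = np.asarray(pc1_strengths, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("PC1 strengths must be finite")
    lo, hi = np.percentile(s, [30, 70])
    labels = np.full(s.shape, CLASS_INT, dtype=object)
    labels[s > hi] = CLASS_RAD
    labels[s < lo] = CLASS_LM
    return labels.astype(str)


def lm_csd_scores(signatures, layer_map) -> np.ndarray:
    """Normalised lacunosum-moleculare CSD score per ripple.

    Mean signature over the central LM channel and its two neighbours,
    divided by the standard deviation of that mean across events (polarity
    preserved). Raises on a zero SD (identical events).
    """
    X = np.asarray(signatures, dtype=float)
    inner = interior_layer_map(layer_map)
    lm_idx = np.flatnonzero(inner == "lacunosum-moleculare")
    if lm_idx.size == 0:
        raise ValueError("no lacunosum-moleculare channels in layer_map")
    centre = int(lm_idx[lm_idx.size // 2])
    chans = [c for c in (centre - 1, centre, centre + 1) if 0 <= c < X.shape[1]]
    if len(chans) < 3:
        warnings.warn("LM channel at array edge; using available neighbours")
    raw = X[:, chans].mean(axis=1)
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero variance across events; cannot normalise LM CSD")
    return raw / sd


def label_by_lm_csd(signatures, layer_map) -> tuple[np.ndarray, np.ndarray]:
    """Percentile classes from the normalised LM CSD (classifier ground truth).

    The lowest 30% of scores (strongest LM sinks) -> LM; the top 30% -> Rad;
    the rest -> intermediate. Returns ``(labels, scores)``.
    """
    scores = lm_csd_scores(signatures, layer_map)
    lo, hi = np.percentile(scores, [30, 70])
    labels = np.full(scores.shape, CLASS_INT, dtype=object)
    labels[scores < lo] = CLASS_LM
    labels[scores > hi] = CLASS_RAD
    return labels.astype(str), scores
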