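"""Ripple detection, theta-cycle segmentation and sleep-state segmentation.

All filtering is zero-phase (forward-backward Butterworth) so that event
timing is unbiased. Ripples are detected on the difference between the CA1
pyramidal-layer trace and a ripple-free reference: the differential signal
is band-passed in the ripple band (80-250 Hz) and a high-frequency control
band (200-500 Hz), the Hilbert envelope is thresholded at five times its
median, nearby peaks are merged, and candidates are validated by four
criteria (power relative to the reference channel, mean frequency, cycle
count, and ripple-band versus control-band power).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.mixture import GaussianMixture

RIPPLE_BAND = (80.0, 250.0)
CONTROL_BAND = (200.0, 500.0)

#: Phase assigned to each theta-cycle control point
#: (zero-crossing, peak, zero-crossing, trough, zero-crossing, next peak).
CONTROL_POINT_PHASES = np.array(
    [-np.pi / 2, 0.0, np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi]
)


def bandpass(x, low_hz: float, high_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter."""
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) outside (0, {nyq})")
    sos = sps.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def lowpass(x, cut_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter."""
    nyq = fs / 2.0
    if not 0 < cut_hz < nyq:
        raise ValueError(f"cutoff {cut_hz} outside (0, {nyq})")
    sos = sps.butter(order, cut_hz / nyq, btype="low", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class RippleEvent:
    peak_time_s: float
    onset_s: float
    offset_s: float
    n_cycles: float
    mean_freq_hz: float
    ripple_power: float
    valid: bool


def detect_ripples(
    lfp_pyr,
    lfp_reference,
    fs: float,
    *,
    threshold_mult: float = 5.0,
    merge_ms: float = 20.0,
    min_cycles: float = 4.0,
    min_freq_hz: float = 80.0,
) -> pd.DataFrame:
    """Detect and validate sharp-wave/ripple events.

    Returns a RippleTable DataFrame with columns ``peak_time_s, onset_s,
    offset_s, n_cycles, mean_freq_hz, ripple_power, valid``. The envelope
    threshold is ``threshold_mult`` times the session median of the
    ripple-band Hilbert envelope; peaks closer than ``merge_ms`` keep only
    the larger; onset/offset are where the envelope falls below half the
    threshold. Validation requires detection-vs-reference ripple power ratio
    >= 2, mean frequency > ``min_freq_hz``, at least ``min_cycles`` cycles
    (unwrapped phase difference onset-to-offset over 2*pi), and ripple-band
    power at least twice the 200-500 Hz control-band power.
    """
    lfp_pyr = np.asarray(lfp_pyr, dtype=float)
    lfp_reference = np.asarray(lfp_reference, dtype=float)
    if np.array_equal(lfp_pyr, lfp_reference):
        warnings.warn("reference equals detection channel; power criterion degenerate")
    diff = lfp_pyr - lfp_reference

    band = bandpass(diff, *RIPPLE_BAND, fs)
    ctrl = bandpass(diff, *CONTROL_BAND, fs)
    ref_band = bandpass(lfp_reference, *RIPPLE_BAND, fs)

    analytic = sps.hilbert(band)
    env = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))

    thr = threshold_mult * np.median(env)
    peaks, _ = sps.find_peaks(env, height=thr)
    if peaks.size == 0:
        return _empty_ripple_table()

    # merge peaks within merge_ms, keeping the larger envelope value
    merge_n = int(round(merge_ms * 1e-3 * fs))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < merge_n:
            if env[p] > env[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)

    half = thr / 2.0
    below = env < half
    rows = []
    prev_offset = -1
    for p in kept:
        left = np.flatnonzero(below[:p])
        onset = int(left[-1]) + 1 if left.size else 0
        right = np.flatnonzero(below[p:])
        offset = p + int(right[0]) - 1 if right.size else env.size - 1
        if onset <= prev_offset:  # same envelope excursion as previous peak
            if rows and env[p] <= env[int(rows[-1]["_peak_idx"])]:
                continue
            if rows:
                rows.pop()
        prev_offset = offset
        dur = (offset - onset) / fs
        if dur <= 0:
            continue
        n_cycles = (phase[offset] - phase[onset]) / (2 * np.pi)
        mean_freq = n_cycles / dur
        sl = slice(onset, offset + 1)
        power = float(np.mean(band[sl] ** 2))
        ref_power = float(np.mean(ref_band[sl] ** 2))
        ctrl_power = float(np.mean(ctrl[sl] ** 2))
        valid = (
            (ref_power <= 0 or power >= 2.0 * ref_power)
            and mean_freq > min_freq_hz
            and n_cycles >= min_cycles
            and power >= 2.0 * ctrl_power
        )
        rows.append(
            {
                "peak_time_s": p / fs,
                "onset_s": onset / fs,
                "offset_s": offset / fs,
                "n_cycles": float(n_cycles),
                "mean_freq_hz": float(mean_freq),
                "ripple_power": power,
                "valid": bool(valid),
                "_peak_idx": p,
            }
        )
    if not rows:
        return _empty_ripple_table()
    table = pd.DataFrame(rows).drop(columns="_peak_idx")
    return table.reset_index(drop=True)


def _empty_ripple_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "peak_time_s",
            "onset_s",
            "offset_s",
            "n_cycles",
            "mean_freq_hz",
            "ripple_power",
            "valid",
        ]
    )


def isolated_mask(peak_times, isolation_s: float = 0.25) -> np.ndarray:
    """True for events with no other event within ``isolation_s`` seconds."""
    t = np.asarray(peak_times, dtype=float)
    if t.size == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(t)
    ts = t[order]
    gap_prev = np.diff(ts, prepend=-np.inf)
    gap_next = np.diff(ts, append=np.inf)
    iso_sorted = (gap_prev > isolation_s) & (gap_next > isolation_s)
    out = np.empty(t.size, dtype=bool)
    out[order] = iso_sorted
    return out


def select_reference_channel(
    recording, *, window_s: float = 4.0
) -> int:
    """Channel maximising Welch ripple-band score power(80-250)/power(70-300).

    Uses 4-s Hann windows with 50% overlap. Ties resolve to the lowest
    channel index.
    """
    data = recording.data
    fs = recording.fs_hz
    nper = int(window_s * fs)
    if data.shape[1] < nper:
        raise ValueError("recording shorter than one Welch window")
    f, pxx = sps.welch(data, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    num = pxx[:, (f >= 80) & (f <= 250)].sum(axis=1)
    den = pxx[:, (f >= 70) & (f <= 300)].sum(axis=1)
    score = num / den
    return int(np.argmax(score))


def ripple_band_score(recording, *, window_s: float = 4.0) -> np.ndarray:
    """Per-channel Welch ripple-band score (see select_reference_channel)."""
    data = recording.data
    fs = recording.fs_hz
    nper = int(window_s * fs)
    if data.shape[1] < nper:
        raise ValueError("recording shorter than one Welch window")
    f, pxx = sps.welch(data, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    return pxx[:, (f >= 80) & (f <= 250)].sum(axis=1) / pxx[:, (f >= 70) & (f <= 300)].sum(
        axis=1
    )


@dataclass
class ThetaCycle:
    """Six ordered control-point times of one validated theta cycle."""

    control_points: np.ndarray  # zc, peak, zc, trough, zc, next peak (seconds)
    valid: bool = True

    @property
    def start_s(self) -> float:
        return float(self.control_points[0])

    @property
    def end_s(self) -> float:
        return float(self.control_points[-1])


def _zero_crossing(x, i0, i1, fs, rising):
    """Interpolated zero-crossing time of x in (i0, i1), or None."""
    seg = x[i0 : i1 + 1]
    s = np.sign(seg)
    if rising:
        idx = np.flatnonzero((s[:-1] <= 0) & (s[1:] > 0))
    else:
        idx = np.flatnonzero((s[:-1] >= 0) & (s[1:] < 0))
    if idx.size == 0:
        return None
    i = i0 + int(idx[0])
    x0, x1 = x[i], x[i + 1]
    frac = 0.0 if x1 == x0 else -x0 / (x1 - x0)
    return (i + frac) / fs


def segment_theta_cycles(
    theta,
    fs: float,
    low_freq_envelope=None,
    *,
    half_period_ms: tuple[float, float] = (31.0, 100.0),
    peak_to_peak_ms: tuple[float, float] = (71.0, 200.0),
) -> list[ThetaCycle]:
    """Segment a narrowband theta component into validated cycles.

    ``theta`` is a narrowband component from any decomposition backend (the
    default pipeline uses a zero-phase 5-12 Hz band-pass). Extrema whose
    magnitude does not exceed ``low_freq_envelope`` at that sample are
    discarded. A peak-trough-peak candidate is valid when both half-periods
    fall within ``half_period_ms`` and the peak-to-peak interval within
    ``peak_to_peak_ms``. Each valid cycle gets six control points:
    zero-crossing before the peak, peak, zero-crossing, trough,
    zero-crossing, next peak.
    """
    theta = np.asarray(theta, dtype=float)
    if low_freq_envelope is None:
        env = np.zeros_like(theta)
    else:
        env = np.asarray(low_freq_envelope, dtype=float)

    peaks, _ = sps.find_peaks(theta)
    troughs, _ = sps.find_peaks(-theta)
    peaks = peaks[theta[peaks] > env[peaks]]
    troughs = troughs[-theta[troughs] > env[troughs]]
    if peaks.size < 2 or troughs.size == 0:
        return []

    hp_lo, hp_hi = half_period_ms[0] * 1e-3, half_period_ms[1] * 1e-3
    pp_lo, pp_hi = peak_to_peak_ms[0] * 1e-3, peak_to_peak_ms[1] * 1e-3
    cycles: list[ThetaCycle] = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        tr = troughs[(troughs > p0) & (troughs < p1)]
        if tr.size != 1:
            continue
        tr = int(tr[0])
        t_p0, t_tr, t_p1 = p0 / fs, tr / fs, p1 / fs
        if not (hp_lo <= t_tr - t_p0 <= hp_hi and hp_lo <= t_p1 - t_tr <= hp_hi):
            continue
        if not (pp_lo <= t_p1 - t_p0 <= pp_hi):
            continue
        zc0 = _zero_crossing(theta, max(0, p0 - int(fs * hp_hi)), p0, fs, rising=True)
        zc1 = _zero_crossing(theta, p0, tr, fs, rising=False)
        zc2 = _zero_crossing(theta, tr, p1, fs, rising=True)
        if zc0 is None or zc1 is None or zc2 is None:
            continue
        cp = np.array([zc0, t_p0, zc1, t_tr, zc2, t_p1])
        if np.any(np.diff(cp) <= 0):
            continue
        cycles.append(ThetaCycle(control_points=cp))
    return cycles


def theta_phase(cycles: list[ThetaCycle], timestamps) -> np.ndarray:
    """Instantaneous theta phase by linear interpolation of control points.

    The peak maps to phase 0 and the trough to pi. Timestamps outside any
    validated cycle return NaN.
    """
    t = np.asarray(timestamps, dtype=float)
    out = np.full(t.shape, np.nan)
    for cyc in cycles:
        cp = cyc.control_points
        m = (t >= cp[0]) & (t <= cp[-1])
        if np.any(m):
            out[m] = np.interp(t[m], cp, CONTROL_POINT_PHASES)
    return out


def theta_component(lfp, fs: float, low_hz: float = 5.0, high_hz: float = 12.0) -> np.ndarray:
    """Default narrowband theta decomposition (zero-phase 5-12 Hz band-pass)."""
    return bandpass(lfp, low_hz, high_hz, fs)


def segment_nrem(
    lfp_pyr,
    speed,
    fs: float,
    *,
    window_s: float = 2.0,
    min_bout_s: float = 10.0,
    rem_min_nrem_s: float = 120.0,
    speed_sd_mult: float = 1.5,
) -> pd.DataFrame:
    """Segment a session into NREM / REM / wake epochs.

    The theta-power ratio (5-10 Hz power over 0.1-10 Hz power) is computed
    from a spectrogram with 2-s windows and 90% overlap, downsampled to
    1 Hz, and split by a two-component Gaussian mixture. NREM requires the
    low-ratio component together with speed below mean + ``speed_sd_mult``
    SD; REM is a low-speed, high-ratio epoch immediately following at least
    2 minutes of NREM; everything else is wake. Returns an epoch table with
    columns ``state, start_s, end_s, duration_s, long_enough`` partitioning
    the session (bouts shorter than ``min_bout_s`` are flagged, not
    dropped). A ``low_confidence`` attribute flags near-unimodal ratio
    distributions.
    """
    lfp_pyr = np.asarray(lfp_pyr, dtype=float)
    speed = np.asarray(speed, dtype=float)
    nper = int(window_s * fs)
    f, tt, sxx = sps.spectrogram(
        lfp_pyr, fs=fs, nperseg=nper, noverlap=int(0.9 * nper)
    )
    theta_p = sxx[(f >= 5) & (f <= 10)].sum(axis=0)
    total_p = sxx[(f >= 0.1) & (f <= 10)].sum(axis=0)
    ratio = theta_p / np.maximum(total_p, np.finfo(float).tiny)

    # downsample the ratio to a 1-Hz grid
    t_grid = np.arange(0.0, lfp_pyr.size / fs, 1.0)
    ratio_1hz = np.interp(t_grid, tt, ratio)

    gmm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(
        ratio_1hz.reshape(-1, 1)
    )
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_).ravel()
    # genuinely bimodal sessions separate by several SDs; near-identical
    # components (or a vanishing component) mean the distribution is unimodal
    low_conf = (
        abs(means[0] - means[1]) < 1.0 * sds.mean() or gmm.weights_.min() < 0.05
    )
    if low_conf:
        # near-unimodal ratio distribution: the mixture split is meaningless,
        # fall back to an absolute criterion on the theta ratio
        low_ratio = ratio_1hz < 0.5
    else:
        low_comp = int(np.argmin(means))
        comp = gmm.predict(ratio_1hz.reshape(-1, 1))
        low_ratio = comp == low_comp

    # speed per 1-s bin
    sp_t = np.arange(speed.size) / fs
    speed_1hz = np.interp(t_grid, sp_t, speed) if speed.size else np.zeros_like(t_grid)
    thr = speed_1hz.mean() + speed_sd_mult * speed_1hz.std()
    slow = speed_1hz <= thr

    state = np.where(low_ratio & slow, "NREM", np.where(slow, "REM-candidate", "wake"))

    # collapse to epochs and resolve REM candidates
    rows = []
    i = 0
    n = state.size
    while i < n:
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        rows.append({"state": state[i], "start_s": float(t_grid[i]), "end_s": float(t_grid[j - 1] + 1.0)})
        i = j
    for k, row in enumerate(rows):
        if row["state"] == "REM-candidate":
            prev = rows[k - 1] if k > 0 else None
            if (
                prev is not None
                and prev["state"] == "NREM"
                and prev["end_s"] - prev["start_s"] >= rem_min_nrem_s
            ):
                row["state"] = "REM"
            else:
                row["state"] = "wake"
    table = pd.DataFrame(rows)
    table["duration_s"] = table["end_s"] - table["start_s"]
    table["long_enough"] = table["duration_s"] >= min_bout_s
    table.attrs["low_confidence"] = bool(low_conf)
    return table
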