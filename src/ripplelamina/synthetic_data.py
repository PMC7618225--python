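"""Synthetic laminar LFP, spike sessions and state sequences with ground truth.

The generator emulates the statistical structure of dorsal-hippocampus sleep
recordings that the analysis modules assume:

* **Laminar LFP** (channel x time, microvolts) with two types of embedded
  sharp-wave/ripple events. Radiatum-type ("Rad") events carry a negative
  sharp-wave deflection peaking on stratum radiatum channels together with a
  fast ripple oscillation on the pyramidal layer. Lacunosum-moleculare-type
  ("LM") events carry a lacunosum-moleculare deflection leading the ripple
  peak by ~17 ms, a weaker radiatum deflection ~12 ms after the peak, a
  positive pyramidal-layer deflection, and a lower ripple frequency. Spatial
  profiles are Gaussian in depth, so the second spatial difference (the CSD)
  has its most negative value in the intended layer.
* **Spike sessions** spanning pre-sleep, exploration and post-sleep epochs,
  with planted coactivity motifs: a deep-biased "core" motif expressed in LM
  events, a "composite" motif (core plus superficial-biased extra units)
  expressed in Rad events, and a wake "recent" motif expressed in
  exploration theta cycles. Across post-sleep, the probability that an LM
  event expresses the prior (pre-sleep core) motif decays as
  ``exp(-t / tau_min)`` toward the recent motif. The drift acts on the
  event-level motif choice, not on unit rates, so occurrence frequency and
  population sparsity stay constant over time.
* **Up/Down energy series**: a 5-Hz two-state semi-Markov process with
  Gaussian emissions, emulating the bimodal dentate-gyrus molecular-layer
  CSD energy.

Conventions inherited by all downstream modules: LFP in microvolts, time in
seconds, channels indexed 0-based from dorsal to ventral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CA1_LAYERS = ("oriens", "pyramidale", "radiatum", "lacunosum-moleculare")

#: Canonical 16-channel dorsal-to-ventral layer map (50-um spacing).
DEFAULT_LAYER_MAP = (
    "oriens",
    "oriens",
    "pyramidale",
    "pyramidale",
    "radiatum",
    "radiatum",
    "radiatum",
    "lacunosum-moleculare",
    "lacunosum-moleculare",
    "lacunosum-moleculare",
    "moleculare",
    "moleculare",
    "moleculare",
    "granule",
    "granule",
    "granule",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic recording.

    Oscillation frequencies default to the typical radiatum-sink (147 Hz) and
    lacunosum-moleculare-sink (125 Hz) ripple frequencies; the ground-truth
    drift constant defaults to 13 minutes. Ripple incidence during NREM rest
    is set to 0.5 events/s, a realistic order of magnitude for extended
    sleep/rest sessions.
    """

    seed: int = 0
    fs_hz: float = 1250.0
    n_channels: int = 16
    channel_spacing_um: float = 50.0
    layer_map: tuple[str, ...] = DEFAULT_LAYER_MAP
    duration_s: float = 600.0

    # units
    n_units_ca1_deep: int = 20
    n_units_ca1_sup: int = 15
    n_units_ca3: int = 12
    n_interneurons: int = 6

    # events
    ripple_rate_hz: float = 0.5
    p_lm: float = 0.3
    rad_freq_hz: float = 147.0
    lm_freq_hz: float = 125.0
    min_event_gap_s: float = 0.35

    # amplitudes (microvolts)
    noise_sd: float = 10.0
    sharpwave_uv: float = 300.0
    lm_sink_uv: float = 250.0
    lm_rad_echo_uv: float = 120.0
    lm_pyr_positive_uv: float = 100.0
    ripple_uv: float = 120.0

    # spike-session structure
    pre_sleep_s: float = 1800.0
    exploration_s: float = 600.0
    post_sleep_s: float = 4260.0
    theta_freq_hz: float = 8.0
    base_rate_hz: float = 0.6
    interneuron_rate_hz: float = 10.0
    rad_boost: float = 6.0
    lm_boost_deep: float = 5.0
    lm_boost_sup: float = 2.5
    motif_gain_hz: float = 30.0
    p_express: float = 0.7
    p_theta_express: float = 0.4
    homogeneous_rates: bool = False
    core_motif: tuple[int, ...] = tuple(range(8))
    composite_extra: tuple[int, ...] = tuple(range(20, 26))
    tau_min: float = 13.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_lm <= 1.0:
            raise ValueError("p_lm must be in [0, 1]")
        if len(self.layer_map) != self.n_channels:
            raise ValueError("layer_map must cover all channels")
        if set(self.core_motif) & set(self.composite_extra):
            raise ValueError("core_motif and composite_extra must be disjoint")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")

    @property
    def n_units(self) -> int:
        return (
            self.n_units_ca1_deep
            + self.n_units_ca1_sup
            + self.n_units_ca3
            + self.n_interneurons
        )

    def layer_channels(self, layer: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.layer_map) == layer)

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("layer_map", "core_motif", "composite_extra"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class LaminarRecording:
    """Channel x time LFP matrix (microvolts) with laminar metadata."""

    data: np.ndarray
    fs_hz: float
    layer_map: tuple[str, ...]
    spacing_um: float

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs_hz

    def layer_channels(self, layer: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.layer_map) == layer)

    def save(self, prefix) -> None:
        """Write as little-endian float32 flat binary (channel-major) + JSON."""
        prefix = Path(prefix)
        self.data.astype("<f4").tofile(prefix.with_suffix(".dat"))
        sidecar = {
            "fs_hz": self.fs_hz,
            "n_channels": self.n_channels,
            "channel_order": "channel-major",
            "layer_map": list(self.layer_map),
            "spacing_um": self.spacing_um,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix) -> "LaminarRecording":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        raw = np.fromfile(prefix.with_suffix(".dat"), dtype="<f4")
        data = raw.reshape(meta["n_channels"], -1).astype(float)
        return cls(
            data=data,
            fs_hz=meta["fs_hz"],
            layer_map=tuple(meta["layer_map"]),
            spacing_um=meta["spacing_um"],
        )


@dataclass
class GroundTruth:
    """Planted structure of a simulated session."""

    event_times_s: np.ndarray
    true_class: np.ndarray  # "Rad" / "LM" per event
    tau_min: float
    motif_memberships: dict = field(default_factory=dict)
    true_updown_state: np.ndarray | None = None
    updown_fs_hz: float = 5.0


@dataclass
class SpikeSession:
    """Unit metadata, spike times and epoch/event tables for one day."""

    units: pd.DataFrame  # unit_id, region, cell_class, sublayer, tetrode
    spikes: pd.DataFrame  # unit_id, spike_time_s (sorted by time)
    epochs: pd.DataFrame  # epoch, start_s, end_s
    events: pd.DataFrame  # epoch, time_s, true_class, expressed
    theta_cycle_times_s: np.ndarray

    def epoch_bounds(self, name: str) -> tuple[float, float]:
        row = self.epochs.loc[self.epochs["epoch"] == name].iloc[0]
        return float(row["start_s"]), float(row["end_s"])

    def event_times(self, epoch: str, klass: str | None = None) -> np.ndarray:
        m = self.events["epoch"] == epoch
        if klass is not None:
            m &= self.events["true_class"] == klass
        return self.events.loc[m, "time_s"].to_numpy()

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.units.to_csv(directory / "units.csv", index=False)
        self.spikes.to_csv(directory / "spikes.csv", index=False, float_format="%.6f")
        self.epochs.to_csv(directory / "epochs.csv", index=False, float_format="%.6f")
        self.events.to_csv(directory / "events.csv", index=False, float_format="%.6f")


def _event_times(rng, rate_hz, duration_s, min_gap_s, margin_s=0.5):
    """Poisson event count, uniform placement with a minimum separation."""
    n_ev = rng.poisson(rate_hz * duration_s)
    lo, hi = margin_s, duration_s - margin_s
    n_ev = min(n_ev, int((hi - lo) / min_gap_s) - 1)
    times = np.sort(rng.uniform(lo, hi, n_ev))
    for _ in range(200):
        bad = np.flatnonzero(np.diff(times) < min_gap_s) + 1
        if bad.size == 0:
            break
        times[bad] = rng.uniform(lo, hi, bad.size)
        times = np.sort(times)
    return times


def _add_bump(data, fs, t0, spatial, sigma_s):
    """Add ``spatial[c] * exp(-(t-t0)^2 / 2 sigma^2)`` to every channel."""
    n = data.shape[1]
    i0 = max(0, int((t0 - 5 * sigma_s) * fs))
    i1 = min(n, int((t0 + 5 * sigma_s) * fs) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    g = np.exp(-0.5 * ((t - t0) / sigma_s) ** 2)
    data[:, i0:i1] += spatial[:, None] * g[None, :]


def _gaussian_profile(n_channels, centre, sigma_ch):
    c = np.arange(n_channels)
    return np.exp(-0.5 * ((c - centre) / sigma_ch) ** 2)


def simulate_laminar_lfp(
    cfg: SimConfig, duration_s: float | None = None
) -> tuple[LaminarRecording, GroundTruth]:
    """Simulate a laminar sleep recording with planted Rad/LM ripples.

    Returns the channel x time LFP matrix (microvolts) and the ground truth
    (event times and true classes). Raises ``ValueError`` when fewer than 4
    channels are requested, since the CSD needs interior channels.
    """
    if cfg.n_channels < 4:
        raise ValueError("CSD profiling needs at least 4 channels")
    duration_s = cfg.duration_s if duration_s is None else float(duration_s)
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_hz
    n = int(round(duration_s * fs))
    data = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_channels, n))

    rad_centre = float(np.mean(cfg.layer_channels("radiatum")))
    lm_centre = float(np.mean(cfg.layer_channels("lacunosum-moleculare")))
    pyr_centre = float(np.mean(cfg.layer_channels("pyramidale")))

    times = _event_times(rng, cfg.ripple_rate_hz, duration_s, cfg.min_event_gap_s)
    is_lm = rng.random(times.size) < cfg.p_lm

    rad_profile = _gaussian_profile(cfg.n_channels, rad_centre, 1.2)
    lm_profile = _gaussian_profile(cfg.n_channels, lm_centre, 1.2)
    pyr_profile = _gaussian_profile(cfg.n_channels, pyr_centre, 1.0)

    for t0, lm in zip(times, is_lm):
        amp = rng.uniform(0.8, 1.2)
        burst_dur = rng.uniform(0.040, 0.100)
        if lm:
            # LM sink leads the ripple peak by ~17 ms; a weaker radiatum sink
            # follows ~12 ms after; positive pyramidal-layer deflection.
            _add_bump(data, fs, t0 - 0.017, -cfg.lm_sink_uv * amp * lm_profile, 0.012)
            _add_bump(data, fs, t0 + 0.012, -cfg.lm_rad_echo_uv * amp * rad_profile, 0.012)
            _add_bump(data, fs, t0 - 0.010, cfg.lm_pyr_positive_uv * amp * pyr_profile, 0.015)
            freq = cfg.lm_freq_hz
        else:
            _add_bump(data, fs, t0, -cfg.sharpwave_uv * amp * rad_profile, 0.012)
            freq = cfg.rad_freq_hz
        i0 = max(0, int((t0 - burst_dur) * fs))
        i1 = min(n, int((t0 + burst_dur) * fs) + 1)
        t = np.arange(i0, i1) / fs
        # window sigma chosen so the envelope stays above half the detection
        # threshold long enough to contain >= 4 ripple cycles at high SNR
        window = np.exp(-0.5 * ((t - t0) / (burst_dur / 3.5)) ** 2)
        osc = cfg.ripple_uv * amp * window * np.cos(2 * np.pi * freq * (t - t0))
        data[:, i0:i1] += pyr_profile[:, None] * osc[None, :]

    rec = LaminarRecording(
        data=data, fs_hz=fs, layer_map=cfg.layer_map, spacing_um=cfg.channel_spacing_um
    )
    truth = GroundTruth(
        event_times_s=times,
        true_class=np.where(is_lm, "LM", "Rad"),
        tau_min=cfg.tau_min,
        motif_memberships={
            "core": np.asarray(cfg.core_motif, dtype=int),
            "composite_extra": np.asarray(cfg.composite_extra, dtype=int),
        },
    )
    return rec, truth


def simulate_updown_energy(
    cfg: SimConfig,
    duration_s: float,
    gap_sd: float = 3.0,
    mean_dwell_up_s: float = 5.7,
    mean_dwell_down_s: float = 4.4,
    fs_hz: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-state semi-Markov energy series at 5 Hz with Gaussian emissions.

    Dwell times are gamma-distributed (shape 4) around the given means; the
    Up state emits ``N(gap_sd, 1)`` and the Down state ``N(0, 1)``. Returns
    ``(energy, states)`` with states coded 1 = Up, 0 = Down.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if gap_sd <= 0:
        raise ValueError("emission gap must be positive")
    rng = np.random.default_rng(cfg.seed + 1)
    n = int(round(duration_s * fs_hz))
    states = np.empty(n, dtype=int)
    state = int(rng.integers(0, 2))
    i = 0
    shape = 4.0
    while i < n:
        mean = mean_dwell_up_s if state == 1 else mean_dwell_down_s
        dwell = rng.gamma(shape, mean / shape)
        j = min(n, i + max(1, int(round(dwell * fs_hz))))
        states[i:j] = state
        state = 1 - state
        i = j
    energy = rng.normal(0.0, 1.0, n) + gap_sd * states
    return energy, states


def _unit_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    uid = 0
    groups = [
        ("CA1", "principal", "deep", cfg.n_units_ca1_deep),
        ("CA1", "principal", "superficial", cfg.n_units_ca1_sup),
        ("CA3", "principal", "deep", cfg.n_units_ca3),
        ("CA1", "interneuron", "deep", cfg.n_interneurons),
    ]
    for region, klass, sub, count in groups:
        for _ in range(count):
            rows.append(
                {
                    "unit_id": uid,
                    "region": region,
                    "cell_class": klass,
                    "sublayer": sub,
                    "tetrode": uid % 8,
                }
            )
            uid += 1
    return pd.DataFrame(rows)


def simulate_spike_session(
    cfg: SimConfig, truth: GroundTruth | None = None
) -> tuple[SpikeSession, GroundTruth]:
    """Simulate spikes across pre-sleep, exploration and post-sleep epochs.

    Motif expression rules (event-level choice; 50-ms windows centred on
    event times, spikes drawn as Bernoulli per 1-ms bin within windows, and
    as a Poisson process at each unit's baseline rate elsewhere):

    * pre-sleep LM events express the *core* motif; Rad events express the
      *composite* motif (core plus ``composite_extra``), each with
      probability ``p_express``;
    * exploration theta cycles express the *recent* motif
      (= ``composite_extra``) with probability ``p_theta_express``;
    * post-sleep LM events express the prior (core) motif with probability
      ``exp(-t / tau_min)`` (t = minutes into post-sleep) and otherwise the
      recent motif; post-sleep Rad events express the composite motif.

    Overall rates are higher in Rad events, and deep units receive a larger
    boost than superficial ones in LM events. Returns the session and the
    (possibly extended) ground truth.
    """
    if len(cfg.core_motif) == 0 or len(cfg.composite_extra) == 0:
        raise ValueError("motif sets must be non-empty")
    rng = np.random.default_rng(cfg.seed + 2)
    units = _unit_table(cfg)
    n_units = len(units)
    if max(max(cfg.core_motif), max(cfg.composite_extra)) >= n_units:
        raise ValueError("motif indices exceed unit count")

    pre_end = cfg.pre_sleep_s
    expl_end = pre_end + cfg.exploration_s
    post_end = expl_end + cfg.post_sleep_s
    epochs = pd.DataFrame(
        {
            "epoch": ["pre-sleep", "exploration", "post-sleep"],
            "start_s": [0.0, pre_end, expl_end],
            "end_s": [pre_end, expl_end, post_end],
        }
    )

    # --- event times and classes per sleep epoch
    pre_times = _event_times(rng, cfg.ripple_rate_hz, cfg.pre_sleep_s, cfg.min_event_gap_s)
    pre_lm = rng.random(pre_times.size) < cfg.p_lm
    if truth is not None:
        post_times = np.asarray(truth.event_times_s, dtype=float) + expl_end
        post_lm = np.asarray(truth.true_class) == "LM"
    else:
        post_times = (
            _event_times(rng, cfg.ripple_rate_hz, cfg.post_sleep_s, cfg.min_event_gap_s)
            + expl_end
        )
        post_lm = rng.random(post_times.size) < cfg.p_lm

    theta_period = 1.0 / cfg.theta_freq_hz
    theta_times = np.arange(pre_end + theta_period, expl_end - theta_period, theta_period)

    core = np.asarray(cfg.core_motif, dtype=int)
    extra = np.asarray(cfg.composite_extra, dtype=int)
    composite = np.concatenate([core, extra])
    memberships = {"core": core, "composite_extra": extra, "composite": composite}

    is_principal = (units["cell_class"] == "principal").to_numpy()
    is_deep = (units["sublayer"] == "deep").to_numpy() & is_principal
    is_sup = (units["sublayer"] == "superficial").to_numpy() & is_principal

    if cfg.homogeneous_rates:
        base = np.full(n_units, cfg.base_rate_hz)
    else:
        base = cfg.base_rate_hz * rng.lognormal(0.0, 0.5, n_units)
    base[~is_principal] = cfg.interneuron_rate_hz

    # --- baseline Poisson spikes over the whole day
    spike_t, spike_u = [], []
    for u in range(n_units):
        k = rng.poisson(base[u] * post_end)
        spike_t.append(rng.uniform(0.0, post_end, k))
        spike_u.append(np.full(k, u))

    # --- event windows: Bernoulli per 1-ms bin
    win_half = 0.025
    n_bins = 50

    def window_rates(klass_lm: bool, expressed: str) -> np.ndarray:
        rates = base.copy()
        if cfg.homogeneous_rates:
            boost = cfg.rad_boost if not klass_lm else cfg.lm_boost_deep
            rates = rates * boost
        elif klass_lm:
            b = np.ones(n_units)
            b[is_deep] = cfg.lm_boost_deep
            b[is_sup] = cfg.lm_boost_sup
            b[~is_principal] = cfg.lm_boost_deep
            rates = rates * b
        else:
            rates = rates * cfg.rad_boost
        if expressed != "none" and cfg.motif_gain_hz > 0:
            rates = rates.copy()
            rates[memberships[expressed]] += cfg.motif_gain_hz
        return rates

    def choose_expressed(epoch: str, t_s: float, lm: bool) -> str:
        if epoch == "post-sleep" and lm:
            t_min = (t_s - expl_end) / 60.0
            if rng.random() < np.exp(-t_min / cfg.tau_min):
                return "core"
            return "composite_extra"
        if rng.random() >= cfg.p_express:
            return "none"
        return "core" if lm else "composite"

    event_rows = []
    for epoch, times, lm_flags in (
        ("pre-sleep", pre_times, pre_lm),
        ("post-sleep", post_times, post_lm),
    ):
        for t0, lm in zip(times, lm_flags):
            expressed = choose_expressed(epoch, t0, lm)
            event_rows.append(
                {
                    "epoch": epoch,
                    "time_s": t0,
                    "true_class": "LM" if lm else "Rad",
                    "expressed": expressed,
                }
            )
            p = np.clip(window_rates(lm, expressed) * 1e-3, 0.0, 1.0)
            hits = rng.random((n_units, n_bins)) < p[:, None]
            uu, bb = np.nonzero(hits)
            if uu.size:
                spike_t.append(t0 - win_half + (bb + rng.random(bb.size)) * 1e-3)
                spike_u.append(uu)

    # --- theta cycles: recent motif expression during exploration
    for t0 in theta_times:
        if cfg.motif_gain_hz > 0 and rng.random() < cfg.p_theta_express:
            rates = base.copy()
            rates[extra] = rates[extra] + cfg.motif_gain_hz
        else:
            rates = base
        p = np.clip(rates * 1e-3, 0.0, 1.0)
        hits = rng.random((n_units, n_bins)) < p[:, None]
        uu, bb = np.nonzero(hits)
        if uu.size:
            spike_t.append(t0 - win_half + (bb + rng.random(bb.size)) * 1e-3)
            spike_u.append(uu)

    spike_t = np.concatenate(spike_t)
    spike_u = np.concatenate(spike_u).astype(int)
    order = np.argsort(spike_t, kind="stable")
    spikes = pd.DataFrame({"unit_id": spike_u[order], "spike_time_s": spike_t[order]})

    session = SpikeSession(
        units=units,
        spikes=spikes,
        epochs=epochs,
        events=pd.DataFrame(event_rows),
        theta_cycle_times_s=theta_times,
    )
    if truth is None:
        out_truth = GroundTruth(
            event_times_s=post_times - expl_end,
            true_class=np.where(post_lm, "LM", "Rad"),
            tau_min=cfg.tau_min,
            motif_memberships=memberships,
        )
    else:
        out_truth = replace(truth, motif_memberships=memberships)
    return session, out_truth


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A generator with no motif structure and class-independent rates."""
    params = dict(
        seed=seed,
        motif_gain_hz=0.0,
        homogeneous_rates=True,
        rad_boost=4.0,
        lm_boost_deep=4.0,
        lm_boost_sup=4.0,
    )
    params.update(overrides)
    return SimConfig(**params)
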