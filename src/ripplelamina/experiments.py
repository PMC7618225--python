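"""Multi-session recovery experiments used for validation and reporting.

These drivers run the full generator -> analysis round trip at a scale that
fits a desktop: several simulated recording days, each analysed with the
same operations a real dataset would go through, with the planted ground
truth available for comparison.
"""

from __future__ import annotations

import numpy as np

from ripplelamina import motif_analysis, population_activity, reactivation_dynamics
from ripplelamina import synthetic_data
from ripplelamina.stats import derive_seeds


def prior_motif_drift(
    n_sessions: int = 8,
    tau_min: float = 13.0,
    seed: int = 0,
    drift: bool = True,
    **cfg_overrides,
) -> dict:
    """Prior-motif expression across post-sleep, pooled over sessions.

    Per simulated day: a coactivity motif is extracted from pre-sleep LM
    ripples (PCA/ICA), its activation is measured in every post-sleep LM
    ripple, and the activations are binned into the six 10-minute windows
    spanning (10, 70] minutes of post-sleep. ``drift=False`` simulates
    sessions whose prior-motif expression probability is constant. Returns
    the concatenated series with session ids plus per-bin ripple occurrence
    frequency and active-cell fraction (the feature-attribution inputs).
    """
    seeds = derive_seeds(seed, n_sessions)
    t_all, v_all, sid_all, occ_all, frac_all = [], [], [], [], []
    for i, s in enumerate(seeds):
        cfg = synthetic_data.SimConfig(
            seed=s,
            tau_min=tau_min if drift else 1e6,
            **cfg_overrides,
        )
        session, truth = synthetic_data.simulate_spike_session(cfg)
        units = session.units
        ca1 = units[(units["region"] == "CA1") & (units["cell_class"] == "principal")]
        uids = ca1["unit_id"].to_numpy()
        pv_pre = population_activity.population_vectors(
            session.spikes, uids, session.event_times("pre-sleep", "LM")
        )
        motifs = motif_analysis.extract_motifs(pv_pre, seed=s)
        if motifs.n_motifs == 0:
            continue
        core = truth.motif_memberships["core"]
        w = motifs.weights[
            np.argmax([np.abs(m[core]).sum() for m in motifs.weights])
        ]
        post_start, _ = session.epoch_bounds("post-sleep")
        t_lm = session.event_times("post-sleep", "LM")
        pv = population_activity.population_vectors(session.spikes, uids, t_lm)
        act = motif_analysis.motif_activation(
            w, population_activity.zscore_rows(pv)
        )
        t_min = (t_lm - post_start) / 60.0
        series = reactivation_dynamics.drift_timecourse({"LM": t_min}, {"LM": act})[
            "LM"
        ]
        t_all.append(series.bin_centres_min)
        v_all.append(series.values)
        sid_all.append(np.full(series.values.size, i))
        edges = np.arange(10.0, 75.0, 10.0)
        occ, frac = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (t_min > lo) & (t_min <= hi)
            occ.append(m.sum() / (hi - lo))
            frac.append((pv[:, m] > 0).mean() if m.any() else np.nan)
        occ_all.append(occ)
        frac_all.append(frac)
    return {
        "times_min": np.concatenate(t_all),
        "values": np.concatenate(v_all),
        "session_ids": np.concatenate(sid_all),
        "occurrence_per_min": np.concatenate(occ_all),
        "active_fraction": np.concatenate(frac_all),
        "n_sessions_used": len(t_all),
    }


def detection_roundtrip(seed: int = 0, duration_s: float = 300.0, **cfg_overrides) -> dict:
    """Detect planted ripples and label their dominant CSD sink.

    Returns recall-with-correct-class, detection recall, and the measured
    per-class ripple frequencies.
    """
    from ripplelamina import csd_profiles, signal_processing

    cfg = synthetic_data.SimConfig(seed=seed, duration_s=duration_s, **cfg_overrides)
    rec, truth = synthetic_data.simulate_laminar_lfp(cfg)
    pyr = signal_processing.select_reference_channel(rec)
    ref = int(np.argmin(signal_processing.ripple_band_score(rec)))
    table = signal_processing.detect_ripples(rec.data[pyr], rec.data[ref], rec.fs_hz)
    valid = table[table["valid"]].reset_index(drop=True)
    det = valid["peak_time_s"].to_numpy()
    sigs, kept = csd_profiles.event_signatures(rec, det)
    sinks = np.array(
        [csd_profiles.dominant_sink_layer(s, rec.layer_map) for s in sigs]
    )
    sink_class = np.where(
        sinks == "lacunosum-moleculare", "LM", np.where(sinks == "radiatum", "Rad", "other")
    )
    n_total = truth.event_times_s.size
    n_detected = 0
    n_correct = 0
    freqs = {"Rad": [], "LM": []}
    for i, t in enumerate(truth.event_times_s):
        if det.size == 0:
            break
        j = int(np.abs(det - t).argmin())
        if abs(det[j] - t) > 0.03:
            continue
        n_detected += 1
        k = np.flatnonzero(kept == j)
        if k.size and sink_class[k[0]] == truth.true_class[i]:
            n_correct += 1
        freqs[truth.true_class[i]].append(valid["mean_freq_hz"].iloc[j])
    return {
        "recall": n_detected / n_total,
        "recall_correct_class": n_correct / n_total,
        "rad_freq_hz": float(np.mean(freqs["Rad"])) if freqs["Rad"] else np.nan,
        "lm_freq_hz": float(np.mean(freqs["LM"])) if freqs["LM"] else np.nan,
        "n_events": n_total,
    }
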