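"""Shared fixtures: simulated recordings and spike sessions (generated once)."""

from __future__ import annotations

import numpy as np
import pytest

from ripplelamina import (
    csd_profiles,
    population_activity,
    signal_processing,
    synthetic_data,
)


@pytest.fixture(scope="session")
def lfp_sim():
    """A 300-s laminar recording with planted Rad/LM ripples."""
    cfg = synthetic_data.SimConfig(seed=1, duration_s=300.0)
    rec, truth = synthetic_data.simulate_laminar_lfp(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def detection(lfp_sim):
    """Detected, validated and CSD-classified ripples of the fixture recording."""
    cfg, rec, truth = lfp_sim
    pyr = signal_processing.select_reference_channel(rec)
    ref = int(np.argmin(signal_processing.ripple_band_score(rec)))
    table = signal_processing.detect_ripples(rec.data[pyr], rec.data[ref], rec.fs_hz)
    valid = table[table["valid"]].reset_index(drop=True)
    sigs, kept = csd_profiles.event_signatures(rec, valid["peak_time_s"].to_numpy())
    valid = valid.iloc[kept].reset_index(drop=True)
    det = valid["peak_time_s"].to_numpy()
    idx = np.abs(det[:, None] - truth.event_times_s[None, :]).argmin(axis=1)
    matched = np.abs(det - truth.event_times_s[idx]) < 0.03
    return {
        "cfg": cfg,
        "rec": rec,
        "truth": truth,
        "pyr": pyr,
        "ref": ref,
        "table": table,
        "valid": valid,
        "signatures": sigs,
        "true_class": np.where(matched, truth.true_class[idx], "none"),
    }


@pytest.fixture(scope="session")
def spike_sim():
    """Default three-epoch spike session with planted motifs and drift."""
    cfg = synthetic_data.SimConfig(seed=5)
    session, truth = synthetic_data.simulate_spike_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def spike_pvs(spike_sim):
    """CA1 principal-cell population vectors per epoch and ripple class."""
    cfg, session, truth = spike_sim
    units = session.units
    ca1 = units[(units["region"] == "CA1") & (units["cell_class"] == "principal")]
    uids = ca1["unit_id"].to_numpy()
    out = {"unit_ids": uids, "units": ca1, "session": session, "truth": truth}
    for epoch in ("pre-sleep", "post-sleep"):
        for klass in ("Rad", "LM"):
            out[(epoch, klass)] = population_activity.population_vectors(
                session.spikes, uids, session.event_times(epoch, klass)
            )
    out["theta"] = population_activity.population_vectors(
        session.spikes, uids, session.theta_cycle_times_s
    )
    return out


@pytest.fixture(scope="session")
def null_spike_pvs():
    """Session from the null generator (no motifs, class-independent rates)."""
    cfg = synthetic_data.null_config(
        seed=7, pre_sleep_s=900.0, post_sleep_s=1500.0, exploration_s=300.0
    )
    session, truth = synthetic_data.simulate_spike_session(cfg)
    units = session.units
    ca1 = units[(units["region"] == "CA1") & (units["cell_class"] == "principal")]
    uids = ca1["unit_id"].to_numpy()
    out = {"unit_ids": uids, "session": session, "truth": truth, "cfg": cfg}
    for klass in ("Rad", "LM"):
        out[("post-sleep", klass)] = population_activity.population_vectors(
            session.spikes, uids, session.event_times("post-sleep", klass)
        )
    return out
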