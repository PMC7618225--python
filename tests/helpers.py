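"""Shared synthetic inputs used by several test modules."""

from __future__ import annotations

import numpy as np

FS = 1250.0
N_T = 250  # samples in a 200-ms trace


def synthetic_traces(n_per_class=120, n_subjects=4, separation=1.0, seed=0, fs=FS):
    """Three waveform classes: negative sharp wave, flat, positive deflection."""
    rng = np.random.default_rng(seed)
    t = np.arange(N_T) / fs - 0.1
    bump = np.exp(-0.5 * (t / 0.015) ** 2)
    traces, labels, subjects = [], [], []
    for s in range(n_subjects):
        subj_gain = rng.uniform(0.8, 1.2)
        for klass, amp in (("Rad", -separation), ("intermediate", 0.0), ("LM", separation)):
            for _ in range(n_per_class):
                noise = rng.normal(0, 1.0, N_T)
                traces.append(subj_gain * (amp * 5.0 * bump) + noise)
                labels.append(klass)
                subjects.append(s)
    return np.asarray(traces), np.asarray(labels), np.asarray(subjects)


def planted_assembly_counts(
    memberships, n_units=30, n_events=900, gain=3.0, seed=0, p_active=0.35
):
    """Poisson counts with all-or-none co-activation of planted assemblies."""
    rng = np.random.default_rng(seed)
    X = rng.poisson(1.5, size=(n_units, n_events))
    for units in memberships:
        active = rng.random(n_events) < p_active
        X[np.ix_(list(units), np.flatnonzero(active))] += rng.poisson(
            gain, size=(len(units), active.sum())
        )
    return X
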