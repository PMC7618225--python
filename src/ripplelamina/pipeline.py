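"""End-to-end orchestration: simulate -> detect -> ... -> reactivation.

Each stage consumes the in-memory context produced by earlier stages and
writes CSV/JSON artefacts into the output directory. All stochastic stages
draw their seeds deterministically from the global seed, so a re-run with
the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ripplelamina import (
    coactivity_graphs,
    csd_profiles,
    motif_analysis,
    population_activity,
    reactivation_dynamics,
    signal_processing,
    state_dynamics,
    synthetic_data,
    waveform_classifier,
)
from ripplelamina.stats import derive_seeds

log = logging.getLogger("ripplelamina")

STAGES = (
    "simulate",
    "detect",
    "csd",
    "classify",
    "states",
    "population",
    "coactivity",
    "motifs",
    "reactivation",
)


class StageError(RuntimeError):
    """A stage was run without its inputs."""


def _require(ctx, key, stage):
    if key not in ctx:
        raise StageError(f"stage '{stage}' needs '{key}'; run earlier stages first")
    return ctx[key]


def run_pipeline(config: dict, out_dir, stages=None) -> dict:
    """Run the requested stages and write a report bundle.

    ``config`` holds a global ``seed`` plus optional ``simulate`` overrides
    for :class:`~ripplelamina.synthetic_data.SimConfig` and per-stage
    keyword overrides. Returns the in-memory context with all intermediate
    results; writes CSV/JSON artefacts, a log and ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    seed = int(config.get("seed", 0))
    stage_seeds = dict(zip(STAGES, derive_seeds(seed, len(STAGES))))
    ctx: dict = {"config": config, "seed": seed, "summary": {}}

    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("seed=%d stages=%s", seed, stages)
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            log.info("running stage %s (seed %d)", stage, stage_seeds[stage])
            globals()[f"_stage_{stage}"](ctx, out, stage_seeds[stage])
        summary = ctx["summary"]
        (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    finally:
        log.removeHandler(handler)
        handler.close()
    return ctx


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _stage_simulate(ctx, out, seed):
    overrides = dict(ctx["config"].get("simulate", {}))
    overrides.setdefault("seed", seed)
    cfg = synthetic_data.SimConfig(**overrides)
    rec, truth = synthetic_data.simulate_laminar_lfp(cfg)
    session, truth = synthetic_data.simulate_spike_session(cfg, None)
    ctx.update(cfg=cfg, recording=rec, truth=truth, session=session)
    cfg.to_yaml(out / "sim_config.yaml")
    rec.save(out / "recording")
    session.save(out / "session")
    ctx["summary"]["simulate"] = {
        "n_lfp_events": int(rec.duration_s * 0 + len(truth.event_times_s)),
        "n_units": len(session.units),
    }


def _stage_detect(ctx, out, seed):
    rec = _require(ctx, "recording", "detect")
    pyr_ch = signal_processing.select_reference_channel(rec)
    scores = signal_processing.ripple_band_score(rec)
    ref_ch = int(np.argmin(scores))
    table = signal_processing.detect_ripples(rec.data[pyr_ch], rec.data[ref_ch], rec.fs_hz)
    table["isolated"] = signal_processing.isolated_mask(table["peak_time_s"].to_numpy())
    ctx.update(pyr_channel=pyr_ch, ref_channel=ref_ch, ripples=table)
    table.to_csv(out / "ripples.csv", index=False, float_format="%.6f")
    ctx["summary"]["detect"] = {
        "pyr_channel": pyr_ch,
        "ref_channel": ref_ch,
        "n_detected": int(len(table)),
        "n_valid": int(table["valid"].sum()),
    }


def _stage_csd(ctx, out, seed):
    rec = _require(ctx, "recording", "csd")
    table = _require(ctx, "ripples", "csd").copy()
    valid = table[table["valid"]].reset_index(drop=True)
    sigs, kept = csd_profiles.event_signatures(rec, valid["peak_time_s"].to_numpy())
    valid = valid.iloc[kept].reset_index(drop=True)
    sinks = [csd_profiles.dominant_sink_layer(s, rec.layer_map) for s in sigs]
    pc_labels, strengths, comps, var = csd_profiles.pca_signature_labels(sigs, rec.layer_map)
    lm_labels, lm_scores = csd_profiles.label_by_lm_csd(sigs, rec.layer_map)
    valid["dominant_sink"] = sinks
    valid["pc1_strength"] = strengths
    valid["class_pc1"] = pc_labels
    valid["class_lm_csd"] = lm_labels
    valid["lm_csd_score"] = lm_scores
    ctx.update(signatures=sigs, classified=valid, pca_var=var)
    pd.DataFrame(sigs).to_csv(out / "csd_signatures.csv", index=False)
    valid.to_csv(out / "ripples_classified.csv", index=False, float_format="%.6f")
    ctx["summary"]["csd"] = {
        "pc1_variance": float(var[0]),
        "lm_sink_fraction": float(np.mean(np.asarray(sinks) == "lacunosum-moleculare")),
    }


def _stage_classify(ctx, out, seed):
    rec = _require(ctx, "recording", "classify")
    valid = _require(ctx, "classified", "classify")
    pyr_ch = ctx["pyr_channel"]
    traces, kept = waveform_classifier.extract_peri_peak_traces(
        rec.data[pyr_ch], rec.fs_hz, valid["peak_time_s"].to_numpy()
    )
    labels = valid["class_lm_csd"].to_numpy()[kept]
    # single simulated subject: alternate events into two pseudo-subjects
    subjects = np.arange(labels.size) % 2
    n_rep = int(ctx["config"].get("classify", {}).get("n_repeats", 50))
    report = waveform_classifier.train_ripple_lda(
        traces, labels, subjects, rec.fs_hz, n_repeats=n_rep, seed=seed
    )
    ctx["classifier_report"] = report
    if report.final_model is not None:
        report.final_model.to_json(out / "lda_model.json")
    ctx["summary"]["classify"] = {
        "mean_gain_pct": report.mean_gain_pct,
        "true_accuracy": report.true_accuracy.tolist(),
        "null_accuracy": report.null_accuracy.tolist(),
    }


def _stage_states(ctx, out, seed):
    rec = _require(ctx, "recording", "states")
    valid = _require(ctx, "classified", "states")
    csd = csd_profiles.compute_csd(rec.data)
    csd = csd_profiles.smooth_laminar(csd, rec.spacing_um)
    inner = csd_profiles.interior_layer_map(rec.layer_map)
    dg = np.flatnonzero(inner == "moleculare")
    energy = state_dynamics.dg_energy(csd, dg, rec.fs_hz)
    seq = state_dynamics.infer_updown(energy, seed=seed)
    props = state_dynamics.lm_proportion_by_state(
        valid["peak_time_s"].to_numpy(), valid["class_pc1"].to_numpy(), seq, energy
    )
    chains = state_dynamics.ripple_chains(np.sort(valid["peak_time_s"].to_numpy()))
    order = np.argsort(valid["peak_time_s"].to_numpy())
    labels_sorted = valid["class_pc1"].to_numpy()[order]
    chain_labels = [labels_sorted[c] for c in chains if len(c) > 1]
    trans = None
    if chain_labels:
        trans = state_dynamics.transition_matrix(chain_labels, n_shuffles=200, seed=seed)
    seq.epochs.to_csv(out / "updown_epochs.csv", index=False, float_format="%.6f")
    state_dynamics.chain_length_histogram(chains).to_csv(
        out / "chain_histogram.csv", index=False
    )
    ctx.update(updown=seq, lm_proportions=props, transitions=trans)
    ctx["summary"]["states"] = {
        "lm_prop_up": props["Up"],
        "lm_prop_down": props["Down"],
        "low_confidence": seq.low_confidence,
    }


def _pv_by_class(ctx, epoch):
    session = ctx["session"]
    units = session.units
    ca1 = units[(units["region"] == "CA1") & (units["cell_class"] == "principal")]
    pvs = {}
    for klass in ("Rad", "LM"):
        times = session.event_times(epoch, klass)
        pvs[klass] = population_activity.population_vectors(
            session.spikes, ca1["unit_id"].to_numpy(), times
        )
    return ca1, pvs


def _stage_population(ctx, out, seed):
    session = _require(ctx, "session", "population")
    ca1, pvs = _pv_by_class(ctx, "post-sleep")
    ctx["ca1_units"] = ca1
    ctx["pvs_post"] = pvs
    X = np.concatenate([pvs["Rad"], pvs["LM"]], axis=1)
    y = np.array(["Rad"] * pvs["Rad"].shape[1] + ["LM"] * pvs["LM"].shape[1])
    pop_cfg = ctx["config"].get("population", {})
    decode = None
    try:
        decode = population_activity.decode_ripple_type(
            X,
            y,
            n_cells=int(pop_cfg.get("n_cells", 15)),
            n_perm=int(pop_cfg.get("n_perm", 20)),
            min_events_per_class=int(pop_cfg.get("min_events_per_class", 250)),
            seed=seed,
        )
    except ValueError as err:
        log.info("decoding skipped: %s", err)
    gini = {
        k: float(np.mean([coactivity_graphs.gini_sparsity(v) for v in p.T if v.sum() > 0]))
        for k, p in pvs.items()
    }
    pr = {k: coactivity_graphs.participation_ratio(p) for k, p in pvs.items()}
    ctx["decode"] = decode
    ctx["summary"]["population"] = {
        "mi_bits": None if decode is None else decode["mi_bits"],
        "mi_null_bits": None if decode is None else decode.get("mi_null_bits"),
        "gini": gini,
        "participation_ratio": pr,
    }


def _stage_coactivity(ctx, out, seed):
    pvs = _require(ctx, "pvs_post", "coactivity")
    graphs = {}
    for klass, p in pvs.items():
        g = coactivity_graphs.population_conditioned_coactivity(p, event_class=klass)
        graphs[klass] = g
        coactivity_graphs.graph_to_edgelist(g).to_csv(
            out / f"coactivity_{klass}.csv", index=False, float_format="%.6g"
        )
    ctx["graphs"] = graphs
    ctx["summary"]["coactivity"] = {
        k: {
            "mean_strength": float(np.nanmean(coactivity_graphs.node_strength(g))),
            "balance": coactivity_graphs.structural_balance(g),
        }
        for k, g in graphs.items()
    }


def _stage_motifs(ctx, out, seed):
    pvs = _require(ctx, "pvs_post", "motifs")
    motifs = motif_analysis.extract_motifs(pvs["LM"], event_class="LM", seed=seed)
    result = {"n_motifs": motifs.n_motifs}
    if motifs.n_motifs:
        n_surr = int(ctx["config"].get("motifs", {}).get("n_surrogates", 100))
        gains = motif_analysis.contribution_gain(
            motifs, pvs["LM"], pvs["Rad"], n_surrogates=n_surr, seed=seed
        )
        agg = motif_analysis.aggregated_count(gains, motifs, seed=seed)
        result.update(aggregated=agg["observed"], expected=agg["expected_mean"], p=agg["p"])
        ctx["motif_gains"] = gains
    ctx["motifs"] = motifs
    (out / "motifs.json").write_text(
        json.dumps(
            _jsonable(
                {
                    "weights": motifs.weights,
                    "threshold": motifs.threshold,
                    "event_class": motifs.event_class,
                }
            ),
            indent=2,
        )
    )
    ctx["summary"]["motifs"] = result


def _stage_reactivation(ctx, out, seed):
    session = _require(ctx, "session", "reactivation")
    ca1 = ctx.get("ca1_units")
    if ca1 is None:
        ca1, _ = _pv_by_class(ctx, "post-sleep")
    uids = ca1["unit_id"].to_numpy()
    spikes = session.spikes

    pre_times = {k: session.event_times("pre-sleep", k) for k in ("Rad", "LM")}
    pv_pre = {
        k: population_activity.population_vectors(spikes, uids, t)
        for k, t in pre_times.items()
    }
    pv_theta = population_activity.population_vectors(
        spikes, uids, session.theta_cycle_times_s
    )
    # balanced pre-sleep baseline coactivity
    rng = np.random.default_rng(seed)
    n_bal = min(pv_pre["Rad"].shape[1], pv_pre["LM"].shape[1])
    bal = np.concatenate(
        [
            pv_pre["Rad"][:, rng.choice(pv_pre["Rad"].shape[1], n_bal, replace=False)],
            pv_pre["LM"][:, rng.choice(pv_pre["LM"].shape[1], n_bal, replace=False)],
        ],
        axis=1,
    )
    A_pre = coactivity_graphs.population_conditioned_coactivity(bal).weights
    A_theta = coactivity_graphs.population_conditioned_coactivity(pv_theta).weights
    W_recent, _, flagged = reactivation_dynamics.recent_prior_transform(A_pre, A_theta)

    post_start, _ = session.epoch_bounds("post-sleep")
    times, values = {}, {}
    for klass in ("Rad", "LM"):
        t = session.event_times("post-sleep", klass)
        pv = population_activity.population_vectors(spikes, uids, t)
        values[klass] = reactivation_dynamics.balance_score(
            W_recent, population_activity.zscore_rows(pv)
        )
        times[klass] = (t - post_start) / 60.0
    series = reactivation_dynamics.drift_timecourse(times, values)
    fits = {}
    for klass, s in series.items():
        try:
            fits[klass] = reactivation_dynamics.fit_flat_vs_exponential(
                s.bin_centres_min, s.values, n_boot=0
            )
        except ValueError:
            continue
    ctx.update(drift_series=series, drift_fits=fits, W_recent=W_recent)
    rows = [
        {"ripple_class": k, "bin_centre_min": c, "value": v}
        for k, s in series.items()
        for c, v in zip(s.bin_centres_min, s.values)
    ]
    pd.DataFrame(rows).to_csv(out / "drift_series.csv", index=False, float_format="%.6f")
    ctx["summary"]["reactivation"] = {
        k: {"model": f.model, "bic_flat": f.bic_flat, "bic_exp": f.bic_exp}
        for k, f in fits.items()
    } | {"regularised_inverse": bool(flagged)}
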