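"""Scenario orchestration: generate (or load) a session, run every analysis
stage in order (saccades -> scotoma -> evoked -> laminar), and assemble a
reproducible report of the headline comparisons."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .evoked import (AnalysisWindows, apply_inclusion_filters, delta_fr,
                     neuron_effect, population_summary, saccade_velocity_check)
from .laminar import (EARLY_WINDOW, MUA_BASELINE_WINDOW, LaminarProfile,
                      channel_significance, estimate_surface, trial_delta_fr)
from .saccades import ResponseField, classify_in_rf, detect_saccades
from .scotoma import (ScotomaModel, StimulusAperture, bin_failure_map,
                      fit_scotoma, mass_contour, overlap_regression,
                      session_failure_test, stimulus_overlap)
from .synthetic_data import GeneratorConfig, SessionBundle, generate_session

VISUAL_CLASSES = ("visual", "visual_movement")
MOVEMENT_CLASSES = ("movement", "visual_movement")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def visual_stats(bundle: SessionBundle, phase_before: str = "before",
                 phase_during: str | None = None,
                 windows: AnalysisWindows | None = None,
                 classes=VISUAL_CLASSES, alpha: float = 0.05):
    """Per-neuron visual dFR statistics for the visually responsive pool.

    The Bonferroni family is the set of neurons tested here (one rank-sum
    per neuron within the inactivation condition).
    """
    windows = windows or AnalysisWindows()
    config = bundle.config
    phase_during = phase_during or config.phases[1]
    kept, log = apply_inclusion_filters(bundle.neurons,
                                        required_phases=config.phases)
    pool = [n for n in kept if n.functional_class in classes]
    n_family = len(pool)
    out = []
    for n in pool:
        b, _ = delta_fr(n.stim_spikes[phase_before],
                        bundle.stim_onsets(phase_before),
                        windows.visual_response, windows.visual_baseline)
        d, _ = delta_fr(n.stim_spikes[phase_during],
                        bundle.stim_onsets(phase_during),
                        windows.visual_response, windows.visual_baseline)
        out.append(neuron_effect(b, d, n_family, neuron_id=n.id,
                                 functional_class=n.functional_class,
                                 alpha=alpha, depth_um=n.depth_um))
    return out, log


def motor_stats(bundle: SessionBundle, phase_before: str = "before",
                phase_during: str | None = None,
                windows: AnalysisWindows | None = None,
                classes=MOVEMENT_CLASSES, alpha: float = 0.05):
    """Per-neuron saccade-locked dFR statistics for the movement-responsive pool."""
    windows = windows or AnalysisWindows()
    config = bundle.config
    phase_during = phase_during or config.phases[1]

    def saccade_onsets(phase):
        sel = (bundle.event_table["event"] == "saccade_onset") \
            & (bundle.event_table["phase"] == phase)
        return bundle.event_table.loc[sel, "t_ms"].to_numpy()

    kept, log = apply_inclusion_filters(bundle.neurons,
                                        required_phases=config.phases)
    pool = [n for n in kept if n.functional_class in classes]
    out = []
    for n in pool:
        b, _ = delta_fr(n.motor_spikes[phase_before], saccade_onsets(phase_before),
                        windows.saccade_response, windows.saccade_baseline)
        d, _ = delta_fr(n.motor_spikes[phase_during], saccade_onsets(phase_during),
                        windows.saccade_response, windows.saccade_baseline)
        out.append(neuron_effect(b, d, len(pool), neuron_id=n.id,
                                 functional_class=n.functional_class,
                                 alpha=alpha, depth_um=n.depth_um))
    return out, log


def behavior_summary(bundle: SessionBundle) -> dict:
    """RF-target failure rates per phase with Fisher's exact test."""
    df = bundle.behavior
    rf = df[df["is_rf_target"]]
    out = {}
    counts = {}
    for tag in ("before", "during"):
        sel = rf[rf["phase"] == tag]
        fails = int((sel["outcome"] == "fail").sum())
        total = int(len(sel))
        counts[tag] = (fails, total - fails)
        out[f"{tag}_fail_pct"] = 100.0 * fails / total if total else float("nan")
        out[f"{tag}_n"] = total
    out["fisher_p"] = session_failure_test(counts["before"], counts["during"])
    return out


def scotoma_analysis(bundle: SessionBundle, mass: float = 0.95) -> dict:
    """Fit the During failure map and compute the stimulus-overlap fraction."""
    df = bundle.behavior
    during = df[(df["phase"] == "during") & ~df["is_rf_target"]]
    fmap = bin_failure_map(during)
    model = fit_scotoma(fmap)
    contour = mass_contour(model, mass)
    overlap = stimulus_overlap(contour, bundle.config.stimulus_aperture)
    return {"model": model.to_dict(), "mass": mass,
            "overlap_fraction": float(overlap)}


def laminar_analysis(bundle: SessionBundle, theta: float = -5.0) -> dict:
    """Channel-wise significance, surface estimate, and early-window profile."""
    out = {}
    for phase, mua in bundle.mua.items():
        table = channel_significance(mua, theta)
        surface = estimate_surface(table["significant"].to_numpy())
        early = [float(np.mean(trial_delta_fr(trials, EARLY_WINDOW,
                                              MUA_BASELINE_WINDOW)))
                 for trials in mua.events[theta]]
        out[phase] = {
            "surface_channel": surface,
            "n_significant": int(table["significant"].sum()),
            "profile": LaminarProfile(
                evoked=np.asarray(early),
                significant=table["significant"].to_numpy(),
                surface_channel=surface,
                channel_spacing_um=mua.channel_spacing_um),
        }
    return out


def free_view_velocities(bundle: SessionBundle, phase: str) -> np.ndarray:
    """Peak velocities of detected in-RF saccades in the free-viewing trace."""
    trace = bundle.free_view_traces[phase]
    events = detect_saccades(trace)
    rf = bundle.config.rf_center
    flags = classify_in_rf(events, rf)
    return np.array([e.peak_velocity for e, f in zip(events, flags) if f])


def run_scenario(config, parts=("stimulus", "motor", "behavior", "mua"),
                 report_seed: int = 0) -> dict:
    """Run one scenario end to end and assemble the report.

    ``config`` is a :class:`GeneratorConfig` or a path to a YAML file. The
    report carries a provenance block (config hash, seed, version) and is
    bit-identical for identical (config, seed).
    """
    if not isinstance(config, GeneratorConfig):
        config = load_config(config)
    bundle = generate_session(config, parts=frozenset(parts))
    report = {
        "scenario": config.scenario,
        "n_neurons_by_class": dict(config.n_neurons_by_class),
        "provenance": {"config_hash": config_hash(config),
                       "seed": config.seed, "version": __version__},
    }

    if "stimulus" in parts:
        vstats, vlog = visual_stats(bundle)
        report["visual"] = population_summary(vstats, seed=report_seed)
        report["visual"]["exclusions"] = vlog
    if "motor" in parts:
        mstats, _ = motor_stats(bundle)
        if len(mstats) >= 3:
            report["motor"] = population_summary(mstats, seed=report_seed)

    if "behavior" in parts:
        report["behavior"] = behavior_summary(bundle)
        try:
            report["scotoma"] = scotoma_analysis(bundle)
        except (ValueError, RuntimeError) as err:
            report["scotoma"] = {"error": str(err)}

    if "mua" in parts:
        lam = laminar_analysis(bundle)
        report["laminar"] = {
            phase: {"surface_channel": v["surface_channel"],
                    "n_significant": v["n_significant"]}
            for phase, v in lam.items()}

    if config.scenario == "LGN_plus_contraSC" and "stimulus" in parts:
        s1, _ = visual_stats(bundle, "before", "during_lgn")
        s2, _ = visual_stats(bundle, "before", "during_both")
        d1 = np.array([s.dfr_during for s in s1])
        d2 = np.array([s.dfr_during for s in s2])
        diff = d2 - d1
        p_rescue = 1.0 if np.all(diff == 0) else float(
            sps.wilcoxon(d1, d2, alternative="two-sided", method="approx").pvalue)
        report["rescue"] = {
            "p_signed_rank": p_rescue,
            "residual_during_lgn": float(d1.mean()),
            "residual_during_both": float(d2.mean()),
        }
        if "motor" in parts:
            vb = free_view_velocities(bundle, "before")
            vd = free_view_velocities(bundle, "during_both")
            report["velocity_check"] = saccade_velocity_check(vb, vd)

    return report


def pooled_v1_run(seeds, suppressions=None, neurons_per_session=None,
                  regression_rng: np.random.Generator | None = None) -> dict:
    """Multi-session V1 scenario: pooled percent reduction and overlap regression.

    One session per (seed, suppression); visually responsive neurons are
    pooled across sessions for the population summary, and the 12-condition
    overlap regression is computed from geometrically derived overlap
    fractions (see :func:`scgate.synthetic_data.generate_overlap_conditions`).
    """
    from .synthetic_data import (V1_SESSION_NEURONS, V1_SESSION_SUPPRESSIONS,
                                 generate_overlap_conditions, v1_session_config)
    suppressions = suppressions or V1_SESSION_SUPPRESSIONS
    neurons_per_session = neurons_per_session or V1_SESSION_NEURONS
    all_stats = []
    for seed, supp, n_vis in zip(seeds, suppressions, neurons_per_session):
        cfg = v1_session_config(seed=seed, suppression=supp, n_visual=n_vis)
        bundle = generate_session(cfg, parts={"stimulus"})
        vstats, _ = visual_stats(bundle)
        all_stats.extend(vstats)
    summary = population_summary(all_stats, seed=0)
    rng = regression_rng or np.random.default_rng(0)
    conditions = generate_overlap_conditions(rng=rng)
    summary["overlap_regression"] = overlap_regression(conditions)
    return summary


def magno_comparison(during_dfr_by_stimulus: dict,
                     static_key: str = "static") -> dict:
    """Paired one-sided tests of residual During responses for magno-favoring
    stimuli against their static counterpart.

    Each value of ``during_dfr_by_stimulus`` is a per-neuron array aligned on
    neuron; NaNs mark neurons missing for that stimulus and are dropped
    pairwise (with a log of how many). A stimulus absent from the mapping is
    simply absent from the result.
    """
    static = np.asarray(during_dfr_by_stimulus[static_key], dtype=float)
    out = {}
    for stim, vals in during_dfr_by_stimulus.items():
        if stim == static_key:
            continue
        v = np.asarray(vals, dtype=float)
        if v.size != static.size:
            raise ValueError(f"{stim} array not aligned with {static_key}")
        ok = ~np.isnan(v) & ~np.isnan(static)
        dropped = int(v.size - ok.sum())
        diff = v[ok] - static[ok]
        if diff.size == 0:
            continue
        p = 1.0 if np.all(diff == 0) else float(
            sps.wilcoxon(diff, alternative="greater", method="approx").pvalue)
        out[stim] = {"p": p, "n_pairs": int(ok.sum()), "n_dropped": dropped}
    return out


# ---------------------------------------------------------------------------
# config and session I/O


def load_config(path) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML file.

    Nested keys ``scotoma_truth`` (A, x0, y0, sx, sy, phi, c),
    ``stimulus_aperture`` (x, y, r) and ``rf_center`` (direction,
    eccentricity) map onto their dataclasses.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "scotoma_truth" in raw and isinstance(raw["scotoma_truth"], dict):
        d = raw["scotoma_truth"]
        raw["scotoma_truth"] = ScotomaModel(
            amplitude=d["A"], x0=d["x0"], y0=d["y0"], sigma_x=d["sx"],
            sigma_y=d["sy"], rotation=d.get("phi", 0.0), offset=d.get("c", 0.0))
    if "stimulus_aperture" in raw and isinstance(raw["stimulus_aperture"], dict):
        d = raw["stimulus_aperture"]
        raw["stimulus_aperture"] = StimulusAperture((d["x"], d["y"]),
                                                    d.get("r", 3.0))
    if "rf_center" in raw and isinstance(raw["rf_center"], dict):
        d = raw["rf_center"]
        raw["rf_center"] = ResponseField(d["direction"], d["eccentricity"])
    return GeneratorConfig(**raw)


def write_session(bundle: SessionBundle, out_dir) -> None:
    """Write a session to plain-text files (CSV tables + ground-truth JSON)."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for n in bundle.neurons:
        for phase, trials in n.stim_spikes.items():
            for trial, spk in enumerate(trials):
                rows.extend((n.id, trial, float(t), phase, "stim")
                            for t in spk)
        for phase, trials in n.motor_spikes.items():
            for trial, spk in enumerate(trials):
                rows.extend((n.id, trial, float(t), phase, "motor")
                            for t in spk)
    pd.DataFrame(rows, columns=["neuron_id", "trial_id", "t_ms", "phase",
                                "block"]).to_csv(
        f"{out_dir}/spikes.csv", index=False)
    bundle.event_table.to_csv(f"{out_dir}/events.csv", index=False)
    if len(bundle.behavior):
        bundle.behavior.to_csv(f"{out_dir}/behavior.csv", index=False)
    if bundle.eye_traces:
        frames = []
        for trial_id, trace in bundle.eye_traces.items():
            df = trace.to_frame()
            df.insert(0, "trial_id", trial_id)
            frames.append(df)
        pd.concat(frames).to_csv(f"{out_dir}/eye_traces.csv", index=False)
    if bundle.mua:
        frames = []
        for phase, mua in bundle.mua.items():
            df = mua.to_frame()
            df.insert(0, "phase", phase)
            frames.append(df)
        pd.concat(frames).to_csv(f"{out_dir}/mua.csv", index=False)
    truth = {
        "config": _jsonable(bundle.config),
        "neurons": [{"id": n.id, "class": n.functional_class,
                     "depth_um": n.depth_um, "snr": n.snr,
                     "true_evoked_before": n.true_evoked_before,
                     "true_evoked_during": n.true_evoked_during,
                     "true_motor_amplitude": n.true_motor_amplitude}
                    for n in bundle.neurons],
    }
    with open(f"{out_dir}/ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, default=str)
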