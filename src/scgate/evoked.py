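"""Per-neuron and population quantification of evoked activity.

The central quantity is the event-locked firing-rate change

    dFR = rate(response window) - rate(baseline window)   [spikes/s]

computed per trial with half-open windows relative to each event (stimulus
onset or saccade onset). The effect of an inactivation is summarized as
percent reduction, (dFR_Before - dFR_During) / dFR_Before * 100, and tested
per neuron (two-sided Wilcoxon rank-sum on per-trial dFR, Bonferroni over
the tested family) and per population (paired Wilcoxon signed-rank across
neurons, Pearson correlation of Before vs During values, bootstrap CIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnalysisWindows:
    """Analysis windows in ms relative to the aligning event (half-open)."""

    psth_bin: float = 20.0
    psth_step: float = 1.0
    visual_response: tuple = (30.0, 130.0)
    visual_baseline: tuple = (-100.0, 0.0)
    saccade_response: tuple = (-50.0, 25.0)
    saccade_baseline: tuple = (-300.0, -200.0)
    early_mua: tuple = (30.0, 80.0)
    mua_baseline: tuple = (-100.0, 0.0)

    def __post_init__(self) -> None:
        for resp, base in ((self.visual_response, self.visual_baseline),
                           (self.saccade_response, self.saccade_baseline),
                           (self.early_mua, self.mua_baseline)):
            if resp[1] <= resp[0] or base[1] <= base[0]:
                raise ValueError("windows must have positive duration")
            if not (resp[1] <= base[0] or base[1] <= resp[0]):
                raise ValueError("response and baseline windows must be disjoint")


@dataclass
class EvokedStats:
    """Before/During evoked activity for one neuron."""

    neuron_id: int
    functional_class: str
    dfr_before: float
    dfr_during: float
    per_trial_before: np.ndarray
    per_trial_during: np.ndarray
    p_between: float          # two-sided rank-sum, Before vs During
    p_residual: float         # right-tailed signed-rank, During vs 0
    percent_reduction: float  # NaN when dfr_before <= 0
    significant_reduction: bool
    significant_residual: bool
    n_comparisons: int
    depth_um: float = float("nan")


@dataclass
class PSTH:
    """Sliding-window peri-event time histogram (spikes/s)."""

    time_ms: np.ndarray       # window centers
    rate: np.ndarray          # per bin
    z_rate: np.ndarray | None = None


def apply_inclusion_filters(neurons, snr_min: float = 1.8,
                            rate_min: float = 1.0,
                            require_rf: bool = True,
                            required_phases=("before",)):
    """Retain neurons meeting the recording-quality criteria.

    A neuron is kept iff SNR >= ``snr_min``, overall firing rate >=
    ``rate_min`` spikes/s, it has a mapped RF, and it was held through every
    required phase. Returns (kept, exclusion_log) where the log lists
    (neuron_id, rule) for each exclusion.
    """
    kept, log = [], []
    for n in neurons:
        if n.snr < snr_min:
            log.append((n.id, "snr"))
            continue
        if n.mean_rate < rate_min:
            log.append((n.id, "rate"))
            continue
        if require_rf and not getattr(n, "has_rf", True):
            log.append((n.id, "no_rf"))
            continue
        phases = set(getattr(n, "stim_spikes", {})) | set(
            getattr(n, "motor_spikes", {}))
        if phases and not set(required_phases) <= phases:
            log.append((n.id, "phase_coverage"))
            continue
        kept.append(n)
    return kept, log


def _counts_in_window(trial_spikes, event_times, window):
    lo, hi = window
    counts = np.empty(len(event_times))
    for i, (spk, t0) in enumerate(zip(trial_spikes, event_times)):
        counts[i] = np.count_nonzero((spk >= t0 + lo) & (spk < t0 + hi))
    return counts


def delta_fr(trial_spikes, event_times, response_window, baseline_window):
    """Per-trial event-locked firing-rate change (spikes/s).

    ``trial_spikes`` holds one spike-time array per event (session clock);
    windows are half-open [start, end) in ms relative to each event.
    Returns (per_trial, mean).
    """
    event_times = np.asarray(event_times, dtype=float)
    if len(trial_spikes) != event_times.size:
        raise ValueError("one spike train per event is required")
    if event_times.size == 0:
        raise ValueError("need at least one event")
    rlen = (response_window[1] - response_window[0]) / 1000.0
    blen = (baseline_window[1] - baseline_window[0]) / 1000.0
    per_trial = (_counts_in_window(trial_spikes, event_times, response_window) / rlen
                 - _counts_in_window(trial_spikes, event_times, baseline_window) / blen)
    return per_trial, float(np.mean(per_trial))


def compute_psth(trial_spikes, event_times, span=(-100.0, 400.0),
                 windows: AnalysisWindows | None = None,
                 z_normalize: bool = False) -> PSTH:
    """Sliding-window PSTH: spike counts in ``psth_bin`` ms windows stepped by
    ``psth_step`` ms, averaged over events and scaled to spikes/s.

    The z-scored variant (display only) normalizes by the mean/SD pooled
    across all time bins.
    """
    windows = windows or AnalysisWindows()
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("need at least one event")
    half = windows.psth_bin / 2.0
    centers = np.arange(span[0] + half, span[1] - half + 1e-9, windows.psth_step)
    rate = np.zeros(centers.size)
    for spk, t0 in zip(trial_spikes, event_times):
        rel = np.asarray(spk, dtype=float) - t0
        rel = np.sort(rel[(rel >= span[0]) & (rel < span[1])])
        lo = np.searchsorted(rel, centers - half, side="left")
        hi = np.searchsorted(rel, centers + half, side="left")
        rate += hi - lo
    rate /= event_times.size * (windows.psth_bin / 1000.0)
    z = None
    if z_normalize:
        sd = rate.std()
        z = (rate - rate.mean()) / sd if sd > 0 else np.zeros_like(rate)
    return PSTH(time_ms=centers, rate=rate, z_rate=z)


def _ranksum_two_sided(a, b) -> float:
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _signed_rank_greater(x) -> float:
    x = np.asarray(x, dtype=float)
    if np.all(x == 0):
        return 1.0
    method = "exact" if (x.size <= 25 and not _has_ties(x)) else "approx"
    return float(stats.wilcoxon(x, alternative="greater", method=method).pvalue)


def _has_ties(x) -> bool:
    ax = np.abs(x[x != 0])
    return ax.size != np.unique(ax).size


def neuron_effect(before_dfr, during_dfr, n_comparisons: int,
                  neuron_id: int = -1, functional_class: str = "",
                  alpha: float = 0.05, depth_um: float = float("nan"),
                  min_trials: int = 5) -> EvokedStats:
    """Per-neuron Before/During comparison on per-trial dFR values.

    ``p_between`` is a two-sided Wilcoxon rank-sum between phases;
    ``p_residual`` a right-tailed signed-rank of the During per-trial dFR
    against zero. Both significance flags apply Bonferroni correction for
    ``n_comparisons`` tests at family alpha ``alpha``; the reduction flag
    additionally requires the During mean to be below the Before mean.
    """
    b = np.asarray(before_dfr, dtype=float)
    d = np.asarray(during_dfr, dtype=float)
    if b.size < min_trials or d.size < min_trials:
        raise ValueError(f"need >= {min_trials} trials per phase")
    p_between = _ranksum_two_sided(b, d)
    p_residual = _signed_rank_greater(d)
    mb, md = float(np.mean(b)), float(np.mean(d))
    reduction = (mb - md) / mb * 100.0 if mb > 0 else float("nan")
    thresh = alpha / max(n_comparisons, 1)
    return EvokedStats(
        neuron_id=neuron_id, functional_class=functional_class,
        dfr_before=mb, dfr_during=md,
        per_trial_before=b, per_trial_during=d,
        p_between=p_between, p_residual=p_residual,
        percent_reduction=reduction,
        significant_reduction=bool(p_between < thresh and md < mb),
        significant_residual=bool(p_residual < thresh),
        n_comparisons=n_comparisons, depth_um=depth_um,
    )


def _boot_ci(values, stat, n_boot, rng):
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    reps = stat(values[idx], axis=1)
    return tuple(np.percentile(reps, [2.5, 97.5]))


def population_summary(stats_list, n_boot: int = 10000,
                       seed: int | None = 0,
                       signed_rank_alternative: str = "two-sided") -> dict:
    """Population-level Before/During summary across neurons.

    Reports mean +- SEM dFR per phase, mean percent reduction (over neurons
    with positive Before dFR), a paired Wilcoxon signed-rank across neurons,
    Pearson correlation of Before vs During values, bootstrap 95% CIs
    (resampling neurons), and a per-class breakdown with a between-class
    rank-sum comparison of percent reduction.
    """
    if len(stats_list) < 3:
        raise ValueError("need at least 3 neurons")
    rng = np.random.default_rng(seed)
    before = np.array([s.dfr_before for s in stats_list])
    during = np.array([s.dfr_during for s in stats_list])
    red = np.array([s.percent_reduction for s in stats_list])
    red_ok = red[~np.isnan(red)]

    diff = before - during
    if np.all(diff == 0):
        p_paired = 1.0
    else:
        p_paired = float(stats.wilcoxon(
            before, during, alternative=signed_rank_alternative,
            method="approx").pvalue)
    if np.all(before == before[0]) or np.all(during == during[0]):
        pearson_r, pearson_p = float("nan"), float("nan")
    else:
        pr = stats.pearsonr(before, during)
        pearson_r, pearson_p = float(pr.statistic), float(pr.pvalue)

    out = {
        "n_neurons": len(stats_list),
        "dfr_before_mean": float(before.mean()),
        "dfr_before_sem": float(before.std(ddof=1) / np.sqrt(before.size)),
        "dfr_during_mean": float(during.mean()),
        "dfr_during_sem": float(during.std(ddof=1) / np.sqrt(during.size)),
        "mean_percent_reduction": float(red_ok.mean()) if red_ok.size else float("nan"),
        "percent_reduction_ci": _boot_ci(red_ok, np.mean, n_boot, rng)
        if red_ok.size else (float("nan"), float("nan")),
        "p_signed_rank": p_paired,
        "pearson_r": pearson_r,
        "pearson_p": pearson_p,
        "n_significant_reduction": int(sum(s.significant_reduction
                                           for s in stats_list)),
        "n_significant_residual": int(sum(s.significant_residual
                                          for s in stats_list)),
    }

    by_class = {}
    for cls in sorted({s.functional_class for s in stats_list}):
        sel = [s for s in stats_list if s.functional_class == cls]
        reds = np.array([s.percent_reduction for s in sel])
        reds = reds[~np.isnan(reds)]
        by_class[cls] = {
            "n": len(sel),
            "dfr_before_mean": float(np.mean([s.dfr_before for s in sel])),
            "dfr_during_mean": float(np.mean([s.dfr_during for s in sel])),
            "mean_percent_reduction": float(reds.mean()) if reds.size else float("nan"),
        }
    out["by_class"] = by_class
    classes = [c for c in by_class if by_class[c]["n"] >= 2]
    if len(classes) == 2:
        a = [s.percent_reduction for s in stats_list
             if s.functional_class == classes[0]
             and not np.isnan(s.percent_reduction)]
        b = [s.percent_reduction for s in stats_list
             if s.functional_class == classes[1]
             and not np.isnan(s.percent_reduction)]
        if len(a) >= 2 and len(b) >= 2:
            out["between_class_p"] = _ranksum_two_sided(a, b)
    return out


def saccade_velocity_check(before_velocities, during_velocities,
                           min_saccades: int = 5) -> dict:
    """One-sided rank-sum test for reduced peak saccade velocity During.

    Used to verify contralateral-SC inactivation: saccades into the
    inactivated field should slow down.
    """
    b = np.asarray(before_velocities, dtype=float)
    d = np.asarray(during_velocities, dtype=float)
    if b.size < min_saccades or d.size < min_saccades:
        raise ValueError(f"need >= {min_saccades} saccades per phase")
    p = float(stats.mannwhitneyu(d, b, alternative="less").pvalue)
    return {"p": p, "mean_before": float(b.mean()), "mean_during": float(d.mean()),
            "n_before": int(b.size), "n_during": int(d.size)}


def stats_to_frame(stats_list) -> pd.DataFrame:
    return pd.DataFrame({
        "neuron_id": [s.neuron_id for s in stats_list],
        "class": [s.functional_class for s in stats_list],
        "dfr_before": [s.dfr_before for s in stats_list],
        "dfr_during": [s.dfr_during for s in stats_list],
        "percent_reduction": [s.percent_reduction for s in stats_list],
        "p_between": [s.p_between for s in stats_list],
        "p_residual": [s.p_residual for s in stats_list],
        "significant_reduction": [s.significant_reduction for s in stats_list],
        "significant_residual": [s.significant_residual for s in stats_list],
        "depth_um": [s.depth_um for s in stats_list],
    })
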