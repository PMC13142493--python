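"""Laminar depth alignment from multiunit activity (MUA).

Recordings from a 32-channel probe (50 um spacing, channel 1 dorsal-most)
are aligned to a common depth origin by estimating the dorsal surface of the
structure from the emergence of visually evoked MUA. MUA is represented as
threshold-crossing event times per channel, computed at a sweep of negative
thresholds (-3 to -6 SD of each channel's noise in 0.5 SD steps). For each
threshold, a channel is "visually driven" if its trial-wise evoked rate
change is significantly above zero (right-tailed Wilcoxon signed-rank,
Benjamini-Hochberg FDR across channels); the estimated surface is the most
superficial channel starting a run of three consecutive significant
channels. The working threshold is the one whose surface estimates best
match independent single-unit-based estimates across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

THETA_GRID = tuple(np.arange(-3.0, -6.5, -0.5))   # SD of channel noise

#: analysis windows (ms relative to stimulus onset), half-open
MUA_RESPONSE_WINDOW = (30.0, 130.0)
MUA_BASELINE_WINDOW = (-100.0, 0.0)
EARLY_WINDOW = (30.0, 80.0)


@dataclass
class LaminarMUASet:
    """Threshold-crossing event times per channel and threshold level.

    ``events[theta][ch]`` is a list over trials of arrays of event times in
    ms relative to stimulus onset (channel index 0 = dorsal-most).
    """

    events: dict
    n_channels: int = 32
    channel_spacing_um: float = 50.0
    noise_sd: np.ndarray | None = None      # per-channel noise SD (arbitrary units)
    thetas: tuple = THETA_GRID

    def n_trials(self, theta: float) -> int:
        return len(self.events[theta][0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for theta, chans in self.events.items():
            for ch, trials in enumerate(chans):
                for trial, times in enumerate(trials):
                    for t in times:
                        rows.append((ch + 1, theta, trial, t))
        return pd.DataFrame(rows, columns=["channel", "theta_sd", "trial", "t_ms"])


@dataclass
class LaminarProfile:
    """Per-channel evoked MUA values with surface estimate for one session."""

    evoked: np.ndarray                     # (n_channels,) spikes/s
    significant: np.ndarray                # (n_channels,) bool
    surface_channel: int | None            # 1-based index, None if undefined
    channel_spacing_um: float = 50.0


@dataclass
class DepthBands:
    """Superficial vs deep comparison bands, um relative to the reference."""

    superficial: tuple = (-50.0, 250.0)
    deep: tuple = (600.0, 900.0)

    def __post_init__(self) -> None:
        lo1, hi1 = self.superficial
        lo2, hi2 = self.deep
        if max(lo1, lo2) <= min(hi1, hi2) and max(lo1, lo2) < min(hi1, hi2):
            if not (hi1 <= lo2 or hi2 <= lo1):
                raise ValueError("bands must be disjoint")


def _window_counts(trials, window):
    lo, hi = window
    return np.array([np.count_nonzero((t >= lo) & (t < hi)) for t in trials])


def trial_delta_fr(trials, response=MUA_RESPONSE_WINDOW,
                   baseline=MUA_BASELINE_WINDOW) -> np.ndarray:
    """Per-trial evoked rate change (spikes/s) for one channel's event times."""
    rlen = (response[1] - response[0]) / 1000.0
    blen = (baseline[1] - baseline[0]) / 1000.0
    return _window_counts(trials, response) / rlen - _window_counts(trials, baseline) / blen


def _signed_rank_greater(x: np.ndarray) -> float:
    """Right-tailed Wilcoxon signed-rank p of x against zero (p=1 if all zero)."""
    x = np.asarray(x, dtype=float)
    if np.all(x == 0):
        return 1.0
    return float(stats.wilcoxon(x, alternative="greater", method="approx").pvalue)


def channel_significance(mua: LaminarMUASet, theta: float,
                         response=MUA_RESPONSE_WINDOW,
                         baseline=MUA_BASELINE_WINDOW,
                         q: float = 0.05) -> pd.DataFrame:
    """Per-channel evoked rate change and BH-FDR-corrected significance.

    Tests whether the trial-wise rate change is greater than zero on each
    channel (right-tailed signed-rank), then controls FDR at ``q`` across
    the probe's channels.
    """
    if not any(np.isclose(theta, t) for t in mua.thetas):
        raise ValueError(f"theta {theta} not in the sweep grid {mua.thetas}")
    theta = float(mua.thetas[int(np.argmin(np.abs(np.asarray(mua.thetas) - theta)))])
    chans = mua.events[theta]
    if len(chans[0]) < 10:
        raise ValueError("need at least 10 stimulus events")
    dfrs = [trial_delta_fr(trials, response, baseline) for trials in chans]
    pvals = np.array([_signed_rank_greater(d) for d in dfrs])
    flags, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return pd.DataFrame({
        "channel": np.arange(1, len(chans) + 1),
        "delta_fr": [float(np.mean(d)) for d in dfrs],
        "p": pvals,
        "p_fdr": p_adj,
        "significant": flags,
    })


def estimate_surface(flags) -> int | None:
    """Most superficial channel starting a run of 3 consecutive significant
    channels (1-based); None when no such run exists."""
    f = np.asarray(flags, dtype=bool)
    for i in range(len(f) - 2):
        if f[i] and f[i + 1] and f[i + 2]:
            return i + 1
    return None


def select_threshold(mua_surfaces, su_surfaces, thetas=THETA_GRID):
    """Pick the threshold whose MUA surface estimates best match single-unit ones.

    ``mua_surfaces`` is a list (one per session) of {theta: channel or None};
    ``su_surfaces`` the per-session single-unit surface channels. For each
    theta, sessions with undefined estimates are dropped and the Pearson
    correlation across the rest is computed; the argmax wins, ties broken
    toward smaller |theta|. Returns (theta_star, table) where table maps
    theta -> (correlation, n_sessions_used).
    """
    su = np.asarray(su_surfaces, dtype=float)
    if len(mua_surfaces) != len(su):
        raise ValueError("mua_surfaces and su_surfaces must align")
    table = {}
    best_theta, best_r = None, -np.inf
    for theta in sorted(thetas, key=abs):          # smaller |theta| first
        est = np.array([s.get(theta) if s.get(theta) is not None else np.nan
                        for s in mua_surfaces], dtype=float)
        ok = ~np.isnan(est)
        n = int(ok.sum())
        if n < 3:
            table[theta] = (np.nan, n)
            continue
        if np.all(est[ok] == est[ok][0]) or np.all(su[ok] == su[ok][0]):
            r = np.nan                              # no variance: undefined
        else:
            r = float(stats.pearsonr(est[ok], su[ok]).statistic)
        table[theta] = (r, n)
        if np.isfinite(r) and r > best_r:           # strict >: first (smallest
            best_r, best_theta = r, theta           # |theta|) wins ties
    if best_theta is None:
        raise ValueError("no threshold has >= 3 usable sessions with variance")
    return float(best_theta), table


def align_profiles(profiles: list[LaminarProfile]):
    """Shift per-session channel vectors so surface channels are co-linear.

    Returns (depth_um, matrix, dropped) where matrix is sessions x depths with
    NaN outside each probe's extent, depth 0 at the estimated surface, and
    ``dropped`` lists indices of profiles without a surface estimate.
    """
    usable = [(i, p) for i, p in enumerate(profiles) if p.surface_channel is not None]
    dropped = [i for i, p in enumerate(profiles) if p.surface_channel is None]
    if not usable:
        raise ValueError("no profile has a defined surface estimate")
    spacing = usable[0][1].channel_spacing_um
    # channel ch (1-based) sits at depth (ch - surface) * spacing
    offsets = []
    for _, p in usable:
        n = len(p.evoked)
        offsets.append((1 - p.surface_channel, n - p.surface_channel))
    lo = min(o[0] for o in offsets)
    hi = max(o[1] for o in offsets)
    depth = np.arange(lo, hi + 1) * spacing
    mat = np.full((len(usable), depth.size), np.nan)
    for row, (_, p) in enumerate(usable):
        n = len(p.evoked)
        start = (1 - p.surface_channel) - lo
        mat[row, start:start + n] = p.evoked
    return depth, mat, dropped


def _band_mean(depth, row, band):
    lo, hi = band
    sel = (depth >= lo) & (depth <= hi)
    vals = row[sel]
    vals = vals[~np.isnan(vals)]
    return float(np.mean(vals)) if vals.size else np.nan


def band_compare(depth: np.ndarray, matrix: np.ndarray,
                 bands: DepthBands | None = None) -> dict:
    """One-sided test for elevated activity in the superficial band.

    Computes each session's mean evoked MUA in the superficial and deep bands
    and tests superficial > deep with a one-sided Wilcoxon signed-rank.
    """
    bands = bands or DepthBands()
    sup = np.array([_band_mean(depth, row, bands.superficial) for row in matrix])
    deep = np.array([_band_mean(depth, row, bands.deep) for row in matrix])
    ok = ~np.isnan(sup) & ~np.isnan(deep)
    if ok.sum() < 3:
        raise ValueError("need >= 3 datasets contributing both bands")
    diff = sup[ok] - deep[ok]
    if np.all(diff == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff, alternative="greater", method="approx").pvalue)
    return {"p": p, "superficial_mean": float(np.mean(sup[ok])),
            "deep_mean": float(np.mean(deep[ok])), "n_datasets": int(ok.sum())}


def band_sweep(depth: np.ndarray, matrix: np.ndarray,
               band_pairs) -> pd.DataFrame:
    """Exploratory band_compare over candidate (superficial, deep) band pairs.

    No multiplicity correction is applied; the sweep is a robustness probe,
    not confirmatory inference.
    """
    rows = []
    for sup_band, deep_band in band_pairs:
        try:
            res = band_compare(depth, matrix, DepthBands(tuple(sup_band),
                                                         tuple(deep_band)))
            rows.append((*sup_band, *deep_band, res["p"], res["n_datasets"]))
        except ValueError:
            rows.append((*sup_band, *deep_band, np.nan, 0))
    return pd.DataFrame(rows, columns=["sup_lo", "sup_hi", "deep_lo", "deep_hi",
                                       "p", "n_datasets"])


def reduction_vs_depth(percent_reduction, depth_um) -> tuple:
    """Pearson correlation between percent reduction and aligned depth."""
    r_ = np.asarray(percent_reduction, dtype=float)
    d = np.asarray(depth_um, dtype=float)
    ok = ~np.isnan(r_) & ~np.isnan(d)
    if ok.sum() < 5:
        raise ValueError("need >= 5 neurons with aligned depth")
    if np.all(d[ok] == d[ok][0]):
        raise ValueError("constant depth vector: correlation undefined")
    res = stats.pearsonr(r_[ok], d[ok])
    return float(res.statistic), float(res.pvalue)
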