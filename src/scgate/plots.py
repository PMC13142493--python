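"""Figure helpers: population PSTHs and failure-map/scotoma overlays."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evoked import PSTH
from .scotoma import FailureMap, ScotomaModel, mass_contour


def plot_psth_pair(before: PSTH, during: PSTH, window=(30.0, 130.0),
                   ax=None, labels=("Before", "During")):
    """Before/During population PSTHs with the response window shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.axvspan(*window, color="0.85", zorder=0)
    ax.plot(before.time_ms, before.rate, color="k", label=labels[0])
    ax.plot(during.time_ms, during.rate, color="crimson", label=labels[1])
    ax.set_xlabel("time from event (ms)")
    ax.set_ylabel("firing rate (spikes/s)")
    ax.legend(frameon=False)
    return ax


def plot_failure_map(fmap: FailureMap, model: ScotomaModel | None = None,
                     mass: float = 0.95, ax=None):
    """Failure-fraction heat map with the fitted scotoma contour overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4))
    extent = [fmap.x_centers[0], fmap.x_centers[-1],
              fmap.y_centers[0], fmap.y_centers[-1]]
    im = ax.imshow(fmap.fail_fraction, origin="lower", extent=extent,
                   vmin=0, vmax=1, cmap="magma", aspect="equal")
    plt.colorbar(im, ax=ax, label="fraction failed")
    if model is not None:
        ell = mass_contour(model, mass)
        th = np.linspace(0, 2 * np.pi, 200)
        ux, uy = ell.a * np.cos(th), ell.b * np.sin(th)
        c, s = np.cos(ell.rotation), np.sin(ell.rotation)
        ax.plot(ell.center[0] + ux * c - uy * s,
                ax.set_ylim()[0] * 0 + ell.center[1] + ux * s + uy * c,
                color="w", lw=1.5)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    return ax


def plot_laminar_profile(depth_um, matrix, bands=None, ax=None):
    """Depth-aligned evoked MUA: per-session traces and the ignore-missing mean."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 4.5))
    for row in matrix:
        ax.plot(row, depth_um, color="0.8", lw=0.8)
    ax.plot(np.nanmean(matrix, axis=0), depth_um, color="k", lw=2)
    if bands is not None:
        for lo, hi in (bands.superficial, bands.deep):
            ax.axhspan(lo, hi, color="0.92", zorder=0)
    ax.invert_yaxis()
    ax.set_xlabel("evoked MUA (spikes/s)")
    ax.set_ylabel("depth from surface (um)")
    return ax
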