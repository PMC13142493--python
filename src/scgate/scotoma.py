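"""Behavioral scotoma quantification.

An inactivation-induced scotoma is mapped with a visually guided saccade
task: targets tile the visual field and each location's failure fraction is
binned on a Cartesian grid. The binned map is fit with a rotated 2D Gaussian
plus constant offset,

    p(x, y) = A * exp(-q/2) + c,
    q = ((dx cos(phi) + dy sin(phi)) / sx)^2 + ((-dx sin(phi) + dy cos(phi)) / sy)^2,

the scotoma boundary is the elliptical contour containing a given fraction
of the Gaussian's mass, and spatial specificity is expressed as the fraction
of a circular stimulus aperture falling inside that contour. Session-level
inference uses Fisher's exact test on the 2x2 phase-by-outcome table and
Fisher's combined probability test across sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from shapely.geometry import Point


@dataclass
class GridSpec:
    """Cartesian binning grid for failure maps (2 deg square bins by default)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    step: float = 2.0

    @property
    def x_edges(self) -> np.ndarray:
        n = max(1, int(round((self.x_max - self.x_min) / self.step)))
        return self.x_min + self.step * np.arange(n + 1)

    @property
    def y_edges(self) -> np.ndarray:
        n = max(1, int(round((self.y_max - self.y_min) / self.step)))
        return self.y_min + self.step * np.arange(n + 1)


@dataclass
class FailureMap:
    """Per-bin saccade failure fractions on a Cartesian grid."""

    x_centers: np.ndarray        # (nx,)
    y_centers: np.ndarray        # (ny,)
    fail_fraction: np.ndarray    # (ny, nx), NaN where missing
    n_trials: np.ndarray         # (ny, nx) integer counts

    @property
    def missing(self) -> np.ndarray:
        return self.n_trials == 0

    def flat(self):
        """(x, y, fraction) arrays over non-missing bins."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        ok = ~self.missing
        return xx[ok], yy[ok], self.fail_fraction[ok]


@dataclass
class ScotomaModel:
    """Rotated 2D Gaussian + offset model of a failure map."""

    amplitude: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    rotation: float          # radians, wrapped to [0, pi)
    offset: float
    residual_norm: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be > 0")

    def predict(self, x, y) -> np.ndarray:
        dx = np.asarray(x, dtype=float) - self.x0
        dy = np.asarray(y, dtype=float) - self.y0
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        u = (dx * c + dy * s) / self.sigma_x
        v = (-dx * s + dy * c) / self.sigma_y
        return self.amplitude * np.exp(-(u * u + v * v) / 2.0) + self.offset

    def failure_probability(self, x, y) -> np.ndarray:
        """Model prediction clipped to [0, 1] for simulating Bernoulli outcomes."""
        return np.clip(self.predict(x, y), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"A": self.amplitude, "x0": self.x0, "y0": self.y0,
                "sx": self.sigma_x, "sy": self.sigma_y, "phi": self.rotation,
                "c": self.offset, "residual": self.residual_norm}


@dataclass
class EllipseRegion:
    center: tuple
    a: float                 # semi-axis, deg
    b: float
    rotation: float          # radians

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be > 0")

    def polygon(self, n_vertices: int = 720):
        """Shapely polygon approximation with >= n_vertices vertices."""
        th = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        ux, uy = self.a * np.cos(th), self.b * np.sin(th)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        xs = self.center[0] + ux * c - uy * s
        ys = self.center[1] + ux * s + uy * c
        from shapely.geometry import Polygon
        return Polygon(zip(xs, ys))

    def contains_points(self, x, y) -> np.ndarray:
        """Exact membership test (used by the Monte-Carlo oracle and tests)."""
        dx = np.asarray(x) - self.center[0]
        dy = np.asarray(y) - self.center[1]
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        u = (dx * c + dy * s) / self.a
        v = (-dx * s + dy * c) / self.b
        return u * u + v * v <= 1.0


@dataclass
class StimulusAperture:
    """Circular stimulus aperture (default radius 3 deg, i.e. a 6 deg aperture)."""

    center: tuple
    radius: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    def polygon(self, n_vertices: int = 720):
        return Point(self.center).buffer(self.radius,
                                         quad_segs=max(128, n_vertices // 4))


def bin_failure_map(trials: pd.DataFrame, grid: GridSpec | None = None) -> FailureMap:
    """Bin scored guided-saccade trials into a failure map.

    ``trials`` needs columns ``target_x_deg``, ``target_y_deg``, ``outcome``
    ("success"/"fail"). When ``grid`` is None, 2 deg bins covering the tested
    targets are used.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    x = trials["target_x_deg"].to_numpy(dtype=float)
    y = trials["target_y_deg"].to_numpy(dtype=float)
    fail = (trials["outcome"] == "fail").to_numpy()
    if grid is None:
        step = 2.0
        grid = GridSpec(np.floor(x.min() / step) * step,
                        np.ceil(x.max() / step) * step + step,
                        np.floor(y.min() / step) * step,
                        np.ceil(y.max() / step) * step + step, step)
    xe, ye = grid.x_edges, grid.y_edges
    total, _, _ = np.histogram2d(y, x, bins=[ye, xe])
    fails, _, _ = np.histogram2d(y[fail], x[fail], bins=[ye, xe])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, fails / total, np.nan)
    return FailureMap(
        x_centers=(xe[:-1] + xe[1:]) / 2.0,
        y_centers=(ye[:-1] + ye[1:]) / 2.0,
        fail_fraction=frac,
        n_trials=total.astype(int),
    )


def _model_vec(params, x, y):
    a, x0, y0, sx, sy, phi, c = params
    dx, dy = x - x0, y - y0
    cph, sph = math.cos(phi), math.sin(phi)
    u = (dx * cph + dy * sph) / abs(sx)
    v = (-dx * sph + dy * cph) / abs(sy)
    return a * np.exp(-(u * u + v * v) / 2.0) + c


def fit_scotoma(fmap: FailureMap) -> ScotomaModel:
    """Least-squares fit of the rotated Gaussian + offset to a failure map.

    Multi-start initialization (center at the max-failure bin and at the map
    centroid; sigma at 2 and 6 deg; rotation at 0 and pi/4) guards against the
    rotation/width local minima this model family is prone to. Predictions are
    not clipped during fitting; the fitted amplitude-plus-offset may exceed 1.
    """
    x, y, z = fmap.flat()
    if x.size < 7:
        raise ValueError("need at least 7 non-missing bins (7 parameters)")

    zmax_i = int(np.argmax(z))
    centers = [(x[zmax_i], y[zmax_i]),
               (float(np.average(x, weights=np.maximum(z, 1e-9))),
                float(np.average(y, weights=np.maximum(z, 1e-9))))]
    best = None
    for cx, cy in centers:
        for sig in (2.0, 6.0):
            for phi0 in (0.0, math.pi / 4):
                p0 = [max(z.max() - z.min(), 0.05), cx, cy, sig, sig, phi0,
                      max(z.min(), 0.0)]
                try:
                    res = optimize.least_squares(
                        lambda p: _model_vec(p, x, y) - z, p0, method="lm",
                        max_nfev=5000)
                except Exception:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
    if best is None:
        raise RuntimeError("scotoma fit failed for every initialization")

    a, x0, y0, sx, sy, phi, c = best.x
    sx, sy = abs(sx), abs(sy)
    if sx < sy:  # canonical form: major axis first (swap is a 90 deg rotation)
        sx, sy = sy, sx
        phi += math.pi / 2
    if a < 0:  # negative-amplitude minimum: equivalent positive form not taken;
        # report as-is but flag (a flat/degenerate map)
        pass
    return ScotomaModel(
        amplitude=float(a), x0=float(x0), y0=float(y0),
        sigma_x=float(sx), sigma_y=float(sy),
        rotation=float(phi % math.pi), offset=float(c),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
    )


def mass_contour(model: ScotomaModel, mass: float = 0.95) -> EllipseRegion:
    """Elliptical contour containing ``mass`` of the Gaussian component.

    Semi-axes are k*sigma with k = sqrt(-2 ln(1 - mass)); the constant offset
    plays no role (it is background, not scotoma).
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    k = math.sqrt(-2.0 * math.log(1.0 - mass))
    return EllipseRegion(center=(model.x0, model.y0),
                         a=k * model.sigma_x, b=k * model.sigma_y,
                         rotation=model.rotation)


def stimulus_overlap(ellipse: EllipseRegion, aperture: StimulusAperture,
                     n_vertices: int = 720) -> float:
    """Fraction of stimulus area inside the scotoma contour.

    Both shapes are approximated by polygons with >= 512 vertices and clipped
    exactly; the area ratio is accurate to better than 1e-3.
    """
    circle = aperture.polygon(n_vertices)
    ell = ellipse.polygon(n_vertices)
    inter = ell.intersection(circle)
    return float(inter.area / circle.area)


def session_failure_test(before: tuple, during: tuple) -> float:
    """Two-sided Fisher's exact p for the 2x2 (phase x outcome) table.

    ``before`` and ``during`` are (fails, successes) integer counts.
    """
    bf, bs = before
    df_, ds = during
    for v in (bf, bs, df_, ds):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    if bf + bs == 0 or df_ + ds == 0:
        raise ValueError("each phase needs at least one trial")
    _, p = stats.fisher_exact([[bf, bs], [df_, ds]], alternative="two-sided")
    return float(p)


def fisher_combined(pvals) -> tuple:
    """Fisher's combined probability test.

    X = -2 sum(ln p_i) referred to chi^2 with 2k degrees of freedom.
    Returns (statistic, combined p).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(x), float(stats.chi2.sf(x, 2 * p.size))


def _wls_fit(x, y, w):
    """Closed-form weighted least squares line fit; returns (slope, intercept)."""
    w = w / w.sum()
    xm = np.sum(w * x)
    ym = np.sum(w * y)
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise ValueError("regression undefined: no spread in x")
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    return slope, ym - slope * xm


def overlap_regression(conditions, n_boot: int = 10000,
                       seed: int | None = 0) -> dict:
    """Weighted regression of percent reduction on stimulus-scotoma overlap.

    ``conditions`` is an iterable of (overlap_fraction, percent_reduction,
    n_neurons); weights are the per-condition neuron counts. The 95% CI for
    slope and intercept comes from a bootstrap over conditions; Spearman rank
    correlation (mid-rank ties) accompanies the fit.
    """
    cond = [(float(o), float(r), float(n)) for o, r, n in conditions]
    if len(cond) < 3:
        raise ValueError("need at least 3 conditions")
    x = np.array([c[0] for c in cond])
    y = np.array([c[1] for c in cond])
    w = np.array([c[2] for c in cond])
    if np.allclose(x, x[0]):
        raise ValueError("regression undefined: all overlaps identical")

    slope, intercept = _wls_fit(x, y, w)
    rho, rho_p = stats.spearmanr(x, y)

    rng = np.random.default_rng(seed)
    k = len(cond)
    boot = np.full((n_boot, 2), np.nan)
    for i in range(n_boot):
        idx = rng.integers(0, k, k)
        xb, yb, wb = x[idx], y[idx], w[idx]
        if np.allclose(xb, xb[0]):
            continue
        boot[i] = _wls_fit(xb, yb, wb)
    ok = ~np.isnan(boot[:, 0])
    slope_ci = tuple(np.percentile(boot[ok, 0], [2.5, 97.5]))
    intercept_ci = tuple(np.percentile(boot[ok, 1], [2.5, 97.5]))
    return {
        "slope": float(slope), "intercept": float(intercept),
        "slope_ci": slope_ci, "intercept_ci": intercept_ci,
        "spearman_r": float(rho), "spearman_p": float(rho_p),
        "n_conditions": k,
    }
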