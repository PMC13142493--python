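"""Scotoma geometry and statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from scgate.scotoma import (EllipseRegion, FailureMap, GridSpec, ScotomaModel,
                            StimulusAperture, bin_failure_map, fisher_combined,
                            fit_scotoma, mass_contour, overlap_regression,
                            session_failure_test, stimulus_overlap)


# ---------------------------------------------------------------------------
# oracles


def fisher_exact_enumeration(before, during):
    """Two-sided Fisher p by exhaustive enumeration of tables with fixed
    margins: sum hypergeometric probabilities of all tables no more likely
    than the observed one."""
    a, b = before
    c, d = during
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def p_table(x):         # x = top-left cell
        return (comb(row1, x, exact=True) * comb(row2, col1 - x, exact=True)
                / comb(n, col1, exact=True))

    p_obs = p_table(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = p_table(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def mc_overlap(ellipse: EllipseRegion, aperture: StimulusAperture,
               n_points: int, rng) -> float:
    """Rejection-sampling oracle: fraction of points uniform in the circle
    that fall inside the ellipse."""
    r = aperture.radius * np.sqrt(rng.random(n_points))
    th = rng.uniform(0, 2 * np.pi, n_points)
    x = aperture.center[0] + r * np.cos(th)
    y = aperture.center[1] + r * np.sin(th)
    return float(np.mean(ellipse.contains_points(x, y)))


def _map_from_model(model, noise_trials=None, rng=None,
                    extent=12.0, step=2.0):
    grid = GridSpec(model.x0 - extent, model.x0 + extent,
                    model.y0 - extent, model.y0 + extent, step)
    xc = (grid.x_edges[:-1] + grid.x_edges[1:]) / 2
    yc = (grid.y_edges[:-1] + grid.y_edges[1:]) / 2
    xx, yy = np.meshgrid(xc, yc)
    p = model.failure_probability(xx, yy)
    if noise_trials is None:
        frac = p
        n = np.full(p.shape, 1000)
    else:
        fails = rng.binomial(noise_trials, p)
        frac = fails / noise_trials
        n = np.full(p.shape, noise_trials)
    return FailureMap(xc, yc, frac, n)


# ---------------------------------------------------------------------------


class TestFailureMap:
    def test_counting(self):
        trials = pd.DataFrame({
            "target_x_deg": [0.5] * 10, "target_y_deg": [0.5] * 10,
            "outcome": ["fail"] * 3 + ["success"] * 7})
        fmap = bin_failure_map(trials, GridSpec(0, 2, 0, 2, 2.0))
        assert fmap.fail_fraction[0, 0] == pytest.approx(0.30)
        assert fmap.n_trials[0, 0] == 10

    def test_all_success_gives_zero(self):
        trials = pd.DataFrame({
            "target_x_deg": np.repeat([1.0, 3.0], 5),
            "target_y_deg": 1.0, "outcome": "success"})
        fmap = bin_failure_map(trials, GridSpec(0, 4, 0, 2, 2.0))
        assert np.nanmax(fmap.fail_fraction) == 0.0

    def test_fractions_are_integer_ratios(self):
        rng = np.random.default_rng(0)
        trials = pd.DataFrame({
            "target_x_deg": rng.uniform(0, 8, 200),
            "target_y_deg": rng.uniform(0, 8, 200),
            "outcome": rng.choice(["fail", "success"], 200)})
        fmap = bin_failure_map(trials)
        ok = ~fmap.missing
        counts = fmap.fail_fraction[ok] * fmap.n_trials[ok]
        assert np.allclose(counts, np.round(counts))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bin_failure_map(pd.DataFrame(columns=["target_x_deg",
                                                  "target_y_deg", "outcome"]))

    def test_binned_map_within_binomial_ci_of_truth(self, rng):
        model = ScotomaModel(0.8, -8.0, -4.0, 4.0, 3.0, 0.3, 0.05)
        n = 200
        fmap = _map_from_model(model, noise_trials=n, rng=rng)
        xx, yy = np.meshgrid(fmap.x_centers, fmap.y_centers)
        p = model.failure_probability(xx, yy)
        # 99.99% binomial band
        half = 3.9 * np.sqrt(p * (1 - p) / n) + 1.0 / n
        assert np.all(np.abs(fmap.fail_fraction - p) <= half)


class TestScotomaFit:
    TRUTH = ScotomaModel(0.9, -8.0, -4.0, 4.0, 2.0, 0.5, 0.05)

    def test_noiseless_recovery_within_one_percent(self):
        fit = fit_scotoma(_map_from_model(self.TRUTH))
        assert fit.amplitude == pytest.approx(0.9, rel=0.01)
        assert fit.x0 == pytest.approx(-8.0, abs=0.08)
        assert fit.y0 == pytest.approx(-4.0, abs=0.04)
        assert fit.sigma_x == pytest.approx(4.0, rel=0.01)
        assert fit.sigma_y == pytest.approx(2.0, rel=0.01)
        assert fit.offset == pytest.approx(0.05, abs=0.005)
        assert (fit.rotation % math.pi) == pytest.approx(0.5, abs=0.02)

    def test_flat_map_degenerates_to_offset(self):
        xc = np.arange(-5.0, 6.0, 2.0)
        fmap = FailureMap(xc, xc, np.full((xc.size, xc.size), 0.1),
                          np.full((xc.size, xc.size), 50))
        fit = fit_scotoma(fmap)
        xx, yy = np.meshgrid(xc, xc)
        assert np.allclose(fit.predict(xx, yy), 0.1, atol=0.01)

    def test_rotation_wrap_equivalence(self):
        a = ScotomaModel(0.8, 0.0, 0.0, 4.0, 2.0, 0.7, 0.0)
        b = ScotomaModel(0.8, 0.0, 0.0, 4.0, 2.0, 0.7 + math.pi, 0.0)
        x = np.linspace(-10, 10, 41)
        xx, yy = np.meshgrid(x, x)
        assert np.allclose(a.predict(xx, yy), b.predict(xx, yy))

    def test_too_few_bins_rejected(self):
        fmap = FailureMap(np.array([0.0, 2.0]), np.array([0.0, 2.0]),
                          np.full((2, 2), 0.5), np.full((2, 2), 10))
        with pytest.raises(ValueError):
            fit_scotoma(fmap)

    def test_parameter_recovery_under_binomial_noise(self):
        # median center error < 0.5 deg, median sigma relative error < 10%
        rng = np.random.default_rng(42)
        center_err, sig_err = [], []
        for _ in range(100):
            truth = ScotomaModel(
                amplitude=rng.uniform(0.5, 0.95),
                x0=rng.uniform(-9, -7), y0=rng.uniform(-5, -3),
                sigma_x=rng.uniform(4.0, 6.0), sigma_y=rng.uniform(2.0, 3.8),
                rotation=rng.uniform(0, math.pi), offset=rng.uniform(0, 0.1))
            fit = fit_scotoma(_map_from_model(truth, noise_trials=50, rng=rng))
            center_err.append(math.hypot(fit.x0 - truth.x0, fit.y0 - truth.y0))
            sig_err.append(max(abs(fit.sigma_x - truth.sigma_x) / truth.sigma_x,
                               abs(fit.sigma_y - truth.sigma_y) / truth.sigma_y))
        assert np.median(center_err) < 0.5
        assert np.median(sig_err) < 0.10


class TestMassContour:
    def test_95_percent_circle_radius_closed_form(self):
        model = ScotomaModel(1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0)
        ell = mass_contour(model, 0.95)
        # independent oracle: solve 1 - exp(-r^2/2) = 0.95 numerically
        from scipy.optimize import brentq
        r_star = brentq(lambda r: 1 - math.exp(-r * r / 2) - 0.95, 0.1, 10.0)
        assert ell.a == pytest.approx(r_star, abs=1e-6)
        assert ell.a == pytest.approx(math.sqrt(-2 * math.log(0.05)), abs=1e-9)

    def test_unit_k_mass(self):
        mass = 1 - math.exp(-0.5)
        ell = mass_contour(ScotomaModel(1, 0, 0, 3.0, 2.0, 0.2, 0.0), mass)
        assert ell.a == pytest.approx(3.0, rel=1e-9)
        assert ell.b == pytest.approx(2.0, rel=1e-9)

    def test_semi_axes_monotone_in_mass(self):
        model = ScotomaModel(1, 0, 0, 3.0, 2.0, 0.0, 0.0)
        sizes = [mass_contour(model, m).a for m in (0.05, 0.3, 0.6, 0.95)]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] < 1.0

    @pytest.mark.parametrize("mass", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_mass_rejected(self, mass):
        with pytest.raises(ValueError):
            mass_contour(ScotomaModel(1, 0, 0, 1, 1, 0, 0), mass)


class TestStimulusOverlap:
    def test_contained_aperture_gives_one(self):
        ell = EllipseRegion((0, 0), 50.0, 40.0, 0.3)
        assert stimulus_overlap(ell, StimulusAperture((2.0, 1.0), 3.0)) \
            == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_shapes_give_zero(self):
        ell = EllipseRegion((0, 0), 2.0, 1.0, 0.0)
        assert stimulus_overlap(ell, StimulusAperture((10.0, 0.0), 3.0)) == 0.0

    def test_half_overlap_on_huge_ellipse_boundary(self, rng):
        # circle centered on the (locally straight) boundary of a huge ellipse
        ell = EllipseRegion((0, 0), 100.0, 100.0, 0.0)
        frac = stimulus_overlap(ell, StimulusAperture((100.0, 0.0), 3.0))
        assert frac == pytest.approx(0.5, abs=0.01)
        assert frac == pytest.approx(
            mc_overlap(ell, StimulusAperture((100.0, 0.0), 3.0), 10 ** 6, rng),
            abs=0.005)

    def test_matches_monte_carlo_oracle_on_random_pairs(self, rng):
        for _ in range(10):
            ell = EllipseRegion((rng.uniform(-5, 5), rng.uniform(-5, 5)),
                                rng.uniform(1, 10), rng.uniform(1, 10),
                                rng.uniform(0, math.pi))
            ap = StimulusAperture((rng.uniform(-8, 8), rng.uniform(-8, 8)),
                                  rng.uniform(1, 5))
            exact = stimulus_overlap(ell, ap)
            assert exact == pytest.approx(mc_overlap(ell, ap, 200_000, rng),
                                          abs=0.01)

    def test_rigid_transform_invariance(self, rng):
        ell = EllipseRegion((1.0, -2.0), 5.0, 3.0, 0.4)
        ap = StimulusAperture((3.0, -3.0), 2.5)
        base = stimulus_overlap(ell, ap)
        for _ in range(5):
            phi = rng.uniform(0, 2 * math.pi)
            dx, dy = rng.uniform(-10, 10, 2)
            c, s = math.cos(phi), math.sin(phi)

            def move(p):
                return (c * p[0] - s * p[1] + dx, s * p[0] + c * p[1] + dy)

            ell2 = EllipseRegion(move(ell.center), ell.a, ell.b,
                                 ell.rotation + phi)
            ap2 = StimulusAperture(move(ap.center), ap.radius)
            assert stimulus_overlap(ell2, ap2) == pytest.approx(base, abs=1e-3)

    def test_overlap_monotone_in_contour_mass(self):
        model = ScotomaModel(0.9, 0.0, 0.0, 4.0, 3.0, 0.2, 0.0)
        ap = StimulusAperture((4.0, 0.0), 3.0)
        vals = [stimulus_overlap(mass_contour(model, m), ap)
                for m in (0.2, 0.5, 0.8, 0.95)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestSessionFailureTest:
    def test_identical_proportions_give_p_one(self):
        assert session_failure_test((0, 20), (0, 20)) == 1.0

    @pytest.mark.parametrize("before,during", [
        ((1, 9), (9, 1)),
        ((0, 20), (18, 2)),
        ((5, 5), (5, 5)),
        ((3, 12), (10, 2)),
        ((0, 30), (30, 0)),
    ])
    def test_agrees_with_enumeration_oracle(self, before, during):
        assert session_failure_test(before, during) == pytest.approx(
            fisher_exact_enumeration(before, during), abs=1e-12)

    def test_extreme_table_is_highly_significant(self):
        assert session_failure_test((0, 20), (18, 2)) < 1e-7

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError):
            session_failure_test((0, 0), (5, 5))


class TestFisherCombined:
    def test_all_ones(self):
        x, p = fisher_combined([1.0, 1.0])
        assert x == 0.0 and p == 1.0

    @pytest.mark.parametrize("p_in", [0.5, 0.05, 0.001])
    def test_single_p_identity(self, p_in):
        _, p = fisher_combined([p_in])
        assert p == pytest.approx(p_in, rel=1e-9)

    def test_two_p05_closed_form(self):
        x, p = fisher_combined([0.05, 0.05])
        assert x == pytest.approx(-4 * math.log(0.05), rel=1e-9)
        assert x == pytest.approx(11.983, abs=5e-3)
        # chi2 with 4 df upper tail has closed form exp(-x/2) (1 + x/2)
        assert p == pytest.approx(math.exp(-x / 2) * (1 + x / 2), rel=1e-9)
        assert p == pytest.approx(0.0175, abs=5e-4)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [-0.1], [1.1]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_combined(bad)


class TestOverlapRegression:
    def test_perfect_line(self):
        conds = [(x, 100.0 * x, 10) for x in (0.1, 0.3, 0.5, 0.8, 1.0)]
        res = overlap_regression(conds, n_boot=200)
        assert res["slope"] == pytest.approx(100.0, rel=1e-9)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert res["spearman_r"] == pytest.approx(1.0, abs=1e-9)

    def test_weight_equivalence(self):
        base = [(0.1, 20.0, 5), (0.5, 60.0, 5), (0.9, 80.0, 5)]
        doubled = base + [(0.5, 60.0, 5)]
        reweighted = [(0.1, 20.0, 5), (0.5, 60.0, 10), (0.9, 80.0, 5)]
        a = overlap_regression(doubled, n_boot=10)
        b = overlap_regression(reweighted, n_boot=10)
        assert a["slope"] == pytest.approx(b["slope"], rel=1e-12)
        assert a["intercept"] == pytest.approx(b["intercept"], rel=1e-12)

    def test_identical_overlaps_rejected(self):
        with pytest.raises(ValueError):
            overlap_regression([(0.5, 10, 4), (0.5, 20, 4), (0.5, 30, 4)],
                               n_boot=10)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            overlap_regression([(0.1, 10, 4), (0.5, 50, 4)], n_boot=10)

    def test_bootstrap_ci_brackets_slope(self):
        rng = np.random.default_rng(0)
        conds = [(x, 90 * x + rng.normal(0, 5), 8)
                 for x in np.linspace(0.05, 1.0, 12)]
        res = overlap_regression(conds, n_boot=2000, seed=1)
        lo, hi = res["slope_ci"]
        assert lo < res["slope"] < hi
        assert lo < 90 < hi + 30      # truth near the interval
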