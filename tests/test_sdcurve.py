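"""Thresholds, strength-duration fits, charge metrics, group statistics."""

import math

import numpy as np
import pytest
from scipy.stats import f_oneway

from rgcestim.estim import ResponseCurve
from rgcestim.sdcurve import (
    charge_density,
    charge_per_phase,
    electrode_area_cm2,
    fit_sd,
    format_fraction,
    group_summary,
    threshold_from_curve,
    weiss_linearization,
)
from rgcestim.synthetic import SyntheticCellModel, evoked_mean


def curve(x, y, mode="PAM", fixed=1.0):
    x = np.asarray(x, float)
    return ResponseCurve("c", mode, fixed, x, np.asarray(y, float), np.zeros_like(x))


class TestThresholdFromCurve:
    def test_linear_interpolation(self):
        est = threshold_from_curve(curve([10.0, 15.0], [1.0, 2.0]))
        assert est.method == "interpolated"
        assert est.threshold_value == pytest.approx(12.5)

    def test_extrapolation_through_first_two_points(self):
        est = threshold_from_curve(curve([10.0, 15.0], [2.0, 2.5]))
        assert est.method == "extrapolated"
        assert est.threshold_value == pytest.approx(5.0)

    def test_extrapolation_floored(self):
        est = threshold_from_curve(curve([10.0, 15.0], [50.0, 50.5]))
        assert est.threshold_value == pytest.approx(1.0)  # 0.1 x smallest tested

    def test_censored_when_never_reached(self):
        est = threshold_from_curve(curve([10.0, 15.0, 20.0], [1.0, 1.1, 1.2]))
        assert est.method == "censored" and math.isnan(est.threshold_value)

    def test_interpolated_between_grid_points(self):
        est = threshold_from_curve(curve([10.0, 15.0, 20.0], [1.0, 1.2, 3.0]))
        assert 15.0 <= est.threshold_value <= 20.0

    def test_infinite_values_capped(self):
        est = threshold_from_curve(curve([10.0, 15.0], [1.0, np.inf]))
        assert np.isfinite(est.threshold_value)

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_grid_oracle_within_one_cell(self, seed):
        """Coarse-grid interpolation lands within one grid cell of the true
        crossing computed on a dense amplitude grid."""
        rng = np.random.default_rng(seed)
        m = SyntheticCellModel(
            "c",
            1,
            spont_rate=float(rng.uniform(5, 30)),
            rheobase_uA=float(rng.uniform(4, 8)),
            chronaxie_ms=float(rng.uniform(0.8, 2.0)),
            evoked_max=float(rng.uniform(8, 15)),
        )
        d = 1.0
        w = 0.09

        def rel(amp):
            return 1.0 + evoked_mean(m, amp, d) / (w * m.spont_rate)

        coarse_x = np.array([10.0, 15.0, 20.0, 25.0, 30.0])
        est = threshold_from_curve(curve(coarse_x, [rel(a) for a in coarse_x]))
        dense_x = np.linspace(0.5, 30.0, 20000)
        dense_y = np.array([rel(a) for a in dense_x])
        above = np.flatnonzero(dense_y >= 1.5)
        true_threshold = dense_x[above[0]]
        if est.method == "censored":
            assert above.size == 0 or true_threshold > coarse_x[-1] - 5.0
        else:
            assert abs(est.threshold_value - true_threshold) <= 5.0


class TestFitSD:
    def test_noiseless_exact_recovery(self):
        D = np.array([0.5, 1.0, 2.0])
        I = 3.0 * (1 + 4.0 / D)
        f = fit_sd(D, I)
        assert f.rheobase_uA == pytest.approx(3.0, abs=1e-6)
        assert f.chronaxie_ms == pytest.approx(4.0, abs=1e-6)
        assert f.rss == pytest.approx(0.0, abs=1e-9)

    def test_two_points_exact_solve(self):
        D = np.array([0.5, 2.0])
        I = 5.0 * (1 + 1.5 / D)
        f = fit_sd(D, I)
        assert f.rss == pytest.approx(0.0, abs=1e-9)
        assert f.rheobase_uA == pytest.approx(5.0, abs=1e-6)

    def test_multiplicative_noise_simulation(self):
        """5% multiplicative noise, durations spanning the chronaxie:
        median relative rheobase error stays below 10%."""
        rng = np.random.default_rng(0)
        D = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        R, C = 3.0, 4.0
        errs = []
        for _ in range(200):
            I = R * (1 + C / D) * (1 + 0.05 * rng.standard_normal(D.size))
            errs.append(abs(fit_sd(D, I).rheobase_uA - R) / R)
        assert np.median(errs) < 0.1

    def test_weiss_linearization_exact_on_law(self):
        D = np.array([0.5, 1.0, 2.0, 4.0])
        I = 2.5 * (1 + 3.0 / D)
        r, c = weiss_linearization(D, I)
        assert r == pytest.approx(2.5) and c == pytest.approx(3.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sd([1.0], [5.0])
        with pytest.raises(ValueError):
            fit_sd([1.0, 1.0], [5.0, 6.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_equivalence(self, seed):
        """The optimizer matches a dense-grid minimizer of the same
        (relative-residual) objective within 1% of parameter values."""
        rng = np.random.default_rng(seed)
        R = float(rng.uniform(2, 8))
        C = float(rng.uniform(0.5, 5))
        D = np.array([0.5, 1.0, 2.0, 4.0])
        I = R * (1 + C / D) * (1 + 0.05 * rng.standard_normal(D.size))
        f = fit_sd(D, I)

        def sse(r, c):
            return np.sum(((r * (1 + c / D) - I) / I) ** 2)

        # two-stage zoomed grid search
        r_grid = np.linspace(0.5 * R, 2.0 * R, 201)
        c_grid = np.linspace(0.3 * C, 3.0 * C, 201)
        vals = np.array([[sse(r, c) for c in c_grid] for r in r_grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        r0, c0 = r_grid[i], c_grid[j]
        r_grid = np.linspace(r0 * 0.97, r0 * 1.03, 121)
        c_grid = np.linspace(c0 * 0.97, c0 * 1.03, 121)
        vals = np.array([[sse(r, c) for c in c_grid] for r in r_grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert f.rheobase_uA == pytest.approx(r_grid[i], rel=0.01)
        assert f.chronaxie_ms == pytest.approx(c_grid[j], rel=0.01)


class TestChargeMetrics:
    def test_discussion_worked_example(self):
        assert charge_per_phase(8.0, 0.5) == pytest.approx(4.0)

    def test_unit_identity(self):
        assert charge_per_phase(1.0, 1.0) == pytest.approx(1.0)

    def test_table_input_arithmetic(self):
        assert charge_per_phase(7.93, 0.5) == pytest.approx(3.965)

    def test_electrode_area(self):
        assert electrode_area_cm2(30.0) == pytest.approx(7.0686e-6, rel=1e-4)

    def test_density_of_4nC_disc(self):
        assert charge_density(4.0, 30.0) == pytest.approx(0.566, abs=5e-4)

    def test_density_of_table_threshold(self):
        assert round(charge_density(charge_per_phase(7.93, 0.5)), 2) == 0.56

    def test_zero_charge(self):
        assert charge_density(0.0, 30.0) == 0.0

    def test_linearity_in_amplitude_and_duration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, d, k = rng.uniform(0.5, 30, 3)
            assert charge_density(charge_per_phase(k * i, d)) == pytest.approx(
                k * charge_density(charge_per_phase(i, d))
            )
            assert charge_density(charge_per_phase(i, k * d)) == pytest.approx(
                k * charge_density(charge_per_phase(i, d))
            )


class TestGroupSummary:
    def test_identical_groups_not_significant(self):
        v = np.arange(10.0)
        out = group_summary({"a": v, "b": v.copy()})
        assert out["anova_p"] > 0.99
        assert out["significance"] == "n.s."

    def test_power_of_large_separation(self):
        """N(0,1) vs N(3,1), n=30: p < 0.001 in at least 99% of 200 runs."""
        rng = np.random.default_rng(4)
        hits = sum(
            f_oneway(rng.normal(0, 1, 30), rng.normal(3, 1, 30)).pvalue < 0.001
            for _ in range(200)
        )
        assert hits / 200 >= 0.99

    def test_rheobase_scale_groups_mostly_not_significant(self):
        """Three groups at the reported rheobase means with matching-scale
        spreads: the one-way ANOVA is non-significant in the majority of
        seeded runs."""
        rng = np.random.default_rng(5)
        ns = 0
        for _ in range(100):
            groups = {
                "normal": rng.normal(3.37, 0.36 * np.sqrt(75), 75),
                "non_severe": rng.normal(3.94, 0.40 * np.sqrt(58), 58),
                "severe": rng.normal(4.80, 1.05 * np.sqrt(12), 12),
            }
            ns += int(group_summary(groups)["anova_p"] > 0.05)
        assert ns > 50

    def test_small_group_excluded(self):
        out = group_summary(
            {"a": np.arange(5.0), "b": np.arange(5.0) + 1, "tiny": np.array([1.0])}
        )
        assert set(out["summary"]["group"]) == {"a", "b"}

    def test_tukey_pairs_present(self):
        rng = np.random.default_rng(6)
        out = group_summary(
            {g: rng.normal(i, 1, 20) for i, g in enumerate("abc")}
        )
        assert len(out["tukey"]) == 3


class TestReportFormatting:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (75, 432, "17.36% (75/432)"),
            (58, 315, "18.41% (58/315)"),
            (12, 174, "6.90% (12/174)"),
            (0, 10, "0.00% (0/10)"),
        ],
    )
    def test_fraction_format(self, k, n, expected):
        assert format_fraction(k, n) == expected
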