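"""Standard-curve fitting, efficiency, quantification and validity gates."""

import math

import numpy as np
import pytest
from scipy import stats

from dsbquant import (
    CtMeasurement,
    StandardCurve,
    StandardPoint,
    amplification_efficiency,
    fit_standard_curve,
    quantify_ct,
    validate_curve,
)
from dsbquant.calibration import read_ct_table
from dsbquant.reference_data import ORGANISMS, reference_standards


def colinear_points(a=40.0, b=3.5, decades=(4, 5, 6, 7)):
    return [
        StandardPoint(f"e{d}", 10.0**d, a - b * d) for d in decades
    ]


class TestFit:
    def test_exact_line_recovered(self):
        curve = fit_standard_curve(colinear_points())
        assert curve.slope_b == pytest.approx(-3.5)
        assert curve.intercept_a == pytest.approx(40.0)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.n_points == 4

    def test_yeast_reference_standards(self):
        """The seven yeast standards reproduce the published fit."""
        curve = fit_standard_curve(reference_standards("yeast"), "yeast")
        assert abs(curve.slope_b) == pytest.approx(3.180, abs=5e-4)
        assert curve.r_squared == pytest.approx(0.996, abs=5e-4)

    def test_human_reference_standards_linear(self):
        curve = fit_standard_curve(reference_standards("human"), "human")
        assert curve.n_points == 6  # EheI excluded
        assert curve.r_squared >= 0.95

    def test_excluded_points_ignored(self):
        pts = colinear_points() + [StandardPoint("bad", 1e3, 99.0, included=False)]
        curve = fit_standard_curve(pts)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.n_points == 4

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_standard_curve(colinear_points(decades=(4, 5)))

    def test_degenerate_design_errors(self):
        pts = [StandardPoint(f"e{i}", 1e5, 20.0 + i) for i in range(4)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_standard_curve(pts)

    def test_nonpositive_n_errors(self):
        pts = colinear_points()[:2] + [StandardPoint("z", 0.0, 30.0)]
        with pytest.raises(ValueError, match="positive"):
            fit_standard_curve(pts)

    def test_scale_equivariance(self):
        """Scaling all break numbers by k shifts only the intercept."""
        rng = np.random.default_rng(5)
        pts = [
            StandardPoint(f"e{i}", 10.0**d, 40 - 3.5 * d + rng.normal(0, 0.1))
            for i, d in enumerate(range(2, 9))
        ]
        base = fit_standard_curve(pts)
        k = 37.0
        scaled = fit_standard_curve(
            [StandardPoint(p.enzyme, p.n_dsbs * k, p.ct) for p in pts]
        )
        assert scaled.slope_b == pytest.approx(base.slope_b, rel=1e-10)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-10)
        assert scaled.intercept_a == pytest.approx(
            base.intercept_a - base.slope_b * math.log10(k), rel=1e-10
        )


class TestEfficiency:
    @pytest.mark.parametrize(
        "slope,expected",
        [(3.65, 87.9), (3.0, 115.4), (-3.65, 87.9)],
    )
    def test_published_range_endpoints(self, slope, expected):
        assert round(amplification_efficiency(slope), 1) == expected

    def test_perfect_doubling_at_lg2_slope(self):
        assert amplification_efficiency(1 / math.log10(2)) == pytest.approx(100.0)

    def test_zero_slope_errors(self):
        with pytest.raises(ValueError):
            amplification_efficiency(0.0)

    def test_strictly_decreasing_in_slope_magnitude(self):
        slopes = np.linspace(2.5, 4.5, 30)
        effs = [amplification_efficiency(s) for s in slopes]
        assert all(a > b for a, b in zip(effs, effs[1:]))


class TestQuantify:
    human_curve = StandardCurve(
        organism="human",
        intercept_a=39.846,
        slope_b=-3.586,
        r_squared=0.983,
        efficiency_percent=amplification_efficiency(3.586),
        n_points=6,
    )

    def _measure(self, ct, sample="s"):
        return [CtMeasurement(sample, 1, ct)]

    def test_ct_at_intercept_gives_one_break(self):
        res = quantify_ct(self.human_curve, self._measure(39.846))
        assert res.n_dsbs_estimate == pytest.approx(1.0)
        assert not res.within_range

    def test_exact_decade(self):
        res = quantify_ct(self.human_curve, self._measure(39.846 - 3.586 * 7))
        assert res.n_dsbs_estimate == pytest.approx(1e7, rel=1e-10)
        assert res.within_range

    def test_replicates_averaged(self):
        ms = [CtMeasurement("s", i, ct) for i, ct in enumerate([20.0, 21.0, 22.0])]
        res = quantify_ct(self.human_curve, ms)
        assert res.ct_mean == pytest.approx(21.0)

    def test_none_replicates_dropped_with_warning(self):
        ms = [CtMeasurement("s", 1, 20.0), CtMeasurement("s", 2, None)]
        with pytest.warns(UserWarning, match="non-amplifying"):
            res = quantify_ct(self.human_curve, ms)
        assert res.ct_mean == pytest.approx(20.0)

    def test_all_none_flagged_below_detection(self):
        ms = [CtMeasurement("s", 1, None), CtMeasurement("s", 2, None)]
        res = quantify_ct(self.human_curve, ms)
        assert res.n_dsbs_estimate is None
        assert "below detection" in res.note

    def test_round_trip_inversion_on_colinear_standards(self):
        pts = colinear_points(a=38.2, b=3.3, decades=(2, 3, 4, 5, 6, 7, 8))
        curve = fit_standard_curve(pts)
        for p in pts:
            res = quantify_ct(curve, self._measure(p.ct))
            assert res.n_dsbs_estimate == pytest.approx(p.n_dsbs, rel=1e-10)


class TestValidate:
    def _curve(self, r2=0.983, slope=-3.586):
        return StandardCurve("human", 39.846, slope, r2,
                             amplification_efficiency(slope), 6)

    def test_published_human_values_pass(self):
        controls = [
            CtMeasurement("ntc", 1, 35.1),
            CtMeasurement("no-ligase", 1, None),
        ]
        report = validate_curve(self._curve(), controls)
        assert report.passed

    def test_amplifying_control_fails(self):
        report = validate_curve(
            self._curve(), [CtMeasurement("ntc", 1, 30.0)]
        )
        assert not report.passed
        assert any("negative control amplified" in r for r in report.reasons)

    def test_slope_out_of_range_fails(self):
        report = validate_curve(self._curve(slope=-2.5))
        assert not report.passed
        assert any("slope out of range" in r for r in report.reasons)

    def test_low_r_squared_fails(self):
        assert not validate_curve(self._curve(r2=0.90)).passed


class TestReferenceRegressions:
    @pytest.mark.parametrize("organism", ORGANISMS)
    def test_matches_independent_ols(self, organism):
        """Package fit agrees with a direct scipy regression on the data."""
        pts = [p for p in reference_standards(organism) if p.included]
        res = stats.linregress(
            np.log10([p.n_dsbs for p in pts]), [p.ct for p in pts]
        )
        curve = fit_standard_curve(reference_standards(organism), organism)
        assert curve.slope_b == pytest.approx(res.slope, rel=1e-12)
        assert curve.r_squared == pytest.approx(res.rvalue**2, rel=1e-12)

    def test_mammals_drop_methylation_sensitive_standard(self):
        for org in ("human", "mouse"):
            pts = reference_standards(org)
            assert [p.enzyme for p in pts if not p.included] == ["EheI"]
        for org in ("arabidopsis", "yeast", "ecoli"):
            assert all(p.included for p in reference_standards(org))


class TestParameterRecovery:
    def test_noisy_simulation_recovers_slope_and_intercept(self):
        """Gaussian Ct noise (sd 0.2) over 7 decades: the fitted slope
        mean is within 0.01 of truth, and (a, b) jointly fall within 3
        standard errors of truth in at least 95% of 1000 seeded
        replicates (with 5 residual degrees of freedom the error ratios
        are t-distributed, so 3 SE covers ~97% per parameter, not the
        Gaussian 99.7%)."""
        true_a, true_b = 38.0, -3.4
        decades = np.arange(2, 9)
        lg = decades.astype(float)
        slopes = []
        covered = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            ct = true_a + true_b * lg + rng.normal(0, 0.2, size=lg.size)
            res = stats.linregress(lg, ct)
            slopes.append(res.slope)
            if (
                abs(res.slope - true_b) <= 3 * res.stderr
                and abs(res.intercept - true_a) <= 3 * res.intercept_stderr
            ):
                covered += 1
        assert abs(np.mean(slopes) - true_b) < 0.01
        assert covered / n_rep >= 0.95


class TestCtTableIO:
    def test_none_sentinel_maps_to_nan(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text(
            "sample,enzyme_or_condition,replicate,ct\n"
            "s1,AluI,1,12.3\ns1,AluI,2,none\n"
        )
        df = read_ct_table(p)
        assert df["ct"].iloc[0] == pytest.approx(12.3)
        assert math.isnan(df["ct"].iloc[1])

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample,ct\ns1,12.3\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_ct_table(p)
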