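"""Lethal-time addition, hyperbolic mortality and the predicted mixture LC50."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lethaltime import (
    DataValidationError,
    DomainError,
    HyperbolicParams,
    component_concentrations,
    hm_lc50_by_inversion,
    hm_predicted_lc50,
    hyperbolic_mortality,
    lethal_time_addition,
    make_mixture,
    predict_mixture_lt50_curve,
)
from lethaltime import datasets as ds
from lethaltime.pipeline import reproduce_report


class TestComponentConcentrations:
    def test_binary_split_33_95_to_1(self, atz_chl_catfish):
        got = component_concentrations(atz_chl_catfish, 8.0)
        assert got == pytest.approx((8 * 33.95 / 34.95, 8 / 34.95), rel=1e-12)
        assert got == pytest.approx((7.7711, 0.2289), abs=5e-5)

    def test_single_component_identity(self):
        spec = make_mixture("solo", [("x", 7.0)])
        assert component_concentrations(spec, 5.0) == pytest.approx((5.0,))

    def test_quaternary_split_direct_arithmetic(self):
        spec = make_mixture(
            "quat",
            [("a", 1.299), ("m", 0.360), ("c", 0.0132), ("l", 0.001)],
        )
        got = component_concentrations(spec, 8.0)
        s = 1.299 + 0.360 + 0.0132 + 0.001
        expect = (8 * 1.299 / s, 8 * 0.360 / s, 8 * 0.0132 / s, 8 * 0.001 / s)
        assert got == pytest.approx(expect, rel=1e-12)
        assert sum(got) == pytest.approx(8.0, abs=1e-12)

    def test_nonpositive_total_rejected(self, atz_chl_catfish):
        with pytest.raises(DomainError):
            component_concentrations(atz_chl_catfish, 0.0)

    def test_unit_scale_converts_to_mg_per_L(self, catfish_coeffs):
        # a component quoted in ug/L (unit_scale 1e-3) is converted to mg/L
        # before the log-log law and the reciprocal sum are applied
        from lethaltime import Component, MixtureSpec, predict_lt50

        spec = MixtureSpec((Component("chlorpyrifos", 1.0, unit_scale=1e-3),))
        (pred,) = predict_mixture_lt50_curve(
            spec, catfish_coeffs, [500.0], times=()
        )  # 500 ug/L = 0.5 mg/L
        lt = predict_lt50(catfish_coeffs["chlorpyrifos"], 0.5)
        assert pred.component_concentrations == pytest.approx((0.5,))
        assert pred.lt50_mix == pytest.approx(1.0 / (0.5 / lt), rel=1e-12)


class TestLethalTimeAddition:
    @pytest.mark.parametrize(
        "pairs,expected,rtol",
        [
            ([(3.88555, 13034.0), (0.114449, 7069.0)], 3181.6, 1e-3),
            ([(7.7711, 1271.2), (0.22890, 842.3)], 156.62, 1e-3),
            ([(1.0, 100.0)], 100.0, 1e-12),
        ],
    )
    def test_worked_values(self, pairs, expected, rtol):
        assert lethal_time_addition(pairs) == pytest.approx(expected, rel=rtol)

    def test_errors(self):
        with pytest.raises(DomainError):
            lethal_time_addition([])
        with pytest.raises(DomainError):
            lethal_time_addition([(1.0, 0.0)])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(
                st.floats(min_value=1e-3, max_value=1e3),
                st.floats(min_value=1e-2, max_value=1e5),
            ),
            min_size=1,
            max_size=6,
        ),
        extra=st.tuples(
            st.floats(min_value=1e-3, max_value=1e3),
            st.floats(min_value=1e-2, max_value=1e5),
        ),
    )
    def test_bounds_monotonicity_permutation(self, pairs, extra):
        lt = lethal_time_addition(pairs)
        assert lt <= min(t / c for c, t in pairs) * (1 + 1e-9)
        assert lethal_time_addition(list(reversed(pairs))) == pytest.approx(
            lt, rel=1e-12
        )
        assert lethal_time_addition(pairs + [extra]) < lt


class TestHyperbolicMortality:
    @pytest.mark.parametrize(
        "lt50,t,expected",
        [(156.62, 96.0, 38), (340.30, 96.0, 22)],
    )
    def test_worked_cells_round_to_published_integers(self, lt50, t, expected):
        p = hyperbolic_mortality(HyperbolicParams(lt50), t)
        assert round(p) == expected

    def test_median_time_gives_exactly_half(self):
        params = HyperbolicParams(lt50=37.5)
        assert hyperbolic_mortality(params, 37.5) == pytest.approx(50.0, abs=1e-12)

    def test_shape_properties(self):
        params = HyperbolicParams(lt50=10.0, p100=80.0)
        assert hyperbolic_mortality(params, 0.0) == 0.0
        ts = np.linspace(0.5, 500, 100)
        ps = [hyperbolic_mortality(params, t) for t in ts]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 80.0
        assert hyperbolic_mortality(params, 1e9) == pytest.approx(80.0, abs=1e-4)
        assert hyperbolic_mortality(params, 10.0) == pytest.approx(40.0, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            hyperbolic_mortality(HyperbolicParams(10.0), -1.0)


class TestPredictMixtureCurve:
    def test_catfish_atz_chl_lt50_sequence(self, atz_chl_catfish, catfish_coeffs):
        preds = predict_mixture_lt50_curve(
            atz_chl_catfish, catfish_coeffs, [4, 8, 12, 16, 20]
        )
        got = [p.lt50_mix for p in preds]
        assert got == pytest.approx([3181.6, 156.62, 26.88, 7.70, 2.92], rel=5e-3)

    def test_tilapia_atz_chl_total_3(self, tilapia_coeffs):
        spec = ds.mixture_spec(ds.TILAPIA, ds.AC)
        (pred,) = predict_mixture_lt50_curve(spec, tilapia_coeffs, [3.0])
        assert pred.lt50_mix == pytest.approx(340.30, rel=5e-3)
        ints = [round(p) for _, p in pred.mortality_curve]
        assert ints == [7, 12, 17, 22]

    def test_lt50_strictly_decreasing_in_total(self, atz_chl_catfish, catfish_coeffs):
        preds = predict_mixture_lt50_curve(
            atz_chl_catfish, catfish_coeffs, [2.0, 5.0, 9.0, 14.0]
        )
        lts = [p.lt50_mix for p in preds]
        assert all(b < a for a, b in zip(lts, lts[1:]))

    def test_missing_coefficients_rejected(self, atz_chl_catfish):
        with pytest.raises(DataValidationError, match="chlorpyrifos"):
            predict_mixture_lt50_curve(
                atz_chl_catfish,
                {"atrazine": ds.REGRESSION[(ds.CATFISH, ds.ATRAZINE)]},
                [4.0],
            )

    def test_reproduction_suite_published_cells_within_half_percent(self):
        """Every internally consistent published mixture-LT50 cell is
        regenerated within 0.5% from the published coefficients and the
        exact mixing ratios."""
        df = reproduce_report(rel_tol=0.005)
        consistent = df[df["consistent_cell"]]
        assert len(consistent) >= 50
        assert consistent["ok"].all(), consistent[~consistent["ok"]]


class TestHmPredictedLc50:
    def test_probit_route_near_published_value(
        self, atz_chl_catfish, catfish_coeffs
    ):
        preds = predict_mixture_lt50_curve(
            atz_chl_catfish, catfish_coeffs, [4, 8, 12, 16, 20]
        )
        lvl = hm_predicted_lc50(preds, t=96.0)
        assert lvl.estimate == pytest.approx(8.5, rel=0.10)

    def test_probit_and_inversion_agree(self, atz_chl_catfish, catfish_coeffs):
        totals = [4, 8, 12, 16, 20]
        preds = predict_mixture_lt50_curve(atz_chl_catfish, catfish_coeffs, totals)
        by_probit = hm_predicted_lc50(preds, t=96.0).estimate
        by_inv = hm_lc50_by_inversion(
            atz_chl_catfish, catfish_coeffs, t=96.0, totals_hint=totals
        )
        assert abs(by_probit - by_inv) / by_inv < 0.15

    def test_symmetric_series_inverts_exactly(self):
        # craft a mixture whose LT50_mix(C*) = 96 at a sampled total and whose
        # mortalities are log-symmetric around it: single component, b = -2
        spec = make_mixture("solo", [("x", 1.0)])
        a = float(np.log(96.0))  # LT50_mix(1 mg/L) = 96 h exactly
        coeffs = {"x": __import__("lethaltime").LtcRegression(a, -2.0, 1.0, 2)}
        totals = [1 / 4, 1 / 2, 1.0, 2.0, 4.0]
        preds = predict_mixture_lt50_curve(spec, coeffs, totals)
        by_probit = hm_predicted_lc50(preds, t=96.0).estimate
        by_inv = hm_lc50_by_inversion(spec, coeffs, t=96.0, totals_hint=totals)
        assert by_inv == pytest.approx(1.0, rel=1e-9)
        # probit route sees non-normal but log-symmetric responses around C*=1
        assert by_probit == pytest.approx(1.0, rel=0.02)

    def test_requires_two_interior_mortalities(self, atz_chl_catfish, catfish_coeffs):
        # at t = 0 every predicted mortality is exactly 0: nothing to fit
        preds = predict_mixture_lt50_curve(
            atz_chl_catfish, catfish_coeffs, [4.0, 8.0], times=(0.0, 96.0)
        )
        with pytest.raises(DataValidationError):
            hm_predicted_lc50(preds, t=0.0)

    def test_inversion_needs_bracketing(self, atz_chl_catfish, catfish_coeffs):
        with pytest.raises(DomainError):
            hm_lc50_by_inversion(
                atz_chl_catfish, catfish_coeffs, t=96.0, c_bracket=(0.001, 0.002)
            )
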