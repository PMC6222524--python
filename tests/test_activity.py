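import math

import numpy as np
import pytest
from sklearn.base import clone

from sletherm import (
    BinaryParams,
    FusionProperties,
    GAS_CONSTANT,
    SleActivityModel,
    ValidationError,
    activity_model_fit,
    ard_percent,
    ideal_solubility,
    nrtl_gamma,
    nrtl_gamma_solvent,
    sle_solve,
    wilson_gamma,
    wilson_gamma_solvent,
    wilson_lambda,
)
from sletherm.activity import _solve_lnx

FUSION = FusionProperties(t_melt=410.15, dh_fus=121300.0)
IDENTITY_WILSON = BinaryParams("wilson", 0.0, 0.0, 0.0, 0.0)
IDENTITY_NRTL = BinaryParams("nrtl", 0.0, 0.0, 0.0, 0.0)


class TestIdealSolubility:
    def test_unity_at_melting_point(self):
        assert ideal_solubility(FUSION, 410.15) == pytest.approx(1.0, abs=1e-14)

    def test_single_line_arithmetic_oracle(self):
        expected = math.exp((121300.0 / GAS_CONSTANT) * (1.0 / 410.15 - 1.0 / 298.2))
        assert ideal_solubility(FUSION, 298.2) == pytest.approx(expected, rel=1e-14)

    def test_strictly_increasing_below_melting(self):
        temps = np.linspace(250.0, 409.0, 40)
        x = ideal_solubility(FUSION, temps)
        assert np.all(np.diff(x) > 0)

    def test_capped_at_one_above_melting(self):
        assert ideal_solubility(FUSION, 450.0) == 1.0


class TestWilsonGamma:
    def test_lambda_identity_and_arithmetic(self):
        assert wilson_lambda(IDENTITY_WILSON, 300.0) == (1.0, 1.0)
        p = BinaryParams("wilson", -17.95, 8001.6, -35.33, 9900.8)
        l12, l21 = wilson_lambda(p, 298.2)
        assert l12 == pytest.approx(math.exp(-17.95 + 8001.6 / 298.2), rel=1e-14)
        assert l21 == pytest.approx(math.exp(-35.33 + 9900.8 / 298.2), rel=1e-14)

    @pytest.mark.parametrize("x1", [0.0, 0.1, 0.5, 0.9])
    def test_identity_parameters_give_ideal_solution(self, x1):
        assert wilson_gamma(x1, 300.0, IDENTITY_WILSON) == pytest.approx(1.0, abs=1e-14)

    def test_closed_form_hand_value(self):
        # Lambda12 = 0.5, Lambda21 = 2.0 at x1 = 0.1:
        # ln g1 = -ln(0.55) + 0.9*(0.5/0.55 - 2.0/1.1)
        p = BinaryParams("wilson", math.log(0.5), 0.0, math.log(2.0), 0.0)
        expected = -math.log(0.55) + 0.9 * (0.5 / 0.55 - 2.0 / 1.1)
        assert math.log(wilson_gamma(0.1, 300.0, p)) == pytest.approx(expected, rel=1e-12)
        assert wilson_gamma(0.1, 300.0, p) == pytest.approx(0.802, abs=5e-4)

    def test_infinite_dilution_limit(self):
        p = BinaryParams("wilson", math.log(0.7), 0.0, math.log(1.4), 0.0)
        expected = 1.0 - math.log(0.7) - 1.4
        assert math.log(wilson_gamma(0.0, 300.0, p)) == pytest.approx(expected, rel=1e-12)

    def test_model_tag_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            wilson_gamma(0.1, 300.0, IDENTITY_NRTL)


class TestNrtlGamma:
    @pytest.mark.parametrize("x1", [0.0, 0.25, 0.75])
    def test_zero_tau_gives_ideal_solution(self, x1):
        assert nrtl_gamma(x1, 300.0, IDENTITY_NRTL) == pytest.approx(1.0, abs=1e-14)

    def test_closed_form_hand_value(self):
        # tau12 = tau21 = 1, sigma = 0.3, x1 = 0.5
        p = BinaryParams("nrtl", 1.0, 0.0, 1.0, 0.0, sigma=0.3)
        g = math.exp(-0.3)
        expected = 0.25 * ((g / (0.5 + 0.5 * g)) ** 2 + g / (0.5 + 0.5 * g) ** 2)
        assert math.log(nrtl_gamma(0.5, 300.0, p)) == pytest.approx(expected, rel=1e-12)
        assert nrtl_gamma(0.5, 300.0, p) == pytest.approx(1.530, abs=2e-3)

    def test_infinite_dilution_limit(self):
        p = BinaryParams("nrtl", 0.8, 0.0, 1.7, 0.0, sigma=0.3)
        expected = 1.7 + 0.8 * math.exp(-0.3 * 0.8)
        assert math.log(nrtl_gamma(0.0, 300.0, p)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "params,g1,g2",
    [
        (BinaryParams("wilson", -0.4, 150.0, 0.3, -80.0), wilson_gamma, wilson_gamma_solvent),
        (BinaryParams("nrtl", 0.6, -250.0, 1.2, 90.0), nrtl_gamma, nrtl_gamma_solvent),
    ],
    ids=["wilson", "nrtl"],
)
def test_gibbs_duhem_consistency(params, g1, g2):
    """x1 dlng1/dx1 + x2 dlng2/dx1 must vanish for a thermodynamically
    consistent binary model (finite differences at probe compositions)."""
    t = 303.0
    h = 1e-6
    for x1 in (0.1, 0.3, 0.5, 0.7, 0.9):
        d1 = (math.log(g1(x1 + h, t, params)) - math.log(g1(x1 - h, t, params))) / (2 * h)
        d2 = (math.log(g2(x1 + h, t, params)) - math.log(g2(x1 - h, t, params))) / (2 * h)
        assert abs(x1 * d1 + (1.0 - x1) * d2) < 1e-6


class TestSleSolve:
    @pytest.mark.parametrize("params", [IDENTITY_WILSON, IDENTITY_NRTL], ids=["wilson", "nrtl"])
    def test_identity_parameters_reduce_to_ideal_solubility(self, params):
        for t in (288.2, 298.2, 318.2):
            pred = sle_solve(params, FUSION, t)
            assert pred.converged
            assert pred.gamma == pytest.approx(1.0, abs=1e-12)
            assert pred.x_calc == pytest.approx(ideal_solubility(FUSION, t), rel=1e-10)

    def test_residual_contract(self):
        p = BinaryParams("wilson", -17.95, 8001.6, -35.33, 9900.8)
        for t in (288.2, 303.2, 318.2):
            pred = sle_solve(p, FUSION, t)
            assert pred.converged
            rhs = (FUSION.dh_fus / GAS_CONSTANT) * (1.0 / FUSION.t_melt - 1.0 / t)
            residual = math.log(pred.x_calc * pred.gamma) - rhs
            assert abs(residual) < 1e-10
            assert pred.iterations >= 1

    def test_temperature_domain(self):
        with pytest.raises(ValidationError, match="melting"):
            sle_solve(IDENTITY_WILSON, FUSION, 420.0)
        with pytest.raises(ValidationError):
            sle_solve(IDENTITY_WILSON, FUSION, -1.0)

    def test_unbracketable_equation_reports_nonconvergence(self):
        # a gamma large enough that ln x + ln gamma - rhs has no sign change
        lnx, _, ok = _solve_lnx(lambda x1, t: 1000.0, rhs=-13.0, t=298.2)
        assert not ok
        assert math.isnan(lnx)

    def test_grid_oracle_locates_the_same_root(self):
        """Dense scan over ln x agrees with the bracketed solver, using an
        independent vectorised evaluation of both gamma models."""
        rng = np.random.default_rng(7)
        grid = np.linspace(-25.0, -1e-9, 200_001)
        x1 = np.exp(grid)
        for _ in range(10):
            t = float(rng.uniform(285.0, 320.0))
            rhs = (FUSION.dh_fus / GAS_CONSTANT) * (1.0 / FUSION.t_melt - 1.0 / t)
            a12, a21 = rng.uniform(-3, 3, 2)
            b12, b21 = rng.uniform(-800, 800, 2)
            x2 = 1.0 - x1

            l12, l21 = np.exp(a12 + b12 / t), np.exp(a21 + b21 / t)
            lng_w = -np.log(x1 + l12 * x2) + x2 * (
                l12 / (x1 + l12 * x2) - l21 / (x2 + l21 * x1)
            )
            t12, t21 = a12 + b12 / t, a21 + b21 / t
            g12, g21 = np.exp(-0.3 * t12), np.exp(-0.3 * t21)
            lng_n = x2**2 * (
                t21 * (g21 / (x1 + x2 * g21)) ** 2 + t12 * g12 / (x2 + x1 * g12) ** 2
            )
            for tag, lng in (("wilson", lng_w), ("nrtl", lng_n)):
                f = grid + lng - rhs
                sign_change = np.nonzero(np.diff(np.sign(f)) != 0)[0]
                params = BinaryParams(tag, a12, b12, a21, b21)
                pred = sle_solve(params, FUSION, t)
                if sign_change.size == 0:
                    assert not pred.converged
                    continue
                assert pred.converged
                lnx_grid = grid[sign_change[0]]
                assert math.log(pred.x_calc) == pytest.approx(
                    lnx_grid, abs=2 * (grid[1] - grid[0])
                )


class TestArdPercent:
    def test_zero_for_identical_vectors(self):
        assert ard_percent([1e-3, 2e-3], [1e-3, 2e-3]) == 0.0

    def test_uniform_scaling(self):
        x = np.array([1e-4, 5e-3, 2e-2])
        assert ard_percent(1.1 * x, x) == pytest.approx(10.0, rel=1e-12)

    def test_two_term_hand_sum(self):
        assert ard_percent([1.0, 3.0], [2.0, 2.0]) == pytest.approx(50.0, rel=1e-14)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            ard_percent([1.0], [1.0, 2.0])


class TestSleActivityModelFitting:
    def test_fit_requires_fusion_and_five_points(self, datasets_by_solvent):
        with pytest.raises(ValidationError, match="fusion"):
            SleActivityModel(model="wilson").fit([288.0, 293.0, 298.0, 303.0, 308.0],
                                                 [1e-4, 2e-4, 3e-4, 4e-4, 5e-4])
        ds = datasets_by_solvent["methanol"]
        with pytest.raises(ValidationError, match="at least 5"):
            activity_model_fit(
                type(ds)(ds.solute_name, ds.solvent_name, ds.points[:4]), FUSION, "wilson"
            )

    def test_fitted_predictions_are_monotone_in_temperature(self, datasets_by_solvent):
        ds = datasets_by_solvent["methanol"]
        model = SleActivityModel(
            model="wilson", fusion=FUSION, multistart=4, random_state=0
        ).fit(ds.temperatures, ds.mole_fractions)
        assert model.result_.converged
        probe = np.linspace(288.2, 318.2, 13)
        x = model.predict(probe)
        assert np.all(np.diff(x) > 0)

    def test_fit_is_deterministic_given_seed(self, datasets_by_solvent):
        ds = datasets_by_solvent["acetone"]
        kwargs = dict(model="nrtl", fusion=FUSION, multistart=2, random_state=3,
                      grid_starts=False)
        a = SleActivityModel(**kwargs).fit(ds.temperatures, ds.mole_fractions)
        b = SleActivityModel(**kwargs).fit(ds.temperatures, ds.mole_fractions)
        assert a.params_ == b.params_
        assert a.ard_percent_ == b.ard_percent_

    def test_sklearn_protocol(self):
        model = SleActivityModel(model="nrtl", fusion=FUSION, sigma=0.25)
        params = model.get_params()
        assert params["sigma"] == 0.25 and params["model"] == "nrtl"
        assert clone(model).get_params()["fusion"] == FUSION
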