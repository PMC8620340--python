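"""Index-engine tests: hand oracles for the formulas, analytic limits, and
order/relabeling invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverwqi import (
    CcmeFactors,
    ObjectiveSpec,
    PanelError,
    bc_wqi,
    ccme_factors,
    ccme_wqi,
    excursion,
    weighted_wqi,
)
from conftest import make_slice

UPPER10 = ObjectiveSpec(parameter="X", direction="upper_limit",
                        objective_high=10.0, standard_S=10.0)
LOWER5 = ObjectiveSpec(parameter="DO", direction="lower_limit",
                       objective_low=5.0, standard_S=5.0, ideal_V0=14.6)
RANGE_PH = ObjectiveSpec(parameter="pH", direction="range", objective_low=6.5,
                         objective_high=8.5, standard_S=8.5, ideal_V0=7.0)


class TestExcursion:
    @pytest.mark.parametrize(
        "value,spec,expected",
        [
            (10.0, UPPER10, 0.0),          # boundary meets the objective
            (25.0, UPPER10, 1.5),          # 25/10 - 1
            (4.0, LOWER5, 0.25),           # 5/4 - 1 (DO convention)
            (7.0, RANGE_PH, 0.0),
            (9.35, RANGE_PH, 0.1),         # violates the upper bound
            (6.2, RANGE_PH, pytest.approx(6.5 / 6.2 - 1)),
        ],
    )
    def test_directional_rules(self, value, spec, expected):
        assert excursion(value, spec) == pytest.approx(expected)

    def test_zero_bound_capped_with_warning(self):
        spec = ObjectiveSpec(parameter="Z", direction="upper_limit",
                             objective_high=0.0, standard_S=1.0)
        with pytest.warns(UserWarning, match="capped"):
            assert excursion(0.5, spec) == 100.0

    def test_zero_value_under_lower_limit_capped(self):
        with pytest.warns(UserWarning, match="capped"):
            assert excursion(0.0, LOWER5) == 100.0

    @given(st.floats(0.01, 1000))
    def test_zero_iff_objective_met(self, value):
        exc = excursion(value, UPPER10)
        assert (exc == 0) == (value <= 10)
        assert exc >= 0


class TestCcme:
    def test_all_passing_factors_zero(self, simple_specs):
        sl = make_slice({(f"P{i}", y): 5.0 for i in range(1, 9)
                         for y in (2003, 2004)})
        f = ccme_factors(sl, simple_specs)
        assert f.F1 == f.F2 == f.F3 == 0
        assert ccme_wqi(f) == 100.0

    def test_hand_arithmetic_oracle(self, simple_specs):
        # 8 params x 2 years = 16 tests; P1 fails twice (exc 0.5, 0.4),
        # P2 once (exc 0.3): 2 failed parameters, 3 failed tests, sum 1.2.
        values = {(f"P{i}", y): 5.0 for i in range(1, 9) for y in (2003, 2004)}
        values[("P1", 2003)] = 15.0
        values[("P1", 2004)] = 14.0
        values[("P2", 2003)] = 13.0
        f = ccme_factors(make_slice(values), simple_specs)
        assert f.F1 == 25.0
        assert f.F2 == 18.75
        assert f.nse == pytest.approx(0.075)
        assert f.F3 == pytest.approx(6.9767, abs=1e-4)
        assert ccme_wqi(f) == pytest.approx(81.513, abs=1e-3)

    def test_all_fail_unit_excursions(self, simple_specs):
        sl = make_slice({(f"P{i}", y): 20.0 for i in range(1, 9)
                         for y in (2003, 2004)})
        f = ccme_factors(sl, simple_specs)
        assert f.F1 == f.F2 == 100.0
        assert f.nse == 1.0
        assert f.F3 == pytest.approx(50.0)  # 1 / (0.01 + 0.01)

    def test_worst_case_clamps_to_zero(self):
        f = CcmeFactors(F1=100, F2=100, F3=100, nse=np.inf, n_parameters=8,
                        n_tests=16, n_failed_parameters=8, n_failed_tests=16)
        raw = 100 - math.sqrt(3 * 100**2) / 1.732
        assert raw < 0  # the 1.732 divisor leaves a tiny negative residue
        assert ccme_wqi(f) == 0.0

    def test_zero_tests_is_error(self, simple_specs):
        with pytest.raises(PanelError, match="zero tests"):
            ccme_factors(make_slice({}), simple_specs)

    def test_f3_stays_below_100(self, simple_specs):
        sl = make_slice({("P1", 2003): 1e9})
        f = ccme_factors(sl, [simple_specs[0]])
        assert 0 <= f.F3 < 100

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_adding_failed_test_never_increases_index(self, simple_specs, seed):
        rng = np.random.default_rng(seed)
        values = {
            (f"P{i}", 2003 + y): float(rng.uniform(1, 15))
            for i in range(1, 9) for y in range(3)
        }
        base = ccme_wqi(ccme_factors(make_slice(values), simple_specs))
        values[("P1", 2099)] = float(rng.uniform(10.01, 40))  # one more failure
        worse = ccme_wqi(ccme_factors(make_slice(values), simple_specs))
        assert worse <= base + 1e-9

    def test_order_invariance(self, simple_specs):
        values = {(f"P{i}", 2003 + y): 5.0 + i + y for i in range(1, 9)
                  for y in range(2)}
        sl = make_slice(values)
        shuffled = sl.sample(frac=1, random_state=4).reset_index(drop=True)
        a = ccme_wqi(ccme_factors(sl, simple_specs))
        b = ccme_wqi(ccme_factors(shuffled, simple_specs))
        assert a == b


class TestBc:
    def test_all_objectives_met_gives_zero(self, simple_specs):
        sl = make_slice({(f"P{i}", 2003): 5.0 for i in range(1, 9)})
        assert bc_wqi(sl, simple_specs).value == 0.0

    def test_worst_case_maps_near_100(self, simple_specs):
        sl = make_slice({(f"P{i}", y): 25.0 for i in range(1, 9)
                         for y in (2003, 2004)})
        res = bc_wqi(sl, simple_specs)
        assert res.factors.F1 == res.factors.F2 == res.factors.F3 == 100.0
        assert res.value == pytest.approx(
            math.sqrt(2 * 100**2 + (100 / 3) ** 2) / 1.453
        )
        assert res.value == pytest.approx(100.0, abs=0.01)

    def test_single_failed_test_hand_oracle(self):
        sl = make_slice({("X", 2003): 15.0})  # excursion 0.5 -> F3 = 50
        res = bc_wqi(sl, [UPPER10])
        assert res.factors.F3 == 50.0
        assert res.value == pytest.approx(
            math.sqrt(100**2 + 100**2 + (50 / 3) ** 2) / 1.453
        )
        assert res.value == pytest.approx(98.0042, abs=1e-3)

    def test_f3_is_maximum_excursion(self, simple_specs):
        sl = make_slice({("P1", 2003): 12.0, ("P2", 2003): 15.0,
                         ("P3", 2003): 5.0})
        res = bc_wqi(sl, simple_specs)
        assert res.factors.F3 == pytest.approx(100 * (15 / 10 - 1), abs=1e-9)

    def test_f3_capped_at_100(self, simple_specs):
        sl = make_slice({("P1", 2003): 30.0})  # excursion 2.0 -> 200, capped
        assert bc_wqi(sl, simple_specs).factors.F3 == 100.0


class TestWeighted:
    def test_vi_equals_si_gives_100(self, default_specs):
        sl = make_slice({(s.parameter, 2003): s.standard_S
                         for s in default_specs})
        assert weighted_wqi(sl, default_specs).value == pytest.approx(100.0)

    def test_vi_equals_v0_gives_0(self, default_specs):
        sl = make_slice({(s.parameter, 2003): s.ideal_V0
                         for s in default_specs})
        assert weighted_wqi(sl, default_specs).value == pytest.approx(0.0)

    def test_two_parameter_hand_oracle(self):
        specs = [LOWER5, RANGE_PH]
        sl = make_slice({("DO", 2003): 7.3, ("pH", 2003): 7.75})
        res = weighted_wqi(sl, specs)
        # Qi: DO 100*7.3/9.6 = 76.0417, pH 100*0.75/1.5 = 50
        # weights 1/5 and 1/8.5 normalized: 0.6296 / 0.3704
        assert res.value == pytest.approx(66.40, abs=0.01)
        weights = [w for _, _, w in res.subindices]
        assert sum(weights) == pytest.approx(1.0)

    def test_single_parameter_equals_its_subindex(self):
        sl = make_slice({("DO", 2003): 6.0, ("DO", 2004): 8.0})
        res = weighted_wqi(sl, [LOWER5])
        qi = 100 * abs(7.0 - 14.6) / abs(5.0 - 14.6)  # Vi = slice mean = 7.0
        assert res.value == pytest.approx(qi)

    def test_weights_renormalized_over_available(self, default_specs):
        full = make_slice({(s.parameter, 2003): s.standard_S
                           for s in default_specs})
        partial = full[full["parameter"].isin(["DO", "pH", "BOD"])]
        assert weighted_wqi(partial, default_specs).value == pytest.approx(100.0)

    def test_all_missing_is_error(self, default_specs):
        with pytest.raises(PanelError):
            weighted_wqi(make_slice({}), default_specs)

    def test_ph_below_ideal_gives_positive_subindex(self):
        res = weighted_wqi(make_slice({("pH", 2003): 6.4}), [RANGE_PH])
        assert res.value == pytest.approx(100 * 0.6 / 1.5)
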