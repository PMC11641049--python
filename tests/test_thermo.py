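"""Driving-force and flux-reversal-point thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from cccflux.thermo import (
    KCC,
    NKCC,
    BathConditions,
    Stoichiometry,
    ThermoError,
    driving_force,
    driving_force_curve,
    frp_chloride,
    nernst_potential,
    solution_conditions,
)

RT = 8.314 * 298.15


class TestStoichiometry:
    def test_electroneutrality_enforced(self):
        with pytest.raises(ThermoError, match="electroneutral"):
            Stoichiometry(1, 1, 1)

    def test_needs_chloride(self):
        with pytest.raises(ThermoError):
            Stoichiometry(0, 0, 0)

    def test_parse(self):
        assert Stoichiometry.parse("1:1:2") == NKCC
        assert Stoichiometry.parse("0:1:1") == KCC


class TestDrivingForce:
    def test_zero_at_frp_substitution(self, nd96):
        # KCC at cl_i = k_o*cl_o/k_i = 2.132: closed-form reversal point
        dmu = driving_force(KCC, nd96.with_cl_i(2.132))
        assert abs(dmu) < 1e-6

    def test_symmetric_concentrations_give_zero(self):
        cond = BathConditions(na_i=10, na_o=10, k_i=5, k_o=5, cl_i=15, cl_o=15)
        for stoich in (KCC, NKCC):
            assert driving_force(stoich, cond) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_value(self, nd96):
        # RT*ln(100*1/(2*106.6)) = -1876.6 J/mol
        dmu = driving_force(KCC, nd96.with_cl_i(1.0))
        assert dmu == pytest.approx(RT * math.log(100.0 / (2 * 106.6)), rel=1e-12)
        assert dmu == pytest.approx(-1876.6, abs=0.5)

    def test_zero_concentration_names_ion(self, nd96):
        with pytest.raises(ThermoError, match="Cl-"):
            driving_force(KCC, nd96.with_cl_i(0.0))
        cond = solution_conditions("Na-free")
        with pytest.raises(ThermoError, match="Na\\+"):
            driving_force(NKCC, cond.with_cl_i(1.0))


class TestFluxReversalPoint:
    def test_nkcc_value(self, nd96):
        # 106.6 * sqrt(96*2 / (10*100)) = 46.71
        assert frp_chloride(NKCC, nd96) == pytest.approx(46.71, abs=0.01)
        assert round(frp_chloride(NKCC, nd96), 1) == 46.7

    def test_kcc_value(self, nd96):
        assert frp_chloride(KCC, nd96) == pytest.approx(2.132, abs=1e-9)

    def test_symmetric_cations_return_external_chloride(self):
        cond = BathConditions(na_i=96, na_o=96, k_i=2, k_o=2, cl_o=106.6)
        for stoich in (KCC, NKCC):
            assert frp_chloride(stoich, cond) == pytest.approx(106.6)

    def test_kcc_frp_linear_in_external_k(self, nd96):
        base = frp_chloride(KCC, nd96)
        doubled = frp_chloride(KCC, BathConditions(k_o=4.0))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_nkcc_frp_scales_with_sqrt_of_cation_product(self, nd96):
        base = frp_chloride(NKCC, nd96)
        cond4 = BathConditions(na_o=96 * 2, k_o=2 * 2)
        assert frp_chloride(NKCC, cond4) == pytest.approx(2 * base, rel=1e-12)

    def test_independent_of_temperature(self, nd96):
        cold = BathConditions(temperature=277.0)
        assert frp_chloride(NKCC, cold) == pytest.approx(frp_chloride(NKCC, nd96))


@st.composite
def random_stoich_and_conditions(draw):
    n_na = draw(st.integers(0, 3))
    n_k = draw(st.integers(0, 3))
    if n_na + n_k == 0:
        n_k = 1
    stoich = Stoichiometry(n_na, n_k, n_na + n_k)
    conc = st.floats(0.5, 300.0, allow_nan=False)
    cond = BathConditions(
        na_i=draw(conc), na_o=draw(conc), k_i=draw(conc), k_o=draw(conc),
        cl_i=1.0, cl_o=draw(conc), temperature=draw(st.floats(270.0, 320.0)),
    )
    return stoich, cond


class TestClosedFormAgainstNumericRoot:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(random_stoich_and_conditions())
    def test_frp_matches_bisection_and_dmu_vanishes(self, sc):
        stoich, cond = sc
        frp = frp_chloride(stoich, cond)
        assert abs(driving_force(stoich, cond.with_cl_i(frp))) < 1e-6
        root = brentq(
            lambda c: driving_force(stoich, cond.with_cl_i(c)),
            frp * 1e-3, frp * 1e3, rtol=1e-14,
        )
        assert root == pytest.approx(frp, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(random_stoich_and_conditions())
    def test_dmu_strictly_increasing_in_internal_chloride(self, sc):
        stoich, cond = sc
        grid = np.geomspace(0.1, 300.0, 30)
        dmu = [driving_force(stoich, cond.with_cl_i(c)) for c in grid]
        assert np.all(np.diff(dmu) > 0)


class TestDrivingForceCurve:
    def test_single_zero_crossing_brackets_frp(self, nd96):
        grid = np.geomspace(0.1, 100.0, 400)
        for stoich, frp in ((KCC, 2.132), (NKCC, 46.71)):
            curve = driving_force_curve(stoich, nd96, grid)
            signs = np.sign(curve["dmu_J_per_mol"].to_numpy())
            crossings = np.flatnonzero(np.diff(signs) > 0)
            assert crossings.size == 1
            lo = curve["cl_i_mM"].iloc[crossings[0]]
            hi = curve["cl_i_mM"].iloc[crossings[0] + 1]
            assert lo < frp < hi

    def test_grid_above_frp_all_positive(self, nd96):
        curve = driving_force_curve(KCC, nd96, np.linspace(3.0, 50.0, 20))
        assert (curve["dmu_J_per_mol"] > 0).all()

    def test_empty_grid_rejected(self, nd96):
        with pytest.raises(ThermoError, match="empty"):
            driving_force_curve(KCC, nd96, [])


class TestSolutions:
    def test_nd96_stated_chloride(self):
        assert solution_conditions("ND96").cl_o == 106.6

    def test_nd96_salt_sum_chloride(self):
        cond = solution_conditions("ND96", use_salt_sum_chloride=True)
        assert cond.cl_o == pytest.approx(103.6)

    def test_high_k_substitution_preserves_osmolality(self):
        cond = solution_conditions("ND96-10K")
        assert cond.k_o == 10.0
        assert cond.na_o == 88.0

    def test_rb_pooled_as_k_congener(self):
        cond = solution_conditions("ND96-5Rb")
        assert cond.k_o == 5.0
        assert cond.na_o == 93.0

    def test_chloride_free_flagged(self):
        cond = solution_conditions("Cl-free")
        assert cond.cl_o == 0.0 and cond.cl_free
        with pytest.raises(ThermoError):
            driving_force(KCC, cond)

    def test_unknown_recipe(self):
        with pytest.raises(ThermoError, match="unknown"):
            solution_conditions("ND1000")


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst_potential(1, 5.0, 5.0) == 0.0

    def test_potassium_equilibrium_near_minus_100mV(self):
        # 25.693 * ln(2/100) = -100.5 mV
        assert nernst_potential(1, 2.0, 100.0) == pytest.approx(-100.5, abs=0.05)

    def test_valence_antisymmetry(self):
        assert nernst_potential(-2, 10.0, 1.0) == pytest.approx(
            -nernst_potential(2, 10.0, 1.0)
        )

    def test_zero_valence_rejected(self):
        with pytest.raises(ThermoError):
            nernst_potential(0, 1.0, 2.0)
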