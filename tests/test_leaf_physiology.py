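import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipsim.leaf_physiology import (
    PA_PER_PPM,
    PhysiologyParams,
    arrhenius,
    canopy_gpp,
    couple_leaf,
    couple_leaf_series,
    dark_respiration,
    farquhar_net,
    maintenance_respiration,
    medlyn_gs,
)

P = PhysiologyParams()


class TestArrhenius:
    def test_identity_at_reference_temperature(self):
        assert arrhenius(50.0, 60000.0, 25.0) == pytest.approx(50.0)

    def test_zero_activation_energy(self):
        assert arrhenius(50.0, 0.0, -10.0) == pytest.approx(50.0)

    def test_closed_form_at_35C(self):
        # independent evaluation of rate25*exp(ea*(T-298.15)/(298.15*R*T))
        t_k = 35.0 + 273.15
        expected = 50.0 * math.exp(60000.0 * (t_k - 298.15) / (298.15 * 8.314 * t_k))
        assert arrhenius(50.0, 60000.0, 35.0) == pytest.approx(expected, rel=1e-12)


class TestFarquhar:
    def test_darkness_respires_only(self):
        a = farquhar_net(25.0, 15.0, 0.0, P)
        assert a == pytest.approx(-dark_respiration(15.0, P), rel=1e-12)

    def test_compensation_point(self):
        gamma = arrhenius(P.gamma_star25, P.ea_gamma, 18.0)
        a = farquhar_net(gamma, 18.0, 1200.0, P)
        assert a == pytest.approx(-dark_respiration(18.0, P), rel=1e-12)

    def test_brute_force_oracle_at_saturating_light(self):
        # independent scalar evaluation of both limitation terms at 25 degC
        ci, t, par = 25.0, 25.0, 1500.0
        ac = P.vcmax25 * (ci - P.gamma_star25) / (ci + P.kc25 * (1 + P.oi / P.ko25))
        q = P.alpha_q * par
        j = ((q + P.jmax25) - math.sqrt((q + P.jmax25) ** 2 - 4 * P.theta_j * q * P.jmax25)) / (
            2 * P.theta_j
        )
        aj = j / 4 * (ci - P.gamma_star25) / (ci + 2 * P.gamma_star25)
        expected = max(min(ac, aj), 0.0) - P.rd25_frac * P.vcmax25
        assert farquhar_net(ci, t, par, P) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("t_leaf", [5.0, 15.0, 25.0, 35.0])
    def test_nondecreasing_in_light(self, t_leaf):
        pars = np.linspace(0.0, 2000.0, 40)
        a = farquhar_net(np.full_like(pars, 25.0), t_leaf, pars, P)
        assert (np.diff(a) >= -1e-12).all()


class TestMedlyn:
    def test_nonpositive_assimilation_gives_g0(self):
        assert medlyn_gs(-2.0, 380.0, 1.0, P) == P.g0
        assert medlyn_gs(0.0, 380.0, 1.0, P) == P.g0

    def test_zero_slope_closed_form(self):
        p = PhysiologyParams(g1=1e-12)
        assert medlyn_gs(10.0, 380.0, 1.0, p) == pytest.approx(p.g0 + 1.6 * 10.0 / 380.0, rel=1e-6)

    def test_closed_form_oracle(self):
        expected = P.g0 + 1.6 * (1 + P.g1 / math.sqrt(1.2)) * 8.0 / 380.0
        assert medlyn_gs(8.0, 380.0, 1.2, P) == pytest.approx(expected, rel=1e-12)

    def test_vpd_floor_applies(self):
        assert medlyn_gs(8.0, 380.0, 0.0, P) == medlyn_gs(8.0, 380.0, P.vpd_floor, P)


class TestCoupling:
    def test_darkness_solution(self):
        sol = couple_leaf(10.0, 0.0, 1.0, 380.0, P)
        assert sol.a_net == pytest.approx(-dark_respiration(10.0, P), abs=1e-6)
        assert sol.gs == pytest.approx(P.g0)
        assert sol.ci > 380.0 * PA_PER_PPM  # respiring leaf: ci above ambient

    def test_residuals_below_tolerance_for_random_forcing(self):
        rng = np.random.default_rng(0)
        n = 10_000
        t = rng.uniform(-5.0, 35.0, n)
        par = rng.uniform(0.0, 2000.0, n)
        vpd = rng.uniform(0.05, 4.0, n)
        ca = np.full(n, 380.0)
        a_net, _, gs, ci_pa = couple_leaf_series(t, par, vpd, ca, P)
        a_check = farquhar_net(ci_pa, t, par, P)
        diffusion = gs / 1.6 * (ca - ci_pa / PA_PER_PPM)
        assert np.max(np.abs(a_net - a_check)) < 1e-3
        assert np.max(np.abs(a_net - diffusion)) < 1e-3

    def test_scalar_and_vector_solvers_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = rng.uniform(0.0, 35.0)
            par = rng.uniform(0.0, 2000.0)
            vpd = rng.uniform(0.05, 4.0)
            sol = couple_leaf(t, par, vpd, 380.0, P)
            a, _, gs, ci = couple_leaf_series([t], [par], [vpd], [380.0], P)
            assert sol.a_net == pytest.approx(float(a[0]), abs=2e-3)
            assert sol.gs == pytest.approx(float(gs[0]), abs=1e-4)

    def test_gs_never_below_residual_conductance(self):
        rng = np.random.default_rng(2)
        n = 2000
        _, _, gs, _ = couple_leaf_series(
            rng.uniform(-5, 35, n), rng.uniform(0, 2000, n), rng.uniform(0.05, 4, n),
            np.full(n, 380.0), P,
        )
        assert (gs >= P.g0 - 1e-15).all()

    def test_gs_nonincreasing_in_vpd(self):
        vpds = np.linspace(0.2, 4.0, 30)
        _, _, gs, _ = couple_leaf_series(
            np.full(30, 22.0), np.full(30, 1500.0), vpds, np.full(30, 380.0), P
        )
        assert (np.diff(gs) <= 1e-10).all()


class TestCanopy:
    def test_zero_lai_zero_flux(self):
        gpp, gs = canopy_gpp(10.0, 0.2, 0.0, P)
        assert gpp == 0.0 and gs == 0.0

    def test_sparse_canopy_scaler_tends_to_lai(self):
        lai = 1e-6
        _, gs = canopy_gpp(0.0, 1.0, lai, P)
        assert gs == pytest.approx(lai, rel=1e-5)

    def test_closed_form_scaler(self):
        scaler = (1 - math.exp(-1.5)) / 0.5
        _, gs = canopy_gpp(0.0, 1.0, 3.0, P)
        assert gs == pytest.approx(scaler, rel=1e-12)


class TestMaintenanceRespiration:
    def test_zero_pools_zero_respiration(self):
        assert maintenance_respiration(0.0, 0.0, 0.0, 15.0, P) == (0.0, 0.0, 0.0)

    def test_proportional_to_pools(self):
        r1 = maintenance_respiration(1.0, 2.0, 10.0, 15.0, P)
        r2 = maintenance_respiration(1.0, 4.0, 10.0, 15.0, P)
        assert r2[1] == pytest.approx(2 * r1[1], rel=1e-12)

    def test_closed_form_oracle(self):
        factor = math.exp(P.ea_resp * (288.15 - 298.15) / (298.15 * 8.314 * 288.15))
        r_leaf, _, r_stem = maintenance_respiration(2.0, 0.0, 5.0, 15.0, P)
        assert r_leaf == pytest.approx(P.r_leaf25 * 2.0 * factor, rel=1e-10)
        assert r_stem == pytest.approx(P.r_stem25 * P.sapwood_frac * 5.0 * factor, rel=1e-10)


@settings(max_examples=50, deadline=None)
@given(
    t=st.floats(-5, 35), par=st.floats(0, 2000), vpd=st.floats(0.05, 4.0),
)
def test_coupled_solution_satisfies_both_constraints(t, par, vpd):
    sol = couple_leaf(t, par, vpd, 380.0, P)
    a_check = farquhar_net(sol.ci, t, par, P)
    diffusion = sol.gs / 1.6 * (380.0 - sol.ci / PA_PER_PPM)
    assert sol.a_net == pytest.approx(a_check, abs=2e-3)
    assert sol.a_net == pytest.approx(diffusion, abs=2e-3)
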