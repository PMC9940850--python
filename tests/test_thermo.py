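"""Canonical droplet free energy: geometry, depletion, profiles,
stationary points, crossovers, stability diagram."""

import numpy as np
import pytest

from mldroplet.thermo import (
    CanonicalSystem,
    ThermoParams,
    barrier_curve,
    boundary_box_length,
    classify_condition,
    cnt_barrier,
    cnt_critical_size,
    crossover_density,
    depleted_density,
    droplet_area,
    droplet_radius,
    finite_size_profile,
    macroscopic_profile,
    stability_diagram,
    stationary_points,
)
from mldroplet.kelvin import kelvin_density
from mldroplet.units import (
    mg_per_ml_to_number_density,
    number_density_to_mg_per_ml,
    surface_tension_to_kT_per_nm2,
)

NDDX4 = ThermoParams(sigma_mN_per_m=0.101, rho_d_star_mgml=4.87,
                     rho_c_mgml=359.0, chain_mass_da=25400.0, label="NDDX4")
FUS = ThermoParams(sigma_mN_per_m=0.37, rho_d_star_mgml=1.03,
                   rho_c_mgml=527.0, chain_mass_da=17180.0, label="FUS-LC")


class TestUnits:
    def test_density_round_trip(self):
        rho = 23.2
        assert number_density_to_mg_per_ml(
            mg_per_ml_to_number_density(rho, 25400.0), 25400.0
        ) == pytest.approx(rho, rel=1e-14)

    def test_surface_tension_conversion_constant(self):
        # 1 mN/m at 300 K is ~0.24143 kT/nm^2
        assert surface_tension_to_kT_per_nm2(1.0, 300.0) == pytest.approx(
            0.24143, rel=1e-4
        )


class TestGeometryAndDepletion:
    def test_area_zero_and_scaling(self):
        assert droplet_area(0.0, 0.0085) == 0.0
        assert droplet_area(800.0, 0.0085) == pytest.approx(
            4.0 * droplet_area(100.0, 0.0085)
        )

    def test_area_cross_check_two_routes(self):
        # n = 100 at rho_c = 0.008512 nm^-3: A ~ 2.50e3 nm^2 = 4 pi r^2
        rho_c = 0.008512
        a = droplet_area(100.0, rho_c)
        r = droplet_radius(100.0, rho_c)
        assert a == pytest.approx(4 * np.pi * r**2, rel=1e-12)
        assert a == pytest.approx(2.50e3, rel=0.01)
        assert r == pytest.approx(14.1, rel=0.01)

    def test_depleted_density_limits_and_value(self):
        system = CanonicalSystem(N=187, V=343000.0)
        rho_c = 0.008512
        assert depleted_density(0.0, system, rho_c) == pytest.approx(187 / 343000.0)
        assert depleted_density(187.0, system, rho_c) == 0.0
        assert depleted_density(130.0, system, rho_c) == pytest.approx(
            1.74e-4, rel=0.01
        )

    def test_droplet_too_big_for_box_rejected(self):
        system = CanonicalSystem(N=1000, V=1000.0)
        with pytest.raises(ValueError):
            depleted_density(999.0, system, 0.008512)


class TestProfiles:
    def test_reference_state_is_zero(self):
        prof = finite_size_profile(NDDX4, CanonicalSystem.from_box_length(187, 70.0))
        assert prof.beta_F[0] == 0.0
        mac = macroscopic_profile(NDDX4, 10.0)
        assert mac.beta_F[0] == 0.0

    def test_confinement_shifts_stationary_points(self):
        # fixed N = 187 chains; growing the box lowers supersaturation:
        # the steady-state droplet shrinks, the barrier rises and the
        # minimum becomes shallower until it disappears
        p = ThermoParams(0.182, 1.0, 359.0, 25400.0)
        sp68 = stationary_points(
            finite_size_profile(p, CanonicalSystem.from_box_length(187, 68.0))
        )
        sp105 = stationary_points(
            finite_size_profile(p, CanonicalSystem.from_box_length(187, 105.0))
        )
        assert sp68.profile_class == "two_stationary"
        assert sp105.profile_class in ("two_stationary", "monotonic")
        if sp105.profile_class == "two_stationary":
            assert sp105.n_ss < sp68.n_ss
            assert sp105.n_crit > sp68.n_crit
            assert sp105.barrier > sp68.barrier

    def test_macroscopic_at_coexistence_is_pure_surface(self):
        prof = macroscopic_profile(NDDX4, NDDX4.rho_d_star_mgml)
        surface = NDDX4.beta_sigma * droplet_area(prof.n, NDDX4.rho_c_nm3)
        assert np.allclose(prof.beta_F, surface, atol=1e-10)

    def test_zero_surface_tension_supersaturated_is_downhill(self):
        p = ThermoParams(1e-12, 4.87, 359.0, 25400.0)
        prof = macroscopic_profile(p, 10.0)
        assert np.all(np.diff(prof.beta_F) < 0)

    def test_undersaturated_macroscopic_reported_monotonic(self):
        prof = macroscopic_profile(NDDX4, 2.0)  # below rho_d* = 4.87
        sp = stationary_points(prof)
        assert sp.profile_class == "monotonic"
        assert np.all(np.diff(prof.beta_F) > 0)

    def test_finite_size_converges_to_cnt_at_rate_n2_over_2N(self):
        # the depletion work differs from the CNT bulk term by
        # (n^2/2N)(1 - rho0/rho_c) to leading order -- the physical
        # finite-reservoir correction of the canonical ensemble
        rho0 = 10.0
        N = 10**6
        V = N / NDDX4.to_nm3(rho0)
        fin = finite_size_profile(NDDX4, CanonicalSystem(N=N, V=V), n_max=50.0)
        S = rho0 / NDDX4.rho_d_star_mgml
        mac = -fin.n * np.log(S) + NDDX4.beta_sigma * droplet_area(
            fin.n, NDDX4.rho_c_nm3
        )
        dev = np.abs(fin.beta_F - mac)
        bound = fin.n**2 / (2 * N) * (1 - NDDX4.to_nm3(rho0) / NDDX4.rho_c_nm3)
        # 5e-7 slack: differences of O(10^7) log terms round at ~1e-7
        assert np.all(dev <= bound * 1.05 + 5e-7)
        assert dev.max() < 1.3e-3


class TestStationaryPointsAgainstPrintedSizes:
    @pytest.mark.parametrize(
        "params,N,L,expected",
        [(NDDX4, 187, 70.0, 130.0), (FUS, 268, 70.0, 243.0)],
    )
    def test_steady_state_size_matches_observation(self, params, N, L, expected):
        sp = stationary_points(
            finite_size_profile(params, CanonicalSystem.from_box_length(N, L))
        )
        assert sp.profile_class == "two_stationary"
        assert sp.n_ss == pytest.approx(expected, rel=0.05)

    def test_minimum_satisfies_kelvin_relation(self, rng):
        # the central internal-consistency oracle: at the free-energy
        # minimum the depleted dilute density equals the
        # curvature-corrected coexistence density
        checked = 0
        while checked < 25:
            p = ThermoParams(
                sigma_mN_per_m=rng.uniform(0.05, 0.5),
                rho_d_star_mgml=rng.uniform(0.5, 8.0),
                rho_c_mgml=rng.uniform(300.0, 600.0),
                chain_mass_da=rng.uniform(1.0e4, 3.0e4),
            )
            system = CanonicalSystem.from_box_length(
                int(rng.integers(50, 400)), rng.uniform(40.0, 90.0)
            )
            sp = stationary_points(finite_size_profile(p, system))
            if sp.profile_class != "two_stationary":
                continue
            lhs = depleted_density(sp.n_ss, system, p.rho_c_nm3)
            rhs = kelvin_density(sp.n_ss, p)
            assert lhs == pytest.approx(rhs, rel=1e-4)
            checked += 1


class TestCNTBarriers:
    def test_closed_form_matches_numeric_maximum(self):
        from scipy.optimize import minimize_scalar

        S = 10.0 / NDDX4.rho_d_star_mgml
        bF = lambda n: -n * np.log(S) + NDDX4.beta_sigma * droplet_area(
            n, NDDX4.rho_c_nm3
        )
        res = minimize_scalar(lambda n: -bF(n), bounds=(1e-3, 1e4), method="bounded",
                              options={"xatol": 1e-10})
        assert -res.fun == pytest.approx(cnt_barrier(NDDX4, 10.0), rel=1e-6)
        assert res.x == pytest.approx(cnt_critical_size(NDDX4, 10.0), rel=1e-6)

    def test_nddx4_barrier_at_10_mgml(self):
        assert cnt_barrier(NDDX4, 10.0) == pytest.approx(6.5, rel=0.02)

    def test_barrier_curve_monotone_and_divergent(self):
        grid = np.linspace(6.0, 40.0, 30)
        curve = barrier_curve(NDDX4, grid)
        assert np.all(np.diff(curve["barrier_kT"]) < 0)
        assert cnt_barrier(NDDX4, NDDX4.rho_d_star_mgml * 1.0000001) > 1e6
        assert cnt_barrier(NDDX4, 2.0) == np.inf
        # closed-form invariant: n*^3 ln^6 S... reduces to
        # n_crit * ln^3 S constant across the grid
        inv = curve["n_crit"] * np.log(curve["supersaturation"]) ** 3
        assert np.allclose(inv, inv.iloc[0], rtol=1e-10)

    def test_crossover_densities(self):
        rho_barrier = crossover_density(NDDX4, FUS, "barrier")
        rho_ncrit = crossover_density(NDDX4, FUS, "n_crit")
        assert rho_barrier == pytest.approx(10.0, rel=0.15)
        assert rho_ncrit == pytest.approx(16.0, rel=0.25)
        assert rho_ncrit > rho_barrier

    def test_crossover_absent_reported_none(self):
        a = ThermoParams(0.101, 4.87, 359.0, 25400.0)
        b = ThermoParams(0.102, 4.87, 359.0, 25400.0)  # strictly higher barrier
        assert crossover_density(a, b, "barrier", (5.0, 50.0)) is None

    def test_identical_params_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            crossover_density(NDDX4, NDDX4, "barrier")


class TestStabilityDiagram:
    def test_below_binodal_always_unstable(self):
        for L in (20.0, 60.0, 150.0):
            assert classify_condition(NDDX4, 2.0, L) == "unstable"

    def test_small_box_condition_inhibited(self):
        # L = 40 nm, N = 25 (16.5 mg/mL total): no phase separation
        assert classify_condition(NDDX4, 16.5, 40.0) == "inhibited"
        assert classify_condition(NDDX4, 16.5, 70.0) == "stable"

    def test_stability_monotone_in_volume(self):
        rho0 = 16.5
        L_star = boundary_box_length(NDDX4, rho0)
        assert L_star is not None
        labels = [
            classify_condition(NDDX4, rho0, L)
            for L in (L_star * 0.8, L_star * 1.05, L_star * 2.0, L_star * 4.0)
        ]
        assert labels == ["inhibited", "stable", "stable", "stable"]

    def test_diagram_long_format(self):
        df = stability_diagram(NDDX4, [2.0, 16.5], [40.0, 70.0])
        assert len(df) == 4
        assert set(df["region"]) <= {"unstable", "inhibited", "stable"}
        assert (df[df.rho0_mgml == 2.0]["region"] == "unstable").all()
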