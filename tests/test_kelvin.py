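"""Gibbs-Thomson/Kelvin analysis: forward model, global fit, bootstrap."""

import numpy as np
import pytest

from mldroplet.kelvin import (
    bootstrap_ci,
    chain_mass_from_table,
    fit_parameters,
    kelvin_density,
    predict_nss,
)
from mldroplet.synthetic import make_observation_table
from mldroplet.thermo import CanonicalSystem, ThermoParams

NDDX4 = ThermoParams(0.101, 4.87, 359.0, 25400.0)
FUS = ThermoParams(0.37, 1.03, 527.0, 17180.0)


class TestKelvinDensity:
    def test_flat_interface_limit(self):
        p = ThermoParams(1e-12, 4.87, 359.0, 25400.0)
        assert kelvin_density(37.0, p) == pytest.approx(p.rho_d_star_nm3, rel=1e-9)

    def test_large_droplet_limit(self):
        assert kelvin_density(1e12, NDDX4) == pytest.approx(
            NDDX4.rho_d_star_nm3, rel=1e-3
        )

    def test_monotone_decreasing_in_size(self):
        n = np.array([10.0, 50.0, 200.0])
        k = kelvin_density(n, NDDX4)
        assert np.all(np.diff(k) < 0)

    def test_value_at_observed_size(self):
        # n_ss = 130 -> r ~ 15.4 nm, exponent 2 beta sigma/(rho_c r)
        assert kelvin_density(130.0, NDDX4) == pytest.approx(1.68e-4, rel=0.01)


class TestPredictNss:
    @pytest.mark.parametrize(
        "params,N,L,expected",
        [(NDDX4, 187, 70.0, 130.0), (FUS, 268, 70.0, 243.0)],
    )
    def test_printed_anchor_points(self, params, N, L, expected):
        nss = predict_nss(params, CanonicalSystem.from_box_length(N, L))
        assert nss == pytest.approx(expected, rel=0.05)

    def test_undersaturated_inhibited(self):
        # rho0 = 25/70^3 nm^-3 ~ 3.1 mg/mL < rho_d* = 4.87
        assert predict_nss(NDDX4, CanonicalSystem.from_box_length(25, 70.0)) is None

    def test_small_box_inhibited_matches_observation(self):
        # the L = 40 nm, N = 25 condition showed no phase separation
        assert predict_nss(NDDX4, CanonicalSystem.from_box_length(25, 40.0)) is None


class TestGlobalFit:
    def test_noiseless_round_trip_is_exact(self):
        table = make_observation_table(0.2, 3.0, 400.0, 20000.0, noise_frac=0.0)
        fit = fit_parameters(table, 400.0, 20000.0)
        assert fit.sigma_mN_per_m == pytest.approx(0.2, rel=1e-6)
        assert fit.rho_d_star_mgml == pytest.approx(3.0, rel=1e-6)

    def test_printed_parameters_recovered(self, nddx4_fit, fus_fit):
        assert nddx4_fit.sigma_mN_per_m == pytest.approx(0.101, rel=0.10)
        assert nddx4_fit.rho_d_star_mgml == pytest.approx(4.87, rel=0.10)
        assert fus_fit.sigma_mN_per_m == pytest.approx(0.37, rel=0.10)
        assert fus_fit.rho_d_star_mgml == pytest.approx(1.03, rel=0.10)

    def test_linear_and_nonlinear_objectives_agree(self, nddx4_table):
        lin = fit_parameters(nddx4_table, 359.0)
        nl = fit_parameters(nddx4_table, 359.0, method="nonlinear")
        assert nl.sigma_mN_per_m == pytest.approx(lin.sigma_mN_per_m, rel=0.02)
        assert nl.rho_d_star_mgml == pytest.approx(lin.rho_d_star_mgml, rel=0.02)

    def test_parity_with_thermo_minimum(self, nddx4_table, nddx4_fit):
        # predictions from the fitted parameters reproduce each fitted
        # row's observation within the fit's own scatter
        stable = nddx4_table[nddx4_table.flag == "stable"]
        rel_dev = []
        for _, row in stable.iterrows():
            system = CanonicalSystem.from_box_length(int(row.N), float(row.L_nm))
            nss = predict_nss(nddx4_fit.params, system)
            rel_dev.append(abs(nss - row.nss) / row.nss)
        assert np.median(rel_dev) < 0.05
        assert max(rel_dev) < 0.15

    def test_too_few_stable_rows_rejected(self, nddx4_table):
        small = nddx4_table[nddx4_table.flag == "stable"].head(2)
        with pytest.raises(ValueError, match=">= 3"):
            fit_parameters(small, 359.0, 25400.0)

    def test_recovery_under_observation_noise(self):
        # at 1% size noise the design grid carries enough information:
        # sigma within 10% and rho_d* within 20% in >= 90% of seeds
        # (at 3% noise the slope uncertainty of this design is ~12%
        # relative -- see the bootstrap tests -- so errors there are
        # dominated by the design, not the estimator)
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            table = make_observation_table(
                0.101, 4.87, 359.0, 25400.0, noise_frac=0.01, seed=seed
            )
            fit = fit_parameters(table, 359.0, 25400.0, weights="nss_err")
            ok = (
                abs(fit.sigma_mN_per_m - 0.101) / 0.101 < 0.10
                and abs(fit.rho_d_star_mgml - 4.87) / 4.87 < 0.20
            )
            hits += ok
        assert hits >= 0.9 * n_seeds

    def test_weighted_fit_attains_linearized_information_bound(self):
        # linearized Cramer-Rao bound for the slope of the weighted
        # log-density regression at the 12-condition design with 3%
        # size noise: the weighted estimator's Monte-Carlo error must
        # sit at the bound (within sampling error), and the bound
        # itself is ~12% relative -- the design's information limit
        from mldroplet.kelvin import _design_matrix, _stable_rows
        from mldroplet.thermo import CanonicalSystem, depleted_density
        from mldroplet.units import surface_tension_from_kT_per_nm2

        mass, rho_c_mgml = 25400.0, 359.0
        rho_c = rho_c_mgml / (mass * 1.66053906892)
        clean = make_observation_table(0.101, 4.87, rho_c_mgml, mass,
                                       noise_frac=0.0)
        stable = _stable_rows(clean)
        x, _ = _design_matrix(stable, rho_c)
        sy = []
        for _, row in stable.iterrows():
            s = CanonicalSystem.from_box_length(int(row.N), float(row.L_nm))
            n, eps = row.nss, 1e-4
            d = (
                np.log(depleted_density(n + eps, s, rho_c))
                - np.log(depleted_density(n - eps, s, rho_c))
            ) / (2 * eps)
            sy.append(abs(d) * 0.03 * n)
        w = 1.0 / np.square(sy)
        xb = np.sum(w * x) / np.sum(w)
        crb_slope = np.sqrt(1.0 / np.sum(w * (x - xb) ** 2))
        crb_rel = surface_tension_from_kT_per_nm2(crb_slope, 300.0) / 0.101
        assert 0.08 < crb_rel < 0.16  # the documented ~12% limit

        errs = []
        for seed in range(40):
            table = make_observation_table(0.101, 4.87, rho_c_mgml, mass,
                                           noise_frac=0.03, seed=seed)
            fit = fit_parameters(table, rho_c_mgml, mass, weights="nss_err")
            errs.append(fit.sigma_mN_per_m - 0.101)
        mc_rel = np.std(errs) / 0.101
        assert mc_rel == pytest.approx(crb_rel, rel=0.35)

    def test_inverse_variance_weighting_beats_equal_weights(self):
        # log-density noise is heteroscedastic (rows with small N - n_ss
        # amplify size noise), so propagated 1/err^2 weights should cut
        # the median sigma error
        errs = {"equal": [], "weighted": []}
        for seed in range(20):
            table = make_observation_table(
                0.101, 4.87, 359.0, 25400.0, noise_frac=0.03, seed=seed
            )
            for label, kw in [("equal", {}), ("weighted", {"weights": "nss_err"})]:
                fit = fit_parameters(table, 359.0, 25400.0, **kw)
                errs[label].append(abs(fit.sigma_mN_per_m - 0.101) / 0.101)
        assert np.median(errs["weighted"]) < np.median(errs["equal"])


class TestBootstrap:
    def test_same_seed_identical_intervals(self, nddx4_table):
        a = bootstrap_ci(nddx4_table, 359.0, n_boot=200, seed=42)
        b = bootstrap_ci(nddx4_table, 359.0, n_boot=200, seed=42)
        assert a.ci95_sigma == b.ci95_sigma
        assert a.ci95_rho == b.ci95_rho

    def test_point_estimates_inside_intervals(self, nddx4_table):
        fit = bootstrap_ci(nddx4_table, 359.0, n_boot=400, seed=7)
        assert fit.ci95_sigma[0] <= fit.sigma_mN_per_m <= fit.ci95_sigma[1]
        assert fit.ci95_rho[0] <= fit.rho_d_star_mgml <= fit.ci95_rho[1]

    def test_sigma_ci_same_order_as_reported_uncertainty(self, nddx4_table):
        # the published estimate carries ~ +/-0.06 mN/m
        fit = bootstrap_ci(nddx4_table, 359.0, n_boot=800, seed=1)
        half = 0.5 * (fit.ci95_sigma[1] - fit.ci95_sigma[0])
        assert 0.01 < half < 0.2

    def test_ci_shrinks_with_noise(self):
        wide = bootstrap_ci(
            make_observation_table(0.2, 3.0, 400.0, 2e4, noise_frac=0.05, seed=3),
            400.0, 2e4, n_boot=300, seed=5,
        )
        narrow = bootstrap_ci(
            make_observation_table(0.2, 3.0, 400.0, 2e4, noise_frac=0.002, seed=3),
            400.0, 2e4, n_boot=300, seed=5,
        )
        assert (narrow.ci95_sigma[1] - narrow.ci95_sigma[0]) < (
            wide.ci95_sigma[1] - wide.ci95_sigma[0]
        )


class TestChainMass:
    def test_masses_from_paired_density_columns(self, nddx4_table, fus_table):
        assert chain_mass_from_table(nddx4_table) == pytest.approx(2.54e4, rel=0.01)
        assert chain_mass_from_table(fus_table) == pytest.approx(1.71e4, rel=0.01)

    def test_fabricated_consistent_table_exact(self):
        import pandas as pd

        rho_nm3 = np.array([1e-4, 2e-4])
        table = pd.DataFrame(
            {"rho0_nm3": rho_nm3, "rho0_mgml": rho_nm3 * 1e4 * 1.66053906892}
        )
        assert chain_mass_from_table(table) == pytest.approx(1e4, rel=1e-12)

    def test_inconsistent_rows_warn(self):
        import pandas as pd

        table = pd.DataFrame(
            {"rho0_nm3": [1e-4, 1e-4], "rho0_mgml": [1.66, 2.0]}
        )
        with pytest.warns(UserWarning, match="inconsistent"):
            chain_mass_from_table(table)
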