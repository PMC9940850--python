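"""Gibbs-Thomson/Kelvin analysis of steady-state droplet observations.

A steady-state droplet of n_ss chains in a finite NVT box coexists
with a dilute phase whose density is elevated above the macroscopic
coexistence value rho_d* by droplet curvature:

    rho_d^(n_ss) = rho_d* exp( 2 sigma / (rho_c kT r_ss) ),
    r_ss = (3 n_ss / (4 pi rho_c))^(1/3).

Since rho_d^(n_ss) = (N - n_ss)/(V - n_ss/rho_c) is fixed by the
simulation condition, each observed (N, V, n_ss) triple constrains
(sigma, rho_d*).  Taking logs the relation is linear in the unknowns:

    ln rho_d^(n_ss) = ln rho_d* + beta*sigma * x,   x = 2/(rho_c r_ss),

so a global least-squares fit over a set of box sizes and chain counts
yields the surface tension (slope) and the equilibrium dilute-phase
density (intercept).  Confidence intervals come from a case-resampling
bootstrap over observation rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .thermo import (
    CanonicalSystem,
    ThermoParams,
    depleted_density,
    droplet_radius,
)
from .units import DA_PER_NM3_TO_MG_PER_ML, surface_tension_from_kT_per_nm2

__all__ = [
    "FitResult",
    "kelvin_density",
    "predict_nss",
    "fit_parameters",
    "bootstrap_ci",
    "chain_mass_from_table",
]

#: Canonical observation-table columns (Table-style layout, explicit units).
TABLE_COLUMNS = ["system", "L_nm", "N", "rho0_nm3", "rho0_mgml", "nss", "nss_err", "flag"]


@dataclass
class FitResult:
    """Outcome of the global Kelvin fit."""

    sigma_mN_per_m: float
    rho_d_star_mgml: float
    rho_c_mgml: float
    chain_mass_da: float
    temperature: float
    residuals: pd.DataFrame
    method: str
    ci95_sigma: tuple[float, float] | None = None
    ci95_rho: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def params(self) -> ThermoParams:
        return ThermoParams(
            sigma_mN_per_m=self.sigma_mN_per_m,
            rho_d_star_mgml=self.rho_d_star_mgml,
            rho_c_mgml=self.rho_c_mgml,
            chain_mass_da=self.chain_mass_da,
            temperature=self.temperature,
        )

    def to_dict(self) -> dict:
        d = dict(
            sigma_mN_per_m=self.sigma_mN_per_m,
            rho_d_star_mgml=self.rho_d_star_mgml,
            rho_c_mgml=self.rho_c_mgml,
            chain_mass_da=self.chain_mass_da,
            temperature_K=self.temperature,
            method=self.method,
            n_boot=self.n_boot,
            seed=self.seed,
            flags=self.flags,
        )
        if self.ci95_sigma is not None:
            d["ci95_sigma_mN_per_m"] = list(self.ci95_sigma)
            d["ci95_rho_d_star_mgml"] = list(self.ci95_rho)
        return d


def kelvin_density(n_ss, params: ThermoParams):
    """Dilute-phase number density [nm^-3] in equilibrium with an
    n_ss-chain droplet (curvature-corrected coexistence density)."""
    n_ss = np.asarray(n_ss, dtype=float)
    if np.any(n_ss <= 0):
        raise ValueError("n_ss must be positive")
    r = droplet_radius(n_ss, params.rho_c_nm3)
    return params.rho_d_star_nm3 * np.exp(
        2.0 * params.beta_sigma / (params.rho_c_nm3 * r)
    )


def predict_nss(params: ThermoParams, system: CanonicalSystem) -> float | None:
    """Steady-state droplet size: the larger (stable) root of
    rho_d^n = kelvin_density(n).

    Returns None when no root exists (condensation inhibited by
    confinement at this N, V).
    """
    rho_c = params.rho_c_nm3
    n_hi = min(float(system.N) * (1.0 - 1e-12), 0.999 * rho_c * system.V)

    def g(n):
        # g = ln rho_d^n - ln kelvin(n); stable root crosses + -> -
        r = droplet_radius(n, rho_c)
        return (
            np.log(depleted_density(n, system, rho_c))
            - np.log(params.rho_d_star_nm3)
            - 2.0 * params.beta_sigma / (rho_c * r)
        )

    grid = np.geomspace(1e-6, n_hi, 600)
    vals = g(grid)
    i_max = int(np.argmax(vals))
    if vals[i_max] <= 0:
        return None
    if vals[-1] >= 0:  # no descending crossing before the depletion cap
        return None
    return float(brentq(g, grid[i_max], n_hi, xtol=1e-10, rtol=8.9e-16))


def _stable_rows(table: pd.DataFrame) -> pd.DataFrame:
    flags = table["flag"].astype(str).str.lower()
    stable = table[flags == "stable"].copy()
    return stable


def _design_matrix(stable: pd.DataFrame, rho_c_nm3: float):
    systems = [
        CanonicalSystem.from_box_length(int(N), float(L))
        for N, L in zip(stable["N"], stable["L_nm"])
    ]
    nss = stable["nss"].to_numpy(dtype=float)
    y = np.log(
        [depleted_density(n, s, rho_c_nm3) for n, s in zip(nss, systems)]
    )
    x = 2.0 / (rho_c_nm3 * droplet_radius(nss, rho_c_nm3))
    return x, y


def fit_parameters(
    table: pd.DataFrame,
    rho_c_mgml: float,
    chain_mass_da: float | None = None,
    temperature: float = 300.0,
    method: str = "linear",
    weights: str | None = None,
) -> FitResult:
    """Global fit of the Kelvin relation to the stable rows of an
    observation table.

    Parameters
    ----------
    table : observation table with columns ``TABLE_COLUMNS``; only rows
        with flag == "stable" enter the fit (>= 3 required).
    rho_c_mgml : condensed-phase density, held fixed (taken from the
        droplet radial density profiles, not fitted).
    chain_mass_da : chain molar mass; derived from the table's paired
        density columns when omitted.
    method : "linear" -- ordinary least squares of ln rho_d^(n_ss) on
        2/(rho_c r_ss) (default); "nonlinear" -- Levenberg-Marquardt in
        density space, initialized from the linear solution.
    weights : None for equal weights, or "nss_err" to weight rows by
        the propagated inverse variance of ln rho_d^(n_ss).
    """
    if chain_mass_da is None:
        chain_mass_da = chain_mass_from_table(table)
    stable = _stable_rows(table)
    if len(stable) < 3:
        raise ValueError(f"need >= 3 stable rows, got {len(stable)}")
    rho_c_nm3 = rho_c_mgml / (chain_mass_da * DA_PER_NM3_TO_MG_PER_ML)
    x, y = _design_matrix(stable, rho_c_nm3)

    if weights == "nss_err":
        # d ln rho_d^n / dn at the observation, times nss_err
        eps = 1e-6
        dy = []
        for L, N, n, e in zip(stable["L_nm"], stable["N"], stable["nss"], stable["nss_err"]):
            s = CanonicalSystem.from_box_length(int(N), float(L))
            d = (
                np.log(depleted_density(n + eps, s, rho_c_nm3))
                - np.log(depleted_density(n - eps, s, rho_c_nm3))
            ) / (2 * eps)
            dy.append(abs(d) * max(float(e), 1e-9))
        w = 1.0 / np.square(dy)
    else:
        w = np.ones_like(y)

    A = np.vstack([x, np.ones_like(x)]).T
    Aw = A * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    (slope, intercept), *_ = np.linalg.lstsq(Aw, yw, rcond=None)

    if method == "nonlinear":
        # residuals in density space (nm^-3), same model
        def resid(p):
            return np.sqrt(w) * (np.exp(p[1] + p[0] * x) - np.exp(y))

        sol = least_squares(resid, x0=[slope, intercept], method="lm")
        slope, intercept = sol.x
    elif method != "linear":
        raise ValueError(f"unknown method {method!r}")

    sigma = surface_tension_from_kT_per_nm2(slope, temperature)
    rho_star_mgml = np.exp(intercept) * chain_mass_da * DA_PER_NM3_TO_MG_PER_ML
    flags = []
    if sigma < 0:
        flags.append("negative_surface_tension")
        warnings.warn("fitted surface tension is negative")
    resid_tbl = stable[["system", "L_nm", "N", "nss"]].copy()
    resid_tbl["x"] = x
    resid_tbl["log_rho_obs"] = y
    resid_tbl["log_rho_fit"] = intercept + slope * x
    resid_tbl["residual"] = y - resid_tbl["log_rho_fit"]
    return FitResult(
        sigma_mN_per_m=float(sigma),
        rho_d_star_mgml=float(rho_star_mgml),
        rho_c_mgml=float(rho_c_mgml),
        chain_mass_da=float(chain_mass_da),
        temperature=temperature,
        residuals=resid_tbl,
        method=method,
        flags=flags,
    )


def bootstrap_ci(
    table: pd.DataFrame,
    rho_c_mgml: float,
    chain_mass_da: float | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    temperature: float = 300.0,
    method: str = "linear",
) -> FitResult:
    """Kelvin fit with percentile-bootstrap 95% confidence intervals.

    Rows are resampled with replacement; replicates with fewer than
    three distinct rows are redrawn (a degenerate design cannot
    constrain two parameters).  Same seed + table -> identical result.
    """
    if chain_mass_da is None:
        chain_mass_da = chain_mass_from_table(table)
    base = fit_parameters(
        table, rho_c_mgml, chain_mass_da, temperature=temperature, method=method
    )
    stable = _stable_rows(table).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n_rows = len(stable)
    sig, rho = np.empty(n_boot), np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n_rows, size=n_rows)
            if len(np.unique(idx)) >= 3:
                break
        with warnings.catch_warnings():
            # degenerate resamples may fit sigma < 0; the percentile
            # interval reports that honestly, no need to warn per draw
            warnings.simplefilter("ignore")
            rep = fit_parameters(
                stable.iloc[idx], rho_c_mgml, chain_mass_da,
                temperature=temperature, method=method,
            )
        sig[b] = rep.sigma_mN_per_m
        rho[b] = rep.rho_d_star_mgml
    base.ci95_sigma = tuple(np.percentile(sig, [2.5, 97.5]))
    base.ci95_rho = tuple(np.percentile(rho, [2.5, 97.5]))
    base.n_boot = n_boot
    base.seed = seed
    return base


def chain_mass_from_table(table: pd.DataFrame, tol: float = 0.01) -> float:
    """Chain molar mass [Da] implied by the table's paired density columns.

    Each row carries the total density both as a number density
    [nm^-3] and a mass density [mg/mL]; their ratio fixes the chain
    mass.  Warns when the per-row values spread by more than ``tol``
    (printed-precision round-off is ~0.3%).
    """
    masses = table["rho0_mgml"].to_numpy(dtype=float) / (
        table["rho0_nm3"].to_numpy(dtype=float) * DA_PER_NM3_TO_MG_PER_ML
    )
    mean = float(np.mean(masses))
    spread = (masses.max() - masses.min()) / mean
    if spread > tol:
        warnings.warn(
            f"chain mass inconsistent across rows (spread {spread:.1%}): "
            + ", ".join(f"{m:.0f}" for m in masses)
        )
    return mean
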