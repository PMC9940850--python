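"""Canonical-ensemble liquid-droplet thermodynamics of protein condensation.

In a closed simulation box (NVT) the assembly of an n-chain condensate
droplet depletes the surrounding dilute phase, so the work of droplet
formation differs qualitatively from the open-system classical
nucleation theory (CNT) expression: the free-energy profile F(n) can
develop a local *minimum* at a self-limiting steady-state size n_ss in
addition to the local maximum at the critical size n*.

The finite-size profile implemented here is the capillarity (modified
liquid droplet) work of formation

    beta*F(n) = beta*sigma*A(n) - Integral_0^n ln(rho_d^m / rho_d*) dm ,

where A(n) is the surface area of a spherical droplet of n chains at
condensed density rho_c and rho_d^m = (N - m)/(V - m/rho_c) is the
depleted dilute-phase density with an m-chain droplet present.  The
integral has a closed form (see :func:`finite_size_profile`).  Its
stationarity condition dF/dn = 0 is exactly the Gibbs-Thomson/Kelvin
relation rho_d^n = rho_d* exp(2 sigma/(rho_c kT r(n))), and in the
macroscopic limit (N, V -> inf at fixed total density rho_d0) it
reduces to the CNT work -n ln(rho_d0/rho_d*) + beta*sigma*A(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .units import (
    kT_kJ_per_mol,
    mg_per_ml_to_number_density,
    number_density_to_mg_per_ml,
    surface_tension_to_kT_per_nm2,
)

__all__ = [
    "ThermoParams",
    "CanonicalSystem",
    "FreeEnergyProfile",
    "StationaryPoints",
    "droplet_radius",
    "droplet_area",
    "depleted_density",
    "finite_size_profile",
    "macroscopic_profile",
    "stationary_points",
    "cnt_barrier",
    "cnt_critical_size",
    "barrier_curve",
    "crossover_density",
    "stability_diagram",
]


@dataclass(frozen=True)
class ThermoParams:
    """Macroscopic condensation parameters of one protein.

    Parameters
    ----------
    sigma_mN_per_m : planar surface tension of the condensed phase.
    rho_d_star_mgml : equilibrium (coexistence) dilute-phase density.
    rho_c_mgml : condensed-phase density.
    chain_mass_da : molar mass of one chain, used to interconvert
        mg/mL and nm^-3 densities.
    temperature : K.
    """

    sigma_mN_per_m: float
    rho_d_star_mgml: float
    rho_c_mgml: float
    chain_mass_da: float
    temperature: float = 300.0
    label: str = ""

    def __post_init__(self):
        if self.rho_c_mgml <= 0 or self.rho_d_star_mgml <= 0:
            raise ValueError("densities must be positive")
        if self.rho_d_star_mgml >= self.rho_c_mgml:
            raise ValueError("rho_d_star must be below rho_c")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy [kJ/mol]."""
        return kT_kJ_per_mol(self.temperature)

    @property
    def beta_sigma(self) -> float:
        """Surface tension in kT/nm^2."""
        return surface_tension_to_kT_per_nm2(self.sigma_mN_per_m, self.temperature)

    @property
    def rho_d_star_nm3(self) -> float:
        return mg_per_ml_to_number_density(self.rho_d_star_mgml, self.chain_mass_da)

    @property
    def rho_c_nm3(self) -> float:
        return mg_per_ml_to_number_density(self.rho_c_mgml, self.chain_mass_da)

    def to_mgml(self, rho_nm3):
        return number_density_to_mg_per_ml(rho_nm3, self.chain_mass_da)

    def to_nm3(self, rho_mgml):
        return mg_per_ml_to_number_density(rho_mgml, self.chain_mass_da)


@dataclass(frozen=True)
class CanonicalSystem:
    """A finite NVT condition: N chains in a cubic box of volume V [nm^3]."""

    N: int
    V: float

    @classmethod
    def from_box_length(cls, N: int, L: float) -> "CanonicalSystem":
        return cls(N=N, V=float(L) ** 3)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.V <= 0:
            raise ValueError("V must be positive")

    @property
    def L(self) -> float:
        return self.V ** (1.0 / 3.0)

    @property
    def rho0_nm3(self) -> float:
        """Total number density N/V [nm^-3]."""
        return self.N / self.V


@dataclass
class FreeEnergyProfile:
    """beta*F versus droplet size n (n treated as continuous)."""

    n: np.ndarray
    beta_F: np.ndarray
    kind: str  # "finite_size" | "macroscopic"
    params: ThermoParams
    system: CanonicalSystem | None = None
    rho0_nm3: float | None = None  # macroscopic total density
    meta: dict = field(default_factory=dict)


@dataclass
class StationaryPoints:
    """Stationary points of a free-energy profile.

    n_crit is the local maximum (critical nucleus), n_ss the local
    minimum (steady-state droplet); barrier = beta*F(n_crit) relative
    to the homogeneous state F(0) = 0.
    """

    profile_class: str  # "monotonic" | "flex" | "two_stationary" | "barrier_only"
    n_crit: float | None = None
    n_ss: float | None = None
    barrier: float | None = None


# ---------------------------------------------------------------------------
# geometry of a spherical droplet

_GEOM = (36.0 * np.pi) ** (1.0 / 3.0)


def droplet_radius(n, rho_c_nm3: float):
    """Radius [nm] of a spherical droplet of n chains at density rho_c [nm^-3]."""
    return (3.0 * np.asarray(n, dtype=float) / (4.0 * np.pi * rho_c_nm3)) ** (1.0 / 3.0)


def droplet_area(n, rho_c_nm3: float):
    """Surface area [nm^2]: A(n) = (36 pi)^(1/3) (n/rho_c)^(2/3)."""
    return _GEOM * (np.asarray(n, dtype=float) / rho_c_nm3) ** (2.0 / 3.0)


def depleted_density(n, system: CanonicalSystem, rho_c_nm3: float):
    """Dilute-phase number density [nm^-3] with an n-chain droplet present.

    rho_d^n = (N - n) / (V - n/rho_c); requires the droplet to fit in
    the box (V - n/rho_c > 0) and 0 <= n <= N.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0) or np.any(n > system.N):
        raise ValueError("n must lie in [0, N]")
    vapor_volume = system.V - n / rho_c_nm3
    if np.any(vapor_volume <= 0):
        raise ValueError("droplet volume exceeds the box")
    return (system.N - n) / vapor_volume


# ---------------------------------------------------------------------------
# free-energy profiles


def _depletion_work(n, system: CanonicalSystem, rho_c_nm3: float, rho_star_nm3: float):
    """Closed form of Integral_0^n ln(rho_d^m / rho_d*) dm.

    Integral of ln(N - m) dm  = N ln N - (N-n) ln(N-n) - n and the
    volume term integrates analogously, giving

        G(n) = N ln N - (N-n) ln(N-n)
               - rho_c [ V ln V - (V - n/rho_c) ln(V - n/rho_c) ]
               - n ln rho_d*  .
    """
    n = np.asarray(n, dtype=float)
    N, V = float(system.N), system.V
    rem = np.clip(N - n, 0.0, None)
    vap = V - n / rho_c_nm3
    # x ln x -> 0 as x -> 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rem_term = np.where(rem > 0, rem * np.log(np.where(rem > 0, rem, 1.0)), 0.0)
    return (
        N * np.log(N)
        - rem_term
        - rho_c_nm3 * (V * np.log(V) - vap * np.log(vap))
        - n * np.log(rho_star_nm3)
    )


def _default_grid(n_max: float, n_points: int = 400) -> np.ndarray:
    """Linear below n = 1, log-spaced above -- resolves both the small-n
    barrier region and the large-n minimum."""
    if n_max <= 1.0:
        return np.linspace(0.0, n_max, n_points)
    n_lin = max(8, n_points // 10)
    lin = np.linspace(0.0, 1.0, n_lin, endpoint=False)
    log = np.geomspace(1.0, n_max, n_points - n_lin)
    return np.concatenate([lin, log])


def finite_size_profile(
    params: ThermoParams,
    system: CanonicalSystem,
    n_max: float | None = None,
    n_points: int = 400,
) -> FreeEnergyProfile:
    """Finite-size (canonical) droplet formation free energy on a grid.

    beta*F(n) = beta*sigma*A(n) - G(n) with G the depletion work above;
    F(0) = 0 by construction.  The grid is truncated (with a warning)
    if it would cross the depletion singularity V = n/rho_c.
    """
    rho_c = params.rho_c_nm3
    cap = min(float(system.N), 0.999 * rho_c * system.V)
    if n_max is None:
        n_max = cap
    elif n_max > cap:
        warnings.warn("n_max truncated at the depletion limit")
        n_max = cap
    n = _default_grid(n_max, n_points)
    bF = params.beta_sigma * droplet_area(n, rho_c) - _depletion_work(
        n, system, rho_c, params.rho_d_star_nm3
    )
    return FreeEnergyProfile(n=n, beta_F=bF, kind="finite_size", params=params, system=system)


def macroscopic_profile(
    params: ThermoParams,
    rho0_mgml: float,
    n_max: float = 1000.0,
    n_points: int = 400,
) -> FreeEnergyProfile:
    """CNT work of droplet formation at fixed total density rho_d0.

    beta*F(n) = -n ln S + beta*sigma*A(n) with supersaturation
    S = rho_d0/rho_d*.  For S <= 1 the profile is monotonically
    increasing (no barrier); this is reported, not an error.
    """
    if rho0_mgml <= 0:
        raise ValueError("total density must be positive")
    rho0 = params.to_nm3(rho0_mgml)
    S = rho0 / params.rho_d_star_nm3
    n = _default_grid(float(n_max), n_points)
    bF = -n * np.log(S) + params.beta_sigma * droplet_area(n, params.rho_c_nm3)
    return FreeEnergyProfile(
        n=n, beta_F=bF, kind="macroscopic", params=params, rho0_nm3=rho0,
        meta={"supersaturation": S},
    )


# ---------------------------------------------------------------------------
# stationary points

def _dF_dn_finite(n, params: ThermoParams, system: CanonicalSystem):
    """Analytic derivative of the finite-size profile:
    dbetaF/dn = 2 beta sigma/(rho_c r(n)) - ln(rho_d^n / rho_d*)."""
    rho_c = params.rho_c_nm3
    surface = 2.0 * params.beta_sigma / (rho_c * droplet_radius(n, rho_c))
    return surface - np.log(depleted_density(n, system, rho_c) / params.rho_d_star_nm3)


def stationary_points(profile: FreeEnergyProfile, rtol: float = 1e-12) -> StationaryPoints:
    """Locate and classify the stationary points of a profile.

    Sign changes of the analytic derivative are bracketed on the
    profile grid and refined with Brent's method.  Classification:
    ``monotonic`` (no stationary point), ``flex`` (derivative touches
    zero without changing sign), ``two_stationary`` (critical size +
    steady-state minimum) for finite-size profiles, or ``barrier_only``
    for macroscopic profiles with S > 1.
    """
    params = profile.params
    if profile.kind == "macroscopic":
        S = profile.meta.get(
            "supersaturation", profile.rho0_nm3 / params.rho_d_star_nm3
        )
        if S <= 1.0:
            return StationaryPoints(profile_class="monotonic")
        n_c = cnt_critical_size(params, S=S)
        return StationaryPoints(
            profile_class="barrier_only", n_crit=n_c,
            barrier=cnt_barrier(params, S=S),
        )

    system = profile.system
    rho_c = params.rho_c_nm3
    n_hi = min(float(system.N) - 1e-9, 0.999 * rho_c * system.V)

    def deriv(n):
        return _dF_dn_finite(n, params, system)

    # dF/dn -> +inf at both ends; a single interior minimum decides the class
    res = minimize_scalar(deriv, bounds=(1e-6, n_hi), method="bounded",
                          options={"xatol": 1e-10})
    d_min, n_min = res.fun, res.x
    if d_min > 0:
        return StationaryPoints(profile_class="monotonic")
    if d_min > -1e-10:
        bF = _beta_F_finite(n_min, params, system)
        return StationaryPoints(profile_class="flex", n_crit=n_min, n_ss=n_min,
                                barrier=float(bF))
    n_crit = brentq(deriv, 1e-9, n_min, xtol=1e-12, rtol=8.9e-16)
    n_ss = brentq(deriv, n_min, n_hi, xtol=1e-12, rtol=8.9e-16)
    barrier = float(_beta_F_finite(n_crit, params, system))
    return StationaryPoints(
        profile_class="two_stationary", n_crit=n_crit, n_ss=n_ss, barrier=barrier
    )


def _beta_F_finite(n, params: ThermoParams, system: CanonicalSystem):
    rho_c = params.rho_c_nm3
    return params.beta_sigma * droplet_area(n, rho_c) - _depletion_work(
        n, system, rho_c, params.rho_d_star_nm3
    )


# ---------------------------------------------------------------------------
# macroscopic (CNT) barriers, critical sizes, crossovers


def _supersaturation(params: ThermoParams, rho0_mgml: float) -> float:
    return rho0_mgml / params.rho_d_star_mgml


def cnt_barrier(params: ThermoParams, rho0_mgml: float | None = None,
                S: float | None = None) -> float:
    """CNT nucleation barrier in kT: 16 pi (beta sigma)^3 / (3 rho_c^2 ln^2 S).

    Returns inf for S <= 1 (no driving force)."""
    if S is None:
        S = _supersaturation(params, rho0_mgml)
    if S <= 1.0:
        return np.inf
    bs = params.beta_sigma
    return 16.0 * np.pi * bs**3 / (3.0 * params.rho_c_nm3**2 * np.log(S) ** 2)


def cnt_critical_size(params: ThermoParams, rho0_mgml: float | None = None,
                      S: float | None = None) -> float:
    """CNT critical nucleus size: 32 pi (beta sigma)^3 / (3 rho_c^2 ln^3 S)."""
    if S is None:
        S = _supersaturation(params, rho0_mgml)
    if S <= 1.0:
        return np.inf
    bs = params.beta_sigma
    return 32.0 * np.pi * bs**3 / (3.0 * params.rho_c_nm3**2 * np.log(S) ** 3)


def barrier_curve(params: ThermoParams, rho0_grid_mgml) -> "pd.DataFrame":
    """Macroscopic barrier and critical size over a grid of bulk densities.

    Densities at or below rho_d* are reported with infinite barrier.
    Returns a DataFrame (rho0_mgml, supersaturation, barrier_kT, n_crit).
    """
    import pandas as pd

    rows = []
    for rho0 in np.asarray(rho0_grid_mgml, dtype=float):
        S = _supersaturation(params, rho0)
        rows.append(
            dict(rho0_mgml=rho0, supersaturation=S,
                 barrier_kT=cnt_barrier(params, S=S),
                 n_crit=cnt_critical_size(params, S=S))
        )
    return pd.DataFrame(rows)


def crossover_density(
    params_a: ThermoParams,
    params_b: ThermoParams,
    quantity: str = "barrier",
    rho_bounds_mgml: tuple[float, float] = (1.0, 200.0),
) -> float | None:
    """Bulk density [mg/mL] at which two proteins' CNT barriers (or
    critical sizes) are equal.

    Root of the difference on a log-density axis, bracketed above both
    rho_d* values.  Returns None when no sign change exists in the
    scanned interval; raises for identical parameter sets (the
    difference vanishes identically).
    """
    fn = {"barrier": cnt_barrier, "n_crit": cnt_critical_size}[quantity]
    lo = max(rho_bounds_mgml[0], params_a.rho_d_star_mgml, params_b.rho_d_star_mgml)
    lo *= 1.0 + 1e-6
    hi = rho_bounds_mgml[1]
    if hi <= lo:
        raise ValueError("empty bracketing interval above both rho_d*")

    def diff(log_rho):
        rho = np.exp(log_rho)
        return fn(params_a, rho0_mgml=rho) - fn(params_b, rho0_mgml=rho)

    grid = np.linspace(np.log(lo), np.log(hi), 512)
    vals = np.array([diff(x) for x in grid])
    if np.allclose(vals, 0.0, atol=1e-12):
        raise ValueError("identical parameter sets: quantities coincide everywhere")
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    root = brentq(diff, grid[i], grid[i + 1], xtol=1e-12)
    return float(np.exp(root))


# ---------------------------------------------------------------------------
# finite-size stability diagram


def classify_condition(params: ThermoParams, rho0_mgml: float, L_nm: float) -> str:
    """Classify one (total density, box size) point.

    ``unstable`` below the binodal (rho_d0 < rho_d*); ``inhibited``
    when the finite-size profile is monotonically increasing (no
    droplet can be stable); else ``stable``.
    """
    if rho0_mgml < params.rho_d_star_mgml:
        return "unstable"
    V = float(L_nm) ** 3
    N = params.to_nm3(rho0_mgml) * V
    if N < 1:
        return "inhibited"
    system = CanonicalSystem(N=max(int(round(N)), 1), V=V)
    sp = stationary_points(finite_size_profile(params, system, n_points=64))
    return "stable" if sp.profile_class == "two_stationary" else "inhibited"


def boundary_box_length(
    params: ThermoParams,
    rho0_mgml: float,
    L_bounds_nm: tuple[float, float] = (5.0, 2000.0),
) -> float | None:
    """Box length at which the profile has a single stationary flex point.

    At fixed supersaturated density, increasing the volume flips the
    profile from monotonic (confinement-inhibited) to two-stationary;
    the boundary is located by bisection on the minimum of dF/dn over
    n, treating N = rho0 * V as continuous.
    """
    if rho0_mgml <= params.rho_d_star_mgml:
        return None
    rho0 = params.to_nm3(rho0_mgml)

    def min_deriv(L):
        V = L**3
        system = CanonicalSystem(N=max(int(np.ceil(rho0 * V)), 2), V=V)
        # continuous N: rebuild with exact float N via a light shim
        object.__setattr__(system, "N", rho0 * V)
        n_hi = min(system.N * (1 - 1e-9), 0.999 * params.rho_c_nm3 * V)
        res = minimize_scalar(
            lambda n: _dF_dn_finite(n, params, system),
            bounds=(1e-6, n_hi), method="bounded", options={"xatol": 1e-10},
        )
        return res.fun

    lo, hi = L_bounds_nm
    f_lo, f_hi = min_deriv(lo), min_deriv(hi)
    if f_lo < 0:  # already stable at the smallest box
        return lo
    if f_hi > 0:  # never stabilizes in range
        return None
    return float(brentq(min_deriv, lo, hi, xtol=1e-6))


def stability_diagram(params: ThermoParams, rho0_grid_mgml, L_grid_nm) -> "pd.DataFrame":
    """Region labels over a (density, box length) grid plus the boundary.

    Returns a long-format DataFrame (rho0_mgml, L_nm, region); the
    boundary curve is available via :func:`boundary_box_length`.
    """
    import pandas as pd

    rows = [
        dict(rho0_mgml=float(rho0), L_nm=float(L),
             region=classify_condition(params, float(rho0), float(L)))
        for rho0 in np.asarray(rho0_grid_mgml, dtype=float)
        for L in np.asarray(L_grid_nm, dtype=float)
    ]
    return pd.DataFrame(rows)
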