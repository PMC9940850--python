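"""Two-state Markov-state model of chain exchange between phases.

Each chain is labeled condensed (member of the largest droplet, by the
same geometric criterion used for droplet detection) or dilute in every
frame.  Transition counts at a chosen lag, pooled over chains, give a
2x2 row-stochastic transition matrix per droplet-size bin; the escape
rate is the inverse mean first passage time of the condensed-to-dilute
transition, which for a two-state chain is k_cd = p_cd / (lag * dt)
with p_cd the per-lag exit probability.  Uncertainty comes from a
Jeffreys (Beta(1/2, 1/2)) posterior on the exit probability.

The module also fits the approximately exponential decay of the escape
rate with droplet size and checks the balance relation between the
rate ratio k_cd/k_dc and the dilute/condensed population ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .detect import ClusterCriteria, detect_clusters

__all__ = [
    "StateTrajectory",
    "RateEstimate",
    "ExpFit",
    "assign_states",
    "estimate_rates",
    "fit_exponential_decay",
    "rate_ratio_balance",
    "implied_timescale_check",
]

CONDENSED, DILUTE = 1, 0


@dataclass
class StateTrajectory:
    """Per-chain condensed/dilute label matrix over frames."""

    states: np.ndarray             # (n_frames, n_chains) in {0, 1}
    frame_interval: float          # ns between frames
    droplet_size_series: np.ndarray  # (n_frames,) largest-cluster size

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        self.droplet_size_series = np.asarray(self.droplet_size_series)
        if len(self.droplet_size_series) != self.states.shape[0]:
            raise ValueError("droplet_size_series length must match frames")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_chains(self) -> int:
        return self.states.shape[1]


@dataclass
class RateEstimate:
    """Per-size-bin exchange rates [1/us]; rate = 1/MFPT at the lag."""

    k_cd: float
    k_dc: float
    size_bin: tuple[float, float]
    n_cd_transitions: int
    n_dc_transitions: int
    lag: int
    ci_cd: tuple[float, float] = (np.nan, np.nan)
    ci_dc: tuple[float, float] = (np.nan, np.nan)
    k_cd_is_upper_bound: bool = False
    k_dc_is_upper_bound: bool = False


@dataclass
class ExpFit:
    """Exponential decay k(n) = prefactor * exp(-decay_constant * n)."""

    prefactor: float          # 1/us
    decay_constant: float     # per chain
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))


def assign_states(
    frames,
    chain_of_bead: np.ndarray,
    criteria: ClusterCriteria = ClusterCriteria(),
    frame_interval: float = 1.0,
) -> StateTrajectory:
    """Label every chain condensed/dilute per frame.

    A chain is condensed iff it belongs to the largest detected
    cluster; frames without any cluster leave all chains dilute.
    """
    chain_of_bead = np.asarray(chain_of_bead, dtype=int)
    n_chains = int(chain_of_bead.max()) + 1
    states, sizes = [], []
    for frame in frames:
        coords, box = (
            (frame.coordinates, frame.box_length)
            if hasattr(frame, "coordinates") else frame
        )
        assign = detect_clusters(coords, box, chain_of_bead, criteria)
        row = np.zeros(n_chains, dtype=np.int8)
        row[assign.largest_members] = CONDENSED
        states.append(row)
        sizes.append(assign.largest_size)
    return StateTrajectory(
        states=np.array(states), frame_interval=frame_interval,
        droplet_size_series=np.array(sizes),
    )


def _rate_from_counts(n_exit: int, n_stay: int, lag_time_us: float):
    """Exit rate [1/us] and Jeffreys 95% CI from pooled transition counts.

    For a two-state Markov chain, MFPT(out) = lag / p_exit, so
    k = p_exit / lag_time.  With no observed exits the rate is the
    Jeffreys upper bound (flagged by the caller).
    """
    n_tot = n_exit + n_stay
    if n_tot == 0:
        return np.nan, (np.nan, np.nan)
    p = n_exit / n_tot
    lo, hi = beta_dist.ppf([0.025, 0.975], 0.5 + n_exit, 0.5 + n_stay)
    return p / lag_time_us, (lo / lag_time_us, hi / lag_time_us)


def estimate_rates(
    traj: StateTrajectory,
    lag: int = 1,
    size_bins: int | list = 5,
    min_transitions: int = 10,
) -> list[RateEstimate]:
    """Exchange rates per droplet-size bin at the given lag (sliding
    window counting).

    ``size_bins`` is either a number of quantile bins over the droplet
    size series or an explicit list of bin edges.  Bins with fewer than
    ``min_transitions`` observed exits report the Jeffreys upper bound
    and are flagged.
    """
    if lag < 1 or lag >= traj.n_frames:
        raise ValueError("lag must be in [1, n_frames)")
    sizes = traj.droplet_size_series[:-lag].astype(float)
    if isinstance(size_bins, int):
        qs = np.linspace(0, 1, size_bins + 1)
        edges = np.unique(np.quantile(sizes, qs))
        if len(edges) < 2:
            edges = np.array([sizes.min() - 0.5, sizes.max() + 0.5])
    else:
        edges = np.asarray(size_bins, dtype=float)
    which = np.clip(np.digitize(sizes, edges[1:-1]), 0, len(edges) - 2)

    s0 = traj.states[:-lag]          # (n_pairs, n_chains)
    s1 = traj.states[lag:]
    lag_time_us = lag * traj.frame_interval * 1e-3
    out = []
    for b in range(len(edges) - 1):
        rows = which == b
        if not np.any(rows):
            continue
        a, z = s0[rows].ravel(), s1[rows].ravel()
        n_cd = int(np.sum((a == CONDENSED) & (z == DILUTE)))
        n_cc = int(np.sum((a == CONDENSED) & (z == CONDENSED)))
        n_dc = int(np.sum((a == DILUTE) & (z == CONDENSED)))
        n_dd = int(np.sum((a == DILUTE) & (z == DILUTE)))
        k_cd, ci_cd = _rate_from_counts(n_cd, n_cc, lag_time_us)
        k_dc, ci_dc = _rate_from_counts(n_dc, n_dd, lag_time_us)
        est = RateEstimate(
            k_cd=k_cd, k_dc=k_dc, size_bin=(edges[b], edges[b + 1]),
            n_cd_transitions=n_cd, n_dc_transitions=n_dc, lag=lag,
            ci_cd=ci_cd, ci_dc=ci_dc,
            k_cd_is_upper_bound=n_cd < min_transitions,
            k_dc_is_upper_bound=n_dc < min_transitions,
        )
        if est.k_cd_is_upper_bound and n_cd == 0:
            est.k_cd = ci_cd[1]
        if est.k_dc_is_upper_bound and n_dc == 0:
            est.k_dc = ci_dc[1]
        out.append(est)
    return out


def fit_exponential_decay(sizes, rates) -> ExpFit:
    """Least-squares fit of ln k against droplet size.

    Non-positive or non-finite rates are excluded with a warning; at
    least three usable points are required.
    """
    sizes = np.asarray(sizes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    ok = np.isfinite(rates) & (rates > 0)
    if np.any(~ok):
        warnings.warn(f"excluding {int(np.sum(~ok))} non-positive/non-finite rates")
    if np.sum(ok) < 3:
        raise ValueError("need >= 3 finite positive rates")
    x, y = sizes[ok], np.log(rates[ok])
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (intercept + slope * x)
    return ExpFit(
        prefactor=float(np.exp(intercept)),
        decay_constant=float(-slope),
        residuals=resid,
    )


def rate_ratio_balance(traj: StateTrajectory, lag: int = 1, n_windows: int = 10):
    """Paired series of (k_cd/k_dc, N_dilute/N_condensed) over time
    windows, with the slope/intercept of their regression.

    At equilibrium detailed balance for the pooled two-state model
    implies k_cd/k_dc = N_d/N_c, so the points fall on the parity line.
    Windows where either phase is empty are dropped; if more than half
    are dropped the analysis is rejected.
    """
    n_pairs = traj.n_frames - lag
    bounds = np.linspace(0, n_pairs, n_windows + 1, dtype=int)
    s0, s1 = traj.states[:-lag], traj.states[lag:]
    lag_time_us = lag * traj.frame_interval * 1e-3
    rate_ratio, pop_ratio = [], []
    dropped = 0
    for w in range(n_windows):
        sl = slice(bounds[w], bounds[w + 1])
        a, z = s0[sl].ravel(), s1[sl].ravel()
        n_c = np.sum(a == CONDENSED)
        n_d = np.sum(a == DILUTE)
        if n_c == 0 or n_d == 0:
            dropped += 1
            continue
        k_cd, _ = _rate_from_counts(
            int(np.sum((a == CONDENSED) & (z == DILUTE))),
            int(np.sum((a == CONDENSED) & (z == CONDENSED))), lag_time_us)
        k_dc, _ = _rate_from_counts(
            int(np.sum((a == DILUTE) & (z == CONDENSED))),
            int(np.sum((a == DILUTE) & (z == DILUTE))), lag_time_us)
        if not (np.isfinite(k_cd) and np.isfinite(k_dc)) or k_dc == 0:
            dropped += 1
            continue
        rate_ratio.append(k_cd / k_dc)
        pop_ratio.append(n_d / n_c)
    if dropped > n_windows / 2:
        raise ValueError("one phase empty in most windows; balance undefined")
    x = np.asarray(pop_ratio)
    y = np.asarray(rate_ratio)
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return dict(
        rate_ratio=y, population_ratio=x,
        slope=float(slope), intercept=float(intercept),
    )


def implied_timescale_check(traj: StateTrajectory, lags=(1, 2, 5)) -> dict[int, float]:
    """Implied relaxation timescale t = -lag*dt/ln(lambda_2) at several
    lags; flat values indicate Markovian state assignments."""
    out = {}
    for lag in lags:
        if lag >= traj.n_frames:
            continue
        a = traj.states[:-lag].ravel()
        z = traj.states[lag:].ravel()
        T = np.zeros((2, 2))
        for s in (0, 1):
            sel = a == s
            if not np.any(sel):
                T[s, s] = 1.0
                continue
            T[s, 1] = np.mean(z[sel] == 1)
            T[s, 0] = 1.0 - T[s, 1]
        lam2 = np.linalg.eigvals(T)
        lam2 = np.sort(np.real(lam2))[0]
        dt_us = lag * traj.frame_interval * 1e-3
        out[lag] = float(-dt_us / np.log(lam2)) if 0 < lam2 < 1 else np.inf
    return out
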