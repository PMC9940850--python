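"""Planted-ground-truth generators for testing the analysis stack.

Three kinds of fixtures, all deterministic given a seed and carrying
their ground truth alongside the data:

* droplet-plus-vapor bead configurations at a prescribed core density
  (for the droplet detector and density profiling);
* observation tables produced by the forward Kelvin model from known
  (sigma, rho_d*) -- the noiseless inverse problem for the global fit;
* per-chain two-state telegraph-process time series with known
  exchange rates (for the Markov-state analysis).

Chains are freely jointed random walks (bond length 0.38 nm): cheap,
and sufficient for geometric detector tests; no attempt is made to
emulate equilibrated conformations or interfacial structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kelvin import TABLE_COLUMNS, predict_nss
from .msm import StateTrajectory
from .simulate import SimulationState, _random_walk_chain
from .thermo import CanonicalSystem, ThermoParams
from .units import DA_PER_NM3_TO_MG_PER_ML

__all__ = [
    "PlantedConfiguration",
    "make_droplet_configuration",
    "make_observation_table",
    "make_telegraph_states",
    "TABLE1_DESIGN",
]

#: The (L [nm], N) design grid used for synthetic observation tables:
#: four box sizes, three loadings each, as in the finite-size
#: simulation campaign the fit is designed for.
TABLE1_DESIGN = [
    (40, 25), (40, 35), (40, 50),
    (50, 49), (50, 69), (50, 98),
    (60, 84), (60, 118), (60, 169),
    (70, 133), (70, 187), (70, 268),
]


@dataclass
class PlantedConfiguration:
    """A droplet-plus-vapor configuration with its ground truth."""

    state: SimulationState
    droplet_members: np.ndarray    # chain indices planted in the sphere
    droplet_radius: float          # nm
    rho_core_mgml: float           # planted core mass density
    bead_masses: np.ndarray


def make_droplet_configuration(
    n_in: int,
    n_out: int,
    rho_c_target_mgml: float,
    box_length: float,
    chain_length: int = 20,
    bead_mass: float = 110.0,
    seed: int = 0,
    bond_length: float = 0.38,
    vapor_margin: float = 6.0,
    link_distance: float = 1.5,
) -> PlantedConfiguration:
    """Plant ``n_in`` chains in a central sphere at a target mass
    density and ``n_out`` chains in the remaining volume.

    The sphere radius is chosen so that n_in chains inside it realize
    ``rho_c_target_mgml`` exactly; chain centers are uniform in the
    sphere, which keeps the core density unbiased.  Because a random
    placement can strand a chain at the sphere edge without neighbors,
    chains outside the single-linkage component at ``link_distance``
    are resampled (seeded, deterministic) until the planted droplet is
    connected -- so any contact criterion with cutoff >= link_distance
    recovers the planted membership exactly.  Vapor chain centers keep
    ``vapor_margin`` nm clearance from the sphere surface.
    """
    from scipy.sparse.csgraph import connected_components

    from .detect import ClusterCriteria, _contact_graph

    rng = np.random.default_rng(seed)
    chain_mass = chain_length * bead_mass
    volume_needed = n_in * chain_mass * DA_PER_NM3_TO_MG_PER_ML / rho_c_target_mgml
    radius = (3.0 * volume_needed / (4.0 * np.pi)) ** (1.0 / 3.0)
    if radius + vapor_margin > box_length / 2.0 and n_out > 0:
        raise ValueError("droplet sphere plus vapor margin does not fit in the box")
    if radius > box_length / 2.0:
        raise ValueError("droplet sphere does not fit in the box")
    center = np.full(3, box_length / 2.0)

    def droplet_chain():
        while True:
            p = rng.uniform(-1.0, 1.0, 3)
            if p @ p <= 1.0:
                break
        com = center + p * radius
        chain = _random_walk_chain(chain_length, bond_length, rng)
        return com + (chain - chain.mean(axis=0))

    chains = [droplet_chain() for _ in range(n_in)]
    # connectivity repair: resample chains stranded outside the giant
    # single-linkage component of the planted droplet
    if n_in > 1:
        link = ClusterCriteria(contact_cutoff=link_distance)
        cob_in = np.repeat(np.arange(n_in), chain_length)
        for _ in range(200):
            graph = _contact_graph(
                np.vstack(chains), box_length, cob_in, link
            )
            _, comp = connected_components(graph, directed=False)
            counts = np.bincount(comp)
            giant = int(np.argmax(counts))
            stranded = np.nonzero(comp != giant)[0]
            if len(stranded) == 0:
                break
            for c in stranded:
                chains[c] = droplet_chain()
        else:
            raise RuntimeError("could not connect the planted droplet")

    for _ in range(n_out):
        while True:
            com = rng.uniform(0.0, box_length, 3)
            if np.linalg.norm(com - center) > radius + vapor_margin:
                break
        chain = _random_walk_chain(chain_length, bond_length, rng)
        chains.append(com + (chain - chain.mean(axis=0)))

    state = SimulationState(
        coordinates=np.vstack(chains) % box_length,
        box_length=box_length,
        chain_of_bead=np.repeat(np.arange(n_in + n_out), chain_length),
    )
    return PlantedConfiguration(
        state=state,
        droplet_members=np.arange(n_in),
        droplet_radius=radius,
        rho_core_mgml=rho_c_target_mgml,
        bead_masses=np.full(len(state.chain_of_bead), float(bead_mass)),
    )


def make_observation_table(
    sigma0_mN_per_m: float,
    rho_d_star0_mgml: float,
    rho_c_mgml: float,
    chain_mass_da: float,
    design=None,
    noise_frac: float = 0.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> pd.DataFrame:
    """Forward-model an observation table from known thermodynamics.

    n_ss per (L, N) condition comes from the Kelvin stationarity
    solver, multiplied by (1 + Gaussian noise truncated at 3 sigma);
    conditions without a stable root are flagged ``none`` (the
    no-phase-separation outcome).  The generating parameters are
    attached as ``DataFrame.attrs['truth']``.
    """
    rng = np.random.default_rng(seed)
    design = TABLE1_DESIGN if design is None else design
    params = ThermoParams(
        sigma_mN_per_m=sigma0_mN_per_m,
        rho_d_star_mgml=rho_d_star0_mgml,
        rho_c_mgml=rho_c_mgml,
        chain_mass_da=chain_mass_da,
        temperature=temperature,
    )
    rows = []
    for i, (L, N) in enumerate(design):
        system = CanonicalSystem.from_box_length(int(N), float(L))
        rho0_nm3 = N / system.V
        rho0_mgml = rho0_nm3 * chain_mass_da * DA_PER_NM3_TO_MG_PER_ML
        nss = predict_nss(params, system)
        if nss is None:
            rows.append(dict(zip(
                TABLE_COLUMNS,
                [f"synthetic-{i + 1}", L, N, rho0_nm3, rho0_mgml,
                 np.nan, np.nan, "none"],
            )))
            continue
        noise = np.clip(rng.normal(0.0, 1.0), -3.0, 3.0) * noise_frac
        nss_obs = nss * (1.0 + noise)
        rows.append(dict(zip(
            TABLE_COLUMNS,
            [f"synthetic-{i + 1}", L, N, rho0_nm3, rho0_mgml,
             nss_obs, abs(nss) * max(noise_frac, 1e-12), "stable"],
        )))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table.attrs["truth"] = dict(
        sigma_mN_per_m=sigma0_mN_per_m, rho_d_star_mgml=rho_d_star0_mgml,
        rho_c_mgml=rho_c_mgml, chain_mass_da=chain_mass_da, seed=seed,
        noise_frac=noise_frac,
    )
    return table


def make_telegraph_states(
    n_chains: int,
    n_frames: int,
    k_cd: float,
    k_dc: float,
    frame_interval: float = 1.0,
    seed: int = 0,
    droplet_size_series: np.ndarray | None = None,
) -> StateTrajectory:
    """Independent two-state telegraph chains with known rates.

    Per-frame switching probabilities are p_cd = k_cd * dt and
    p_dc = k_dc * dt (rates in 1/us, dt = frame_interval in ns), which
    requires rate * dt < 1.  Chains start from the stationary
    distribution (condensed with probability k_dc/(k_cd + k_dc)).
    Ground truth is attached as ``traj.truth``.
    """
    dt_us = frame_interval * 1e-3
    p_cd, p_dc = k_cd * dt_us, k_dc * dt_us
    if not (0 <= p_cd < 1 and 0 <= p_dc < 1):
        raise ValueError("rates too fast for the frame interval")
    rng = np.random.default_rng(seed)
    pi_c = k_dc / (k_cd + k_dc) if (k_cd + k_dc) > 0 else 1.0
    states = np.empty((n_frames, n_chains), dtype=np.int8)
    states[0] = (rng.random(n_chains) < pi_c).astype(np.int8)
    u = rng.random((n_frames - 1, n_chains))
    for t in range(1, n_frames):
        prev = states[t - 1]
        flip_prob = np.where(prev == 1, p_cd, p_dc)
        states[t] = np.where(u[t - 1] < flip_prob, 1 - prev, prev)
    if droplet_size_series is None:
        droplet_size_series = states.sum(axis=1)
    traj = StateTrajectory(
        states=states, frame_interval=frame_interval,
        droplet_size_series=droplet_size_series,
    )
    traj.truth = dict(k_cd=k_cd, k_dc=k_dc, seed=seed)
    return traj
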