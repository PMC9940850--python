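"""Droplet identification and characterization in periodic configurations.

Droplets are found with a two-stage geometric criterion: (1) chains
are linked whenever they share at least ``min_contacts`` interchain
bead-bead contacts within ``contact_cutoff`` (minimum image), and
clusters are the connected components of that contact graph
(single linkage); (2) the assignment is refined by reassigning to the
dilute phase any chain whose center of mass lies farther than
``com_cutoff`` from its cluster's center of mass.  Centers of mass in
the periodic box are computed with per-axis circular means, which is
robust to droplets crossing the boundaries.

On trajectories the module measures the steady-state droplet size
(time average of the largest cluster after an equilibration window,
with a block-average standard error), radial mass-density profiles
about the droplet center, the condensed-phase density rho_c from the
profile core, and the gyration-tensor asphericity of the droplet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .units import DA_PER_NM3_TO_MG_PER_ML

__all__ = [
    "ClusterCriteria",
    "ClusterAssignment",
    "RadialProfile",
    "DropletObservation",
    "detect_clusters",
    "steady_state_size",
    "radial_density_profile",
    "estimate_rho_c",
    "asphericity",
    "periodic_com",
]


@dataclass(frozen=True)
class ClusterCriteria:
    """Two-stage droplet criterion.

    com_cutoff = None uses an adaptive cutoff of twice the cluster's
    radius of gyration.
    """

    contact_cutoff: float = 1.0       # nm
    min_contacts: int = 1
    com_cutoff: float | None = None   # nm; None -> 2 x cluster Rg

    def __post_init__(self):
        if self.contact_cutoff <= 0 or self.min_contacts < 1:
            raise ValueError("criteria must be positive")
        if self.com_cutoff is not None and self.com_cutoff <= 0:
            raise ValueError("com_cutoff must be positive")


@dataclass
class ClusterAssignment:
    """Per-chain cluster ids; 0 means dilute, clusters are numbered
    from 1 in decreasing size order."""

    labels: np.ndarray
    largest_size: int

    @property
    def largest_members(self) -> np.ndarray:
        return np.nonzero(self.labels == 1)[0]


@dataclass
class RadialProfile:
    bin_centers: np.ndarray    # nm
    density_mgml: np.ndarray
    density_nm3: np.ndarray    # bead number density
    droplet_com: np.ndarray    # nm


@dataclass
class DropletObservation:
    """One steady-state measurement in Table-style layout."""

    N: int
    V: float                  # nm^3
    n_ss: float
    n_err: float
    outcome_flag: str         # "stable" | "fluctuating" | "none"
    n_frames: int = 0


def periodic_com(coords: np.ndarray, box: float, weights=None) -> np.ndarray:
    """Center of mass under periodic boundaries via circular means.

    Each axis is mapped onto a unit circle; the angular mean is mapped
    back, which keeps a cluster that straddles a boundary intact.
    """
    if weights is None:
        weights = np.ones(len(coords))
    w = np.asarray(weights, dtype=float)
    theta = coords * (2.0 * np.pi / box)
    sin = np.average(np.sin(theta), axis=0, weights=w)
    cos = np.average(np.cos(theta), axis=0, weights=w)
    ang = np.arctan2(-sin, -cos) + np.pi  # in [0, 2 pi)
    return ang * box / (2.0 * np.pi)


def _min_image(dr: np.ndarray, box: float) -> np.ndarray:
    return dr - box * np.round(dr / box)


def _contact_graph(coords, box, chain_of_bead, criteria: ClusterCriteria):
    """Chain-chain adjacency from bead-bead contacts (periodic KD-tree)."""
    wrapped = coords % box
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(criteria.contact_cutoff, output_type="ndarray")
    n_chains = int(chain_of_bead.max()) + 1 if len(chain_of_bead) else 0
    if len(pairs) == 0:
        return coo_matrix((n_chains, n_chains))
    ci = chain_of_bead[pairs[:, 0]]
    cj = chain_of_bead[pairs[:, 1]]
    inter = ci != cj
    ci, cj = ci[inter], cj[inter]
    lo, hi = np.minimum(ci, cj), np.maximum(ci, cj)
    counts = coo_matrix(
        (np.ones(len(lo)), (lo, hi)), shape=(n_chains, n_chains)
    ).tocsr()
    counts.data = (counts.data >= criteria.min_contacts).astype(float)
    counts.eliminate_zeros()
    return counts


def detect_clusters(
    coords: np.ndarray,
    box: float,
    chain_of_bead: np.ndarray,
    criteria: ClusterCriteria = ClusterCriteria(),
) -> ClusterAssignment:
    """Assign chains to condensed clusters (label >= 1) or dilute (0)."""
    chain_of_bead = np.asarray(chain_of_bead, dtype=int)
    n_chains = int(chain_of_bead.max()) + 1 if len(chain_of_bead) else 0
    if n_chains == 0:
        return ClusterAssignment(labels=np.zeros(0, dtype=int), largest_size=0)
    graph = _contact_graph(coords, box, chain_of_bead, criteria)
    n_comp, comp = connected_components(graph, directed=False)

    wrapped = coords % box
    labels = np.zeros(n_chains, dtype=int)
    sizes = np.bincount(comp, minlength=n_comp)
    cluster_ids = [c for c in range(n_comp) if sizes[c] >= 2]

    # stage 2: COM-distance refinement
    for c in cluster_ids:
        chains = np.nonzero(comp == c)[0]
        mask = np.isin(chain_of_bead, chains)
        com = periodic_com(wrapped[mask], box)
        d_beads = np.linalg.norm(_min_image(wrapped[mask] - com, box), axis=1)
        rg = np.sqrt(np.mean(d_beads**2))
        cutoff = criteria.com_cutoff if criteria.com_cutoff is not None else 2.0 * rg
        for ch in chains:
            ch_mask = chain_of_bead == ch
            ch_com = periodic_com(wrapped[ch_mask], box)
            if np.linalg.norm(_min_image(ch_com - com, box)) <= cutoff:
                labels[ch] = c + 1  # provisional id
    # renumber: singletons dilute, clusters by decreasing size
    final = np.zeros(n_chains, dtype=int)
    kept = [
        (np.sum(labels == c + 1), c + 1)
        for c in cluster_ids
        if np.sum(labels == c + 1) >= 2
    ]
    for rank, (_, old) in enumerate(sorted(kept, reverse=True), start=1):
        final[labels == old] = rank
    largest = int(np.sum(final == 1))
    return ClusterAssignment(labels=final, largest_size=largest)


def _block_error(series: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean from contiguous block averages."""
    n = len(series) // n_blocks
    if n < 1:
        raise ValueError("too few frames for blocking")
    blocks = series[: n * n_blocks].reshape(n_blocks, n).mean(axis=1)
    return float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))


def steady_state_size(
    largest_series: np.ndarray,
    N: int,
    V: float,
    equilibration_fraction: float = 0.5,
    n_blocks: int = 5,
    min_droplet: int = 5,
    fluct_rel_err: float = 0.25,
    multi_series: np.ndarray | None = None,
) -> DropletObservation:
    """Average steady-state droplet size with block-average error.

    ``largest_series`` is the per-frame largest-cluster size (use
    :func:`detect_clusters` over a trajectory); the first
    ``equilibration_fraction`` of frames is discarded.  Outcome flags:
    ``none`` when the largest cluster stays below ``min_droplet`` in
    >= 90% of frames; ``fluctuating`` when the relative block error
    exceeds ``fluct_rel_err`` or (optionally, via ``multi_series`` =
    per-frame count of clusters >= min_droplet) several droplets
    coexist in >= 25% of frames; otherwise ``stable``.
    """
    series = np.asarray(largest_series, dtype=float)
    start = int(len(series) * equilibration_fraction)
    prod = series[start:]
    if len(prod) < n_blocks:
        raise ValueError("too few post-equilibration frames for blocking")
    mean = float(prod.mean())
    err = _block_error(prod, n_blocks)
    if np.mean(prod < min_droplet) >= 0.9:
        flag = "none"
    elif (mean > 0 and err / mean > fluct_rel_err) or (
        multi_series is not None
        and np.mean(np.asarray(multi_series[start:]) >= 2) >= 0.25
    ):
        flag = "fluctuating"
    else:
        flag = "stable"
    return DropletObservation(
        N=N, V=V, n_ss=mean, n_err=err, outcome_flag=flag, n_frames=len(prod)
    )


def radial_density_profile(
    frames,
    chain_of_bead: np.ndarray,
    bead_masses: np.ndarray,
    criteria: ClusterCriteria = ClusterCriteria(),
    bin_width: float = 0.5,
    min_detection_fraction: float = 0.5,
) -> RadialProfile:
    """Spherically averaged mass-density profile about the droplet COM.

    ``frames`` iterates over (coords, box) pairs or SimulationState
    objects.  Frames without a detectable droplet are skipped; if more
    than half are skipped the profile is rejected.
    """
    chain_of_bead = np.asarray(chain_of_bead, dtype=int)
    histo = None
    n_used = n_total = 0
    box_ref = None
    com_last = None
    for frame in frames:
        coords, box = (
            (frame.coordinates, frame.box_length)
            if hasattr(frame, "coordinates") else frame
        )
        n_total += 1
        box_ref = box
        assign = detect_clusters(coords, box, chain_of_bead, criteria)
        if assign.largest_size < 2:
            continue
        mask = np.isin(chain_of_bead, assign.largest_members)
        wrapped = coords % box
        com = periodic_com(wrapped[mask], box, bead_masses[mask])
        com_last = com
        r = np.linalg.norm(_min_image(wrapped - com, box), axis=1)
        if histo is None:
            n_bins = int((box / 2.0) / bin_width)
            edges = np.arange(n_bins + 1) * bin_width
            histo = np.zeros(n_bins)
        h, _ = np.histogram(r, bins=edges, weights=bead_masses)
        histo += h
        n_used += 1
    if n_total == 0 or n_used / n_total < min_detection_fraction:
        raise ValueError(
            f"droplet detected in only {n_used}/{n_total} frames; profile rejected"
        )
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_da_nm3 = histo / n_used / shell_vol
    centers = 0.5 * (edges[1:] + edges[:-1])
    mean_mass = float(np.mean(bead_masses))
    return RadialProfile(
        bin_centers=centers,
        density_mgml=rho_da_nm3 * DA_PER_NM3_TO_MG_PER_ML,
        density_nm3=rho_da_nm3 / mean_mass,
        droplet_com=com_last,
    )


def estimate_rho_c(profile: RadialProfile, core_radius_fraction: float = 0.5):
    """Condensed-phase density [mg/mL] from the profile core.

    The core is the set of shells within ``core_radius_fraction`` of
    the half-density radius (where the profile first falls below half
    its inner plateau).  Peak and half radius are located on a
    volume-weighted 3-bin moving average -- the innermost shells are
    tiny and Poisson-noisy, so the raw profile can spike there -- and
    the returned estimate is the volume-weighted mean of the raw
    profile over the core (= core mass / core volume).  A profile
    without a plateau-then-decay shape is reported with a warning
    rather than rejected.
    """
    rho = profile.density_mgml
    if np.all(rho <= 0):
        return 0.0
    centers = profile.bin_centers
    width = centers[1] - centers[0] if len(centers) > 1 else 2.0 * centers[0]
    edges = np.concatenate([[max(centers[0] - width / 2, 0.0)], centers + width / 2])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    smooth = np.array(
        [
            np.average(rho[max(0, i - 1):i + 2],
                       weights=shell_vol[max(0, i - 1):i + 2])
            for i in range(len(rho))
        ]
    )
    peak_idx = int(np.argmax(smooth))
    half_idx = None
    for i in range(peak_idx + 1, len(rho)):
        if smooth[i] < 0.5 * smooth[peak_idx]:
            half_idx = i
            break
    if half_idx is None:
        warnings.warn("no half-density radius found; profile may lack a plateau")
        half_idx = len(rho)
    r_half = centers[min(half_idx, len(rho) - 1)]
    core = centers <= core_radius_fraction * r_half
    if not np.any(core):
        core = np.zeros_like(core)
        core[0] = True
    return float(np.average(rho[core], weights=shell_vol[core]))


def asphericity(coords: np.ndarray, box: float, chain_of_bead: np.ndarray,
                assignment: ClusterAssignment, cluster: int = 1) -> float:
    """Normalized gyration-tensor asphericity of a droplet.

    b = (l1 - (l2 + l3)/2) / (l1 + l2 + l3) with l1 >= l2 >= l3 the
    gyration-tensor eigenvalues; 0 for a sphere, 1 for a line.
    """
    members = np.nonzero(assignment.labels == cluster)[0]
    mask = np.isin(np.asarray(chain_of_bead), members)
    if np.sum(mask) < 2:
        raise ValueError("cluster has fewer than 2 beads")
    wrapped = coords[mask] % box
    com = periodic_com(wrapped, box)
    rel = _min_image(wrapped - com, box)
    gyr = rel.T @ rel / len(rel)
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    return float((lam[0] - 0.5 * (lam[1] + lam[2])) / lam.sum())
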