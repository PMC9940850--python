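"""Readers and writers for the package's file formats.

Canonical outputs are CSV (tables, profiles) and JSON (fit reports);
all physical columns carry explicit units in their names.  Trajectories
can be exchanged either through a dependency-free whitespace format
(``frame chain bead x y z`` per line, one ``# box <L> <time_ns>``
header per frame) or through GRO/XTC via MDAnalysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DropletObservation, RadialProfile
from .kelvin import TABLE_COLUMNS, FitResult
from .simulate import SimulationState

__all__ = [
    "read_observation_table",
    "write_observation_table",
    "observation_row",
    "packaged_table",
    "write_profile_csv",
    "read_profile_csv",
    "write_fit_report",
    "read_fit_report",
    "write_text_trajectory",
    "read_text_trajectory",
    "write_gro",
    "write_xtc",
    "read_md_trajectory",
]

_DATA_DIR = Path(__file__).parent / "data"


def packaged_table(protein: str) -> pd.DataFrame:
    """Load one of the packaged finite-size observation tables
    ('NDDX4' or 'FUS-LC')."""
    key = protein.strip().upper().replace("_", "-")
    path = _DATA_DIR / f"{key.lower().replace('-', '_')}_observations.csv"
    if not path.exists():
        raise FileNotFoundError(f"no packaged table for {protein!r}")
    return read_observation_table(path)


def read_observation_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return table


def write_observation_table(table: pd.DataFrame, path, metadata: dict | None = None):
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        table.to_csv(fh, index=False)


def observation_row(system_id: str, L_nm: float, obs: DropletObservation,
                    rho0_mgml: float, rho0_nm3: float) -> pd.DataFrame:
    """Render one droplet observation as a single-row table."""
    return pd.DataFrame(
        [[system_id, L_nm, obs.N, rho0_nm3, rho0_mgml, obs.n_ss, obs.n_err,
          obs.outcome_flag]],
        columns=TABLE_COLUMNS,
    )


def write_profile_csv(profile: RadialProfile, path):
    pd.DataFrame(
        {"r_nm": profile.bin_centers, "rho_mgml": profile.density_mgml,
         "rho_nm3": profile.density_nm3}
    ).to_csv(path, index=False)


def read_profile_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit_report(result: FitResult, path, extra: dict | None = None):
    report = result.to_dict()
    report["residuals"] = result.residuals.to_dict(orient="records")
    if extra:
        report.update(extra)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)


def read_fit_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# trajectories


def write_text_trajectory(frames, path):
    """Whitespace trajectory: per frame a ``# box L time`` header then
    ``frame chain bead x y z`` lines."""
    with open(path, "w") as fh:
        for f_idx, frame in enumerate(frames):
            fh.write(f"# box {frame.box_length:.6f} {frame.time:.6f}\n")
            for b, (c, xyz) in enumerate(
                zip(frame.chain_of_bead, frame.coordinates)
            ):
                fh.write(
                    f"{f_idx} {c} {b} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                )


def read_text_trajectory(path) -> list[SimulationState]:
    frames = []
    box = time = None
    coords, chains = [], []

    def flush():
        if coords:
            frames.append(
                SimulationState(
                    coordinates=np.asarray(coords),
                    box_length=box,
                    chain_of_bead=np.asarray(chains, dtype=int),
                    time=time,
                )
            )

    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "#":
                flush()
                coords, chains = [], []
                box, time = float(parts[2]), float(parts[3])
                continue
            chains.append(int(parts[1]))
            coords.append([float(parts[3]), float(parts[4]), float(parts[5])])
    flush()
    return frames


def write_gro(state: SimulationState, path, name: str = "CG condensate"):
    """Single-frame GRO file (one 'GLY CA' pseudo-atom per bead)."""
    n = len(state.chain_of_bead)
    with open(path, "w") as fh:
        fh.write(f"{name}, t= {state.time:.3f}\n{n}\n")
        for i, (c, xyz) in enumerate(zip(state.chain_of_bead, state.coordinates)):
            fh.write(
                f"{(int(c) + 1) % 100000:>5d}GLY"
                f"{'CA':>7s}{(i + 1) % 100000:>5d}"
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n"
            )
        L = state.box_length
        fh.write(f"{L:10.5f}{L:10.5f}{L:10.5f}\n")


def write_xtc(frames, path, gro_path=None):
    """Write an XTC trajectory (requires MDAnalysis); optionally also a
    matching single-frame GRO topology."""
    import MDAnalysis as mda

    frames = list(frames)
    first = frames[0]
    n = len(first.chain_of_bead)
    u = mda.Universe.empty(n, trajectory=True)
    u.dimensions = [first.box_length * 10] * 3 + [90, 90, 90]
    if gro_path is not None:
        write_gro(first, gro_path)
    with mda.Writer(str(path), n) as wr:
        for frame in frames:
            u.atoms.positions = frame.coordinates * 10.0  # nm -> A
            u.dimensions = [frame.box_length * 10] * 3 + [90, 90, 90]
            wr.write(u.atoms)


def read_md_trajectory(topology, trajectory=None, chain_of_bead=None):
    """Read GRO (+ optional XTC) into SimulationState frames via
    MDAnalysis; coordinates come back in nm.

    chain_of_bead overrides the residue-id-based chain map.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(
        str(topology), str(trajectory)
    )
    if chain_of_bead is None:
        chain_of_bead = u.atoms.resids - u.atoms.resids.min()
    frames = []
    for ts in u.trajectory:
        frames.append(
            SimulationState(
                coordinates=u.atoms.positions / 10.0,
                box_length=float(ts.dimensions[0]) / 10.0,
                chain_of_bead=np.asarray(chain_of_bead, dtype=int),
                time=float(ts.time) / 1000.0,
            )
        )
    return frames
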