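"""One-bead-per-residue coarse-grained potential for disordered proteins.

Each residue is a single bead.  Consecutive beads are connected by a
harmonic bond (r0 = 0.38 nm, k = 1000 kJ/mol/nm^2).  Charged residues
interact through a Debye-Hueckel screened Coulomb potential (screening
length 1 nm, roughly 100 mM ionic strength).  Short-range contacts are
12-6 Lennard-Jones with a stickers-and-spacers energy scale: Arg, Phe,
Tyr, Trp and Gln are stickers, everything else is a spacer, and the
pair well depths obey eps(St-St) = 1.5 eps(St-Sp) = 3 eps(Sp-Sp).  The
absolute sticker-sticker scale is the model's single free parameter.

The per-residue LJ diameters shipped here are a stand-in taken from
the widely used hydropathy-scale (HPS) one-bead-per-residue convention
(van der Waals diameters of the residues); they are overridable from a
delimited text table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ResidueParams",
    "ForceFieldConfig",
    "ChainTopology",
    "STICKER_RESIDUES",
    "classify_stickers",
    "default_residue_table",
    "load_residue_table",
    "build_topology",
    "topologies_from_fasta",
    "bond_energy",
    "debye_huckel_energy",
    "lj_energy",
    "total_energy",
    "total_forces",
]

#: Sticker residues (one-letter codes): large aromatic/planar side chains.
STICKER_RESIDUES = frozenset("RFYWQ")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# one-letter code -> (sigma_nm [HPS stand-in], charge e, mass Da)
_DEFAULT_TABLE = {
    "A": (0.504, 0, 71.08), "R": (0.656, +1, 156.19), "N": (0.568, 0, 114.10),
    "D": (0.558, -1, 115.09), "C": (0.548, 0, 103.14), "Q": (0.602, 0, 128.13),
    "E": (0.592, -1, 129.12), "G": (0.450, 0, 57.05), "H": (0.608, 0, 137.14),
    "I": (0.618, 0, 113.16), "L": (0.618, 0, 113.16), "K": (0.636, +1, 128.17),
    "M": (0.618, 0, 131.19), "F": (0.636, 0, 147.18), "P": (0.556, 0, 97.12),
    "S": (0.518, 0, 87.08), "T": (0.562, 0, 101.10), "W": (0.678, 0, 186.21),
    "Y": (0.646, 0, 163.18), "V": (0.586, 0, 99.13),
}


@dataclass(frozen=True)
class ResidueParams:
    """Per-residue bead parameters."""

    name: str          # one-letter code
    sigma_lj: float    # nm
    epsilon_class: str  # "sticker" | "spacer"
    charge: float      # elementary charges
    mass: float        # Da

    def __post_init__(self):
        if self.sigma_lj <= 0:
            raise ValueError("sigma_lj must be positive")
        if self.epsilon_class not in ("sticker", "spacer"):
            raise ValueError("epsilon_class must be 'sticker' or 'spacer'")


@dataclass(frozen=True)
class ForceFieldConfig:
    """Global force-field settings.

    eps_stst is the absolute sticker-sticker LJ well depth [kJ/mol] --
    the single free energy scale of the model; the mixed and
    spacer-spacer depths are eps_stst/1.5 and eps_stst/3 exactly.
    """

    eps_stst: float = 1.0
    debye_length: float = 1.0          # nm
    lj_cutoff: float = 2.0             # nm
    coulomb_cutoff: float = 3.5        # nm
    dielectric_prefactor: float = 138.935458 / 80.0  # kJ/mol nm e^-2, water
    bond_r0: float = 0.38              # nm
    bond_k: float = 1.0e3              # kJ/mol/nm^2

    def __post_init__(self):
        if self.eps_stst <= 0 or self.debye_length <= 0:
            raise ValueError("eps_stst and debye_length must be positive")

    def eps_pair(self, class_i: str, class_j: str) -> float:
        n_st = (class_i == "sticker") + (class_j == "sticker")
        return self.eps_stst / (1.0, 1.5, 3.0)[2 - n_st]


@dataclass(frozen=True)
class ChainTopology:
    """Bead parameters and bonds of one chain."""

    sequence: str
    bead_params: tuple[ResidueParams, ...]
    bond_list: tuple[tuple[int, int], ...]
    chain_mass: float

    def __len__(self) -> int:
        return len(self.bead_params)


def _normalize_code(code: str, position: int) -> str:
    c = code.upper()
    if len(c) == 3:
        if c not in _THREE_TO_ONE:
            raise ValueError(f"unknown residue code {code!r} at position {position}")
        return _THREE_TO_ONE[c]
    if len(c) == 1 and c in _DEFAULT_TABLE:
        return c
    raise ValueError(f"unknown residue code {code!r} at position {position}")


def classify_stickers(sequence) -> list[str]:
    """Label each residue 'sticker' or 'spacer'.

    Stickers are Arg, Phe, Tyr, Trp and Gln; unknown codes are
    rejected with the offending position.
    """
    seq = list(sequence) if not isinstance(sequence, str) else list(sequence)
    out = []
    for i, code in enumerate(seq):
        one = _normalize_code(code, i)
        out.append("sticker" if one in STICKER_RESIDUES else "spacer")
    return out


def default_residue_table() -> dict[str, ResidueParams]:
    """Built-in residue table (HPS-convention diameters as a stand-in;
    D/E carry -1, K/R +1, His neutral)."""
    return {
        code: ResidueParams(
            name=code, sigma_lj=sig,
            epsilon_class="sticker" if code in STICKER_RESIDUES else "spacer",
            charge=float(q), mass=m,
        )
        for code, (sig, q, m) in _DEFAULT_TABLE.items()
    }


def load_residue_table(path) -> dict[str, ResidueParams]:
    """Read a residue table from delimited text
    (columns: residue, sigma_nm, charge, mass_Da)."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    table = {}
    for _, row in df.iterrows():
        code = _normalize_code(str(row["residue"]).strip(), -1)
        table[code] = ResidueParams(
            name=code, sigma_lj=float(row["sigma_nm"]),
            epsilon_class="sticker" if code in STICKER_RESIDUES else "spacer",
            charge=float(row["charge"]), mass=float(row["mass_da"]),
        )
    return table


def build_topology(sequence: str, residue_table=None) -> ChainTopology:
    """Build a linear chain topology from a protein sequence."""
    table = residue_table or default_residue_table()
    beads = []
    for i, code in enumerate(sequence):
        one = _normalize_code(code, i)
        if one not in table:
            raise ValueError(f"residue {code!r} at position {i} missing from table")
        beads.append(table[one])
    bonds = tuple((i, i + 1) for i in range(len(beads) - 1))
    return ChainTopology(
        sequence="".join(b.name for b in beads),
        bead_params=tuple(beads),
        bond_list=bonds,
        chain_mass=float(sum(b.mass for b in beads)),
    )


def topologies_from_fasta(path, residue_table=None) -> dict[str, ChainTopology]:
    """Build one topology per record of a FASTA file."""
    from Bio import SeqIO

    return {
        rec.id: build_topology(str(rec.seq), residue_table)
        for rec in SeqIO.parse(str(path), "fasta")
    }


# ---------------------------------------------------------------------------
# pair potentials


def bond_energy(r, config: ForceFieldConfig = ForceFieldConfig()):
    """Harmonic bond energy 0.5 k (r - r0)^2 [kJ/mol]."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    return 0.5 * config.bond_k * (r - config.bond_r0) ** 2


def debye_huckel_energy(r, qi, qj, config: ForceFieldConfig = ForceFieldConfig()):
    """Screened Coulomb energy: pref * qi qj exp(-r/lambda_D)/r [kJ/mol],
    zero beyond the Coulomb cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    e = config.dielectric_prefactor * qi * qj * np.exp(-r / config.debye_length) / r
    return np.where(r <= config.coulomb_cutoff, e, 0.0)


def lj_energy(r, params_i: ResidueParams, params_j: ResidueParams,
              config: ForceFieldConfig = ForceFieldConfig()):
    """12-6 Lennard-Jones with class-mixed well depth and
    Lorentz (arithmetic-mean) diameters, truncated at the LJ cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    sig = 0.5 * (params_i.sigma_lj + params_j.sigma_lj)
    eps = config.eps_pair(params_i.epsilon_class, params_j.epsilon_class)
    sr6 = (sig / r) ** 6
    return np.where(r <= config.lj_cutoff, 4.0 * eps * (sr6 * sr6 - sr6), 0.0)


# ---------------------------------------------------------------------------
# system energy / forces (minimum-image periodic cubic box)


class SystemTopology:
    """Flattened per-bead arrays for a set of chains, built once."""

    def __init__(self, topologies: list[ChainTopology]):
        sigma, charge, sticker, mass, chain_of_bead, bonds = [], [], [], [], [], []
        offset = 0
        for c, top in enumerate(topologies):
            for b in top.bead_params:
                sigma.append(b.sigma_lj)
                charge.append(b.charge)
                sticker.append(b.epsilon_class == "sticker")
                mass.append(b.mass)
                chain_of_bead.append(c)
            bonds.extend((i + offset, j + offset) for i, j in top.bond_list)
            offset += len(top)
        self.sigma = np.asarray(sigma)
        self.charge = np.asarray(charge)
        self.is_sticker = np.asarray(sticker, dtype=bool)
        self.mass = np.asarray(mass)
        self.chain_of_bead = np.asarray(chain_of_bead, dtype=int)
        self.bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
        self.n_beads = offset
        self.n_chains = len(topologies)


def _pair_list(coords: np.ndarray, box: float, cutoff: float):
    """Candidate pairs within cutoff (minimum image).

    Uses a cell-linked list when the box accommodates >= 3 cells per
    side, otherwise falls back to all pairs -- identical results, the
    cell list only prunes.
    """
    n = len(coords)
    n_cells = int(box // cutoff)
    # vectorized all-pairs beats the Python cell loop below ~10^3 beads
    if n_cells < 3 or n < 1000:
        iu, ju = np.triu_indices(n, k=1)
        return iu, ju
    cell_size = box / n_cells
    idx = np.floor(coords / cell_size).astype(int) % n_cells
    flat = (idx[:, 0] * n_cells + idx[:, 1]) * n_cells + idx[:, 2]
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    starts = np.searchsorted(sorted_flat, np.arange(n_cells**3))
    ends = np.searchsorted(sorted_flat, np.arange(n_cells**3), side="right")

    neigh_offsets = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    )
    pairs_i, pairs_j = [], []
    for cx in range(n_cells):
        for cy in range(n_cells):
            for cz in range(n_cells):
                c = (cx * n_cells + cy) * n_cells + cz
                mine = order[starts[c]:ends[c]]
                if len(mine) == 0:
                    continue
                for dx, dy, dz in neigh_offsets:
                    nc = (
                        ((cx + dx) % n_cells) * n_cells + ((cy + dy) % n_cells)
                    ) * n_cells + ((cz + dz) % n_cells)
                    if nc < c:
                        continue
                    other = order[starts[nc]:ends[nc]]
                    if nc == c:
                        ii, jj = np.meshgrid(mine, mine, indexing="ij")
                        mask = ii < jj
                        pairs_i.append(ii[mask]); pairs_j.append(jj[mask])
                    else:
                        ii, jj = np.meshgrid(mine, other, indexing="ij")
                        pairs_i.append(ii.ravel()); pairs_j.append(jj.ravel())
    if not pairs_i:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(pairs_i), np.concatenate(pairs_j)


def _min_image(dr: np.ndarray, box: float) -> np.ndarray:
    return dr - box * np.round(dr / box)


def _nonbonded_terms(coords, box, st: SystemTopology, config: ForceFieldConfig,
                     with_forces: bool):
    cutoff = max(config.lj_cutoff, config.coulomb_cutoff)
    if box < 2.0 * cutoff:
        raise ValueError(
            f"box ({box} nm) smaller than twice the largest cutoff ({cutoff} nm)"
        )
    iu, ju = _pair_list(coords % box, box, cutoff)
    if len(iu) == 0:
        z = np.zeros_like(coords)
        return 0.0, z
    # exclude directly bonded (1-2) pairs
    if len(st.bonds):
        nb = st.n_beads
        sorted_bonds = np.sort(st.bonds, axis=1)
        bond_keys = sorted_bonds[:, 0].astype(np.int64) * nb + sorted_bonds[:, 1]
        pair_keys = np.minimum(iu, ju).astype(np.int64) * nb + np.maximum(iu, ju)
        keep = ~np.isin(pair_keys, bond_keys)
        iu, ju = iu[keep], ju[keep]
    dr = _min_image(coords[iu] - coords[ju], box)
    r2 = np.einsum("ij,ij->i", dr, dr)
    within = r2 <= cutoff * cutoff
    iu, ju, dr, r2 = iu[within], ju[within], dr[within], r2[within]
    # clamp to avoid 0/0 at exact overlaps; the resulting huge finite
    # force is handled by the integrator's displacement cap
    r = np.maximum(np.sqrt(r2), 1e-4)

    energy = 0.0
    forces = np.zeros_like(coords) if with_forces else None

    # LJ
    lj_mask = r <= config.lj_cutoff
    if np.any(lj_mask):
        i, j, rr = iu[lj_mask], ju[lj_mask], r[lj_mask]
        sig = 0.5 * (st.sigma[i] + st.sigma[j])
        n_st = st.is_sticker[i].astype(int) + st.is_sticker[j].astype(int)
        eps = config.eps_stst / np.array([3.0, 1.5, 1.0])[n_st]
        sr6 = (sig / rr) ** 6
        energy += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
        if with_forces:
            # dU/dr = 4 eps (-12 sr12 + 6 sr6)/r ; force on i along +dr
            dudr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / rr
            fvec = -(dudr / rr)[:, None] * dr[lj_mask]
            np.add.at(forces, i, fvec)
            np.add.at(forces, j, -fvec)

    # Debye-Hueckel
    qq = st.charge[iu] * st.charge[ju]
    dh_mask = (r <= config.coulomb_cutoff) & (qq != 0.0)
    if np.any(dh_mask):
        i, j, rr = iu[dh_mask], ju[dh_mask], r[dh_mask]
        q = qq[dh_mask]
        lam = config.debye_length
        e = config.dielectric_prefactor * q * np.exp(-rr / lam) / rr
        energy += float(np.sum(e))
        if with_forces:
            dudr = -e * (1.0 / rr + 1.0 / lam)
            fvec = -(dudr / rr)[:, None] * dr[dh_mask]
            np.add.at(forces, i, fvec)
            np.add.at(forces, j, -fvec)
    return energy, forces


def _bonded_terms(coords, box, st: SystemTopology, config: ForceFieldConfig,
                  with_forces: bool):
    if len(st.bonds) == 0:
        return 0.0, (np.zeros_like(coords) if with_forces else None)
    i, j = st.bonds[:, 0], st.bonds[:, 1]
    dr = _min_image(coords[i] - coords[j], box)
    r = np.linalg.norm(dr, axis=1)
    energy = float(np.sum(0.5 * config.bond_k * (r - config.bond_r0) ** 2))
    forces = None
    if with_forces:
        forces = np.zeros_like(coords)
        dudr = config.bond_k * (r - config.bond_r0)
        fvec = -(dudr / r)[:, None] * dr
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)
    return energy, forces


def total_energy(coords: np.ndarray, box: float, system_top: SystemTopology,
                 config: ForceFieldConfig = ForceFieldConfig()) -> float:
    """Total potential energy [kJ/mol] of a periodic configuration.

    Bonded + Debye-Hueckel + Lennard-Jones with minimum-image
    convention; 1-2 bonded pairs are excluded from the nonbonded sums.
    """
    e_b, _ = _bonded_terms(coords, box, system_top, config, False)
    e_nb, _ = _nonbonded_terms(coords, box, system_top, config, False)
    return e_b + e_nb


def total_forces(coords: np.ndarray, box: float, system_top: SystemTopology,
                 config: ForceFieldConfig = ForceFieldConfig()):
    """Analytic forces [kJ/mol/nm], returned with the total energy."""
    e_b, f_b = _bonded_terms(coords, box, system_top, config, True)
    e_nb, f_nb = _nonbonded_terms(coords, box, system_top, config, True)
    return e_b + e_nb, f_b + f_nb
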