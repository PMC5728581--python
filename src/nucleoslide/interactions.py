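"""Non-bonded histone-DNA energy terms and the contact-count observable.

Three pieces:

* a purely repulsive r^-12 excluded volume between protein and DNA
  beads, with per-kind radii rescaled by 1.1;
* Debye-Hueckel screened electrostatics with a temperature- and
  salt-dependent dielectric.  Phosphates carry -0.6e when interacting
  with other DNA charges (counter-ion condensation) but -1.0e when
  interacting with protein charges; the two interaction classes are
  evaluated separately so no bead state is mutated;
* the salt-titration observable: the number of phosphate groups within
  a cutoff (default 12 A) of the globular histone core.

Energies are returned in kBT at ``params.temperature``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import units
from .errors import GeometryError

DEFAULT_CONTACT_CUTOFF = 12.0  # Angstrom (1.2 nm)
DEFAULT_EXV_EPSILON_KCAL = 0.2  # kcal/mol; generic repulsion scale


@dataclass
class InteractionParams:
    """Parameters of the non-bonded terms."""

    ionic_strength: float = 0.2           # mol/L monovalent
    temperature: float = units.DEFAULT_TEMPERATURE  # K
    dna_dna_phosphate_charge: float = -0.6   # e
    protein_dna_phosphate_charge: float = -1.0  # e
    exv_epsilon: float = units.kcal_mol_to_kbt(DEFAULT_EXV_EPSILON_KCAL)  # kBT
    radius_scale: float = 1.1
    permittivity_model: str = "empirical"    # or "constant"
    permittivity_constant: float = 78.0

    def __post_init__(self):
        if self.ionic_strength <= 0:
            raise ValueError("ionic strength must be positive")
        if self.radius_scale <= 0:
            raise ValueError("radius_scale must be positive")
        if self.permittivity_model not in ("empirical", "constant"):
            raise ValueError("permittivity_model must be 'empirical' or 'constant'")

    @property
    def eps_r(self) -> float:
        if self.permittivity_model == "constant":
            return self.permittivity_constant
        return units.permittivity_empirical(self.temperature, self.ionic_strength)


@dataclass(frozen=True)
class ContactCount:
    cutoff: float
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be non-negative")


def _split_indices(structure):
    prot = np.array(sorted(
        i for c in structure.protein_chains for i in structure.chains[c]), dtype=int)
    dna = np.array(sorted(
        i for c in structure.dna_chains for i in structure.chains[c]), dtype=int)
    return prot, dna


def excluded_volume(structure, params: InteractionParams, positions=None,
                    term_floor: float = 1e-12) -> float:
    """Protein-DNA r^-12 repulsion in kBT.

    E = sum over protein-DNA pairs of eps_ev * (sigma_ij / r_ij)^12 with
    sigma_ij = radius_scale * (R_i + R_j) / 2.  Pairs where the term
    falls below ``term_floor`` are skipped via a neighbour search.
    """
    pos = structure.positions if positions is None else positions
    prot, dna = _split_indices(structure)
    if prot.size == 0 or dna.size == 0:
        return 0.0
    radii = structure.radii
    sig_max = params.radius_scale * (radii[prot].max() + radii[dna].max()) / 2.0
    cutoff = np.inf if term_floor <= 0 else sig_max * term_floor ** (-1.0 / 12.0)
    t_prot = cKDTree(pos[prot])
    t_dna = cKDTree(pos[dna])
    pairs = t_prot.query_ball_tree(t_dna, cutoff)
    energy = 0.0
    for a, neigh in enumerate(pairs):
        if not neigh:
            continue
        i = prot[a]
        j = dna[np.asarray(neigh, dtype=int)]
        r = np.linalg.norm(pos[j] - pos[i], axis=1)
        if np.any(r == 0):
            raise GeometryError("coincident protein and DNA beads (r = 0)")
        sig = params.radius_scale * (radii[i] + radii[j]) / 2.0
        energy += np.sum((sig / r) ** 12)
    return float(params.exv_epsilon * energy)


def _dh_pair_sum(pos_i, q_i, pos_j, q_j, lb, lam, same_set=False) -> float:
    """Screened-Coulomb double sum; with same_set=True counts i<j once."""
    total = 0.0
    for a in range(len(pos_i)):
        start = a + 1 if same_set else 0
        d = pos_j[start:] - pos_i[a]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0):
            raise GeometryError("coincident charges (r = 0)")
        total += q_i[a] * np.sum(q_j[start:] * np.exp(-r / lam) / r)
    return lb * total


def debye_huckel(structure, params: InteractionParams, positions=None,
                 include_dna_dna: bool = True) -> float:
    """Debye-Hueckel electrostatic energy in kBT.

    Protein-DNA pairs use the -1.0e phosphate charge, DNA-DNA pairs the
    condensed -0.6e charge.  Protein beads use their stored charges.
    Only phosphates carry DNA charge.
    """
    pos = structure.positions if positions is None else positions
    eps_r = params.eps_r
    lb = units.bjerrum_length(params.temperature, eps_r)
    lam = units.debye_length(params.temperature, eps_r, params.ionic_strength)
    charges = structure.charges
    prot, _ = _split_indices(structure)
    prot = prot[charges[prot] != 0]
    p_idx = np.array(structure.all_phosphates, dtype=int)
    energy = 0.0
    if prot.size and p_idx.size:
        q_p = np.full(p_idx.size, params.protein_dna_phosphate_charge)
        energy += _dh_pair_sum(pos[prot], charges[prot], pos[p_idx], q_p, lb, lam)
    if prot.size > 1:
        energy += _dh_pair_sum(pos[prot], charges[prot], pos[prot], charges[prot],
                               lb, lam, same_set=True)
    if include_dna_dna and p_idx.size > 1:
        q_d = np.full(p_idx.size, params.dna_dna_phosphate_charge)
        energy += _dh_pair_sum(pos[p_idx], q_d, pos[p_idx], q_d, lb, lam,
                               same_set=True)
    return float(energy)


def count_contacts(structure, cutoff: float = DEFAULT_CONTACT_CUTOFF,
                   positions=None) -> ContactCount:
    """Phosphates within ``cutoff`` of any non-tail histone core bead.

    Linker phosphates are included when they fall inside the cutoff.
    """
    pos = structure.positions if positions is None else positions
    core = np.array(sorted(structure.histone_core), dtype=int)
    if core.size == 0:
        raise GeometryError("histone core is empty")
    p_idx = np.array(structure.all_phosphates, dtype=int)
    tree = cKDTree(pos[core])
    dmin, _ = tree.query(pos[p_idx], k=1)
    return ContactCount(cutoff=float(cutoff), count=int(np.sum(dmin <= cutoff)))


def titration_curve(ensemble, cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    burn_in_frames: int = 0) -> pd.DataFrame:
    """Mean contact count (with standard error) per salt condition.

    ``ensemble`` maps salt concentration (mol/L) to a Trajectory or a
    list of Trajectories.  ``burn_in_frames`` frames are discarded from
    the start of every trajectory.  SE is over the pooled frames and is
    NaN when only one frame survives.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    rows = []
    for salt in sorted(ensemble):
        trajs = ensemble[salt]
        if hasattr(trajs, "topology"):
            trajs = [trajs]
        counts = []
        for traj in trajs:
            for xyz in traj.coords[burn_in_frames:]:
                counts.append(count_contacts(traj.topology, cutoff, xyz).count)
        if not counts:
            raise ValueError(f"no frames left for salt {salt} after burn-in")
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts)) if len(counts) > 1 else np.nan
        rows.append({"salt": salt, "mean_contacts": counts.mean(),
                     "se_contacts": se, "n_frames": len(counts)})
    return pd.DataFrame(rows)
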