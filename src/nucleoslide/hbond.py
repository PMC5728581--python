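"""Sliding-invariant coarse-grained histone-DNA hydrogen-bond potential.

Each native hydrogen bond is defined by a protein CA donor and reference
geometry (r0, theta0, phi0) measured in a reference structure.  At
evaluation time every bond is scored against *all* DNA phosphates:

    V_hb = -eps * sum_i sum_j f(r_ij - r0_i) g(th_ij - th0_i) g(ph_ij - ph0_i)

so the potential is invariant under a rotation-coupled (screw-like)
repositioning of the DNA — a slid phosphate is replaced by the next one
with identical relative geometry.  ``f`` is a narrow Gaussian in the
donor-phosphate distance and ``g`` a compactly supported angular window,
which makes each bond specific to a single phosphate and avoids double
counting against neighbouring phosphates.

The raw non-negative inner sum for bond *i* is exposed as that bond's
*occupancy* (1 for a perfectly formed bond); the energy applies the
attractive sign so a formed bond contributes -eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError, TopologyError

DEFAULT_EPSILON = 1.2   # kBT; validated stability range is roughly 1.2-2.4 kBT
DEFAULT_SIGMA = 1.0     # Angstrom
DEFAULT_DELTA_PHI = 10.0  # degrees


def f_dist(dr, sigma: float = DEFAULT_SIGMA):
    """Gaussian distance factor exp(-(dr/sigma)^2); 1 at dr=0."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    dr = np.asarray(dr, dtype=float)
    return np.exp(-(dr / sigma) ** 2)


def g_ang(dphi, delta_phi: float = DEFAULT_DELTA_PHI):
    """Angular window: 1 inside ±delta_phi, smooth ramp to 0 at ±2*delta_phi.

    On the ramp the value is 1 - cos^2(pi*dphi/(2*delta_phi)); the
    function is continuous everywhere and has compact support.
    """
    if delta_phi <= 0:
        raise ValueError("delta_phi must be positive")
    d = np.abs(np.asarray(dphi, dtype=float))
    out = np.zeros_like(d)
    out[d <= delta_phi] = 1.0
    ramp = (d > delta_phi) & (d <= 2 * delta_phi)
    out[ramp] = 1.0 - np.cos(np.pi * d[ramp] / (2.0 * delta_phi)) ** 2
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class HBondSpec:
    """One native hydrogen bond: donor residue and reference geometry."""

    donor: tuple  # (chain_id, residue_index) of the HB-forming CA bead
    r0: float     # Angstrom
    theta0: float  # degrees
    phi0: float    # degrees

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        for a in (self.theta0, self.phi0):
            if not 0.0 <= a <= 180.0:
                raise ValueError("reference angles must lie in [0, 180] degrees")


@dataclass
class HBondModel:
    """A native-bond list with global potential parameters."""

    bonds: list = field(default_factory=list)
    epsilon: float = DEFAULT_EPSILON
    sigma: float = DEFAULT_SIGMA
    delta_phi: float = DEFAULT_DELTA_PHI

    def __post_init__(self):
        if self.sigma <= 0 or self.delta_phi <= 0 or self.epsilon < 0:
            raise ValueError("require sigma > 0, delta_phi > 0, epsilon >= 0")

    def with_epsilon(self, epsilon: float) -> "HBondModel":
        return HBondModel(bonds=list(self.bonds), epsilon=epsilon,
                          sigma=self.sigma, delta_phi=self.delta_phi)


@dataclass(frozen=True)
class BondGeometry:
    r_ij: float
    theta_ij: float
    phi_ij: float


def _angle_deg(u, v) -> float:
    """Unsigned angle between two vectors in degrees."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("zero-length vector in angle computation")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _donor_frame(structure, donor, positions):
    """Donor CA position and the neighbour vector CA_{i-1} -> CA_{i+1}."""
    chain, resid = donor
    try:
        i_d = structure.bead_index(chain, resid, "CA")
    except KeyError:
        raise GeometryError(f"donor {donor} not found") from None
    if structure.beads[i_d].flexible_tail:
        raise TopologyError(
            f"donor {donor} is on a flexible tail; tails are excluded "
            "from the hydrogen-bond machinery"
        )
    try:
        i_m = structure.bead_index(chain, resid - 1, "CA")
        i_p = structure.bead_index(chain, resid + 1, "CA")
    except KeyError:
        raise GeometryError(
            f"donor {donor} lacks a chain neighbour; terminal residues "
            "cannot form an evaluable bond"
        ) from None
    return positions[i_d], positions[i_p] - positions[i_m]


def bond_geometry(structure, donor, p_index, positions=None) -> BondGeometry:
    """Measure (r, theta, phi) for one donor/phosphate pair.

    * r: donor CA to phosphate distance,
    * theta: angle between CA->P and the donor's neighbour vector
      CA_{i-1} -> CA_{i+1},
    * phi: angle at the phosphate between the donor CA and the sugar
      bead of the same nucleotide.
    """
    pos = structure.positions if positions is None else positions
    if hasattr(donor, "donor"):
        donor = donor.donor
    ca, nvec = _donor_frame(structure, donor, pos)
    p = pos[p_index]
    try:
        s = pos[structure.sugar_of_phosphate(p_index)]
    except KeyError:
        raise GeometryError(
            f"phosphate bead {p_index} has no sugar in its nucleotide"
        ) from None
    r = float(np.linalg.norm(p - ca))
    theta = _angle_deg(p - ca, nvec)
    phi = _angle_deg(ca - p, s - p)
    return BondGeometry(r_ij=r, theta_ij=theta, phi_ij=phi)


def extract_hbond_model(refs, hb_pairs, epsilon=DEFAULT_EPSILON,
                        sigma=DEFAULT_SIGMA, delta_phi=DEFAULT_DELTA_PHI,
                        symmetrize: bool = True) -> HBondModel:
    """Build an HBondModel from native donor/phosphate pairs.

    Parameters
    ----------
    refs
        One reference structure or a sequence of (typically two)
        reference structures.
    hb_pairs
        Iterable of ``((donor_chain, donor_resid), phosphate)`` where
        ``phosphate`` is ``(chain, resid)`` of the bonded nucleotide.
    symmetrize
        When a reference declares ``symmetric_pairs``, average the
        geometry over the two symmetric copies of each histone as well
        as over the reference structures; each listed donor still gets
        its own HBondSpec (with the group-mean geometry).

    Bonds found in only a subset of the references are kept with the
    mean over the available copies.  Tail donors are rejected.
    """
    if hasattr(refs, "beads"):
        refs = [refs]
    refs = list(refs)
    if not refs:
        raise ValueError("need at least one reference structure")

    # canonical donor key under the symmetry pairing of each reference
    def canon(ref, donor):
        if not symmetrize:
            return donor
        try:
            i = ref.bead_index(donor[0], donor[1], "CA")
        except KeyError:
            return donor
        for a, b in ref.symmetric_pairs:
            if i in (a, b):
                j = min(a, b)
                bead = ref.beads[j]
                return (bead.chain_id, bead.residue_index)
        return donor

    samples: dict[tuple, list[BondGeometry]] = {}
    donors_listed: list[tuple] = []
    donor_group: dict[tuple, tuple] = {}
    for donor, phosphate in hb_pairs:
        donor = tuple(donor)
        if donor not in donor_group:
            donors_listed.append(donor)
        found = False
        for ref in refs:
            try:
                p_idx = ref.bead_index(phosphate[0], phosphate[1], "P")
            except KeyError:
                continue
            geom = bond_geometry(ref, donor, p_idx)
            key = canon(ref, donor)
            donor_group[donor] = key
            samples.setdefault(key, []).append(geom)
            found = True
        if not found and donor not in donor_group:
            donor_group[donor] = donor
        if not found:
            raise KeyError(
                f"bond ({donor}, {phosphate}) not found in any reference"
            )

    bonds = []
    for donor in donors_listed:
        geoms = samples[donor_group[donor]]
        bonds.append(HBondSpec(
            donor=donor,
            r0=float(np.mean([g.r_ij for g in geoms])),
            theta0=float(np.mean([g.theta_ij for g in geoms])),
            phi0=float(np.mean([g.phi_ij for g in geoms])),
        ))
    return HBondModel(bonds=bonds, epsilon=epsilon, sigma=sigma,
                      delta_phi=delta_phi)


def hb_energy(structure, model: HBondModel, positions=None,
              cutoff_sigmas: float = 6.0):
    """Total hydrogen-bond energy (kBT) and per-bond occupancies.

    The phosphate sum runs over both DNA strands.  Phosphates farther
    than ``r0 + cutoff_sigmas*sigma`` from a donor contribute less than
    1e-15 to the Gaussian factor and are skipped.
    """
    pos = structure.positions if positions is None else positions
    p_idx = np.array(structure.all_phosphates, dtype=int)
    if p_idx.size == 0:
        raise TopologyError("structure has no phosphate beads")
    p_pos = pos[p_idx]
    s_pos = np.empty_like(p_pos)
    for k, pi in enumerate(p_idx):
        s_pos[k] = pos[structure.sugar_of_phosphate(int(pi))]
    tree = cKDTree(p_pos)

    occupancies = np.zeros(len(model.bonds))
    for i, bond in enumerate(model.bonds):
        ca, nvec = _donor_frame(structure, bond.donor, pos)
        cand = tree.query_ball_point(ca, bond.r0 + cutoff_sigmas * model.sigma)
        if not cand:
            continue
        cand = np.asarray(cand, dtype=int)
        dp = p_pos[cand] - ca          # CA -> P
        r = np.linalg.norm(dp, axis=1)
        nn = nvec / np.linalg.norm(nvec)
        cth = np.clip(dp @ nn / r, -1.0, 1.0)
        theta = np.degrees(np.arccos(cth))
        ds = s_pos[cand] - p_pos[cand]  # P -> S
        dc = -dp                        # P -> CA
        num = np.einsum("ij,ij->i", ds, dc)
        den = np.linalg.norm(ds, axis=1) * r
        phi = np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))
        occupancies[i] = np.sum(
            f_dist(r - bond.r0, model.sigma)
            * g_ang(theta - bond.theta0, model.delta_phi)
            * g_ang(phi - bond.phi0, model.delta_phi)
        )
    total = -model.epsilon * occupancies.sum()
    return total, occupancies


# ---------------------------------------------------------------------
# TSV interchange for bond lists
# ---------------------------------------------------------------------

HB_TSV_COLUMNS = ["donor_chain", "donor_resid", "r0", "theta0", "phi0"]


def write_hbond_tsv(model: HBondModel, path) -> None:
    rows = [{
        "donor_chain": b.donor[0], "donor_resid": b.donor[1],
        "r0": f"{b.r0:.4f}", "theta0": f"{b.theta0:.4f}", "phi0": f"{b.phi0:.4f}",
    } for b in model.bonds]
    pd.DataFrame(rows, columns=HB_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hbond_tsv(path, epsilon=DEFAULT_EPSILON, sigma=DEFAULT_SIGMA,
                   delta_phi=DEFAULT_DELTA_PHI) -> HBondModel:
    df = pd.read_csv(path, sep="\t", comment="#")
    bonds = [HBondSpec(donor=(str(r.donor_chain), int(r.donor_resid)),
                       r0=float(r.r0), theta0=float(r.theta0), phi0=float(r.phi0))
             for r in df.itertuples()]
    return HBondModel(bonds=bonds, epsilon=epsilon, sigma=sigma, delta_phi=delta_phi)
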