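"""Idealized nucleosome fixtures with analytically known ground truth.

The generator builds a kinematic stand-in for a crystal-derived
nucleosome: DNA beads laid on an ideal superhelical path (straight
tangent linkers at both ends), pseudo-histone hydrogen-bond donor sites
at the half-integer superhelical locations, and a pseudo-histone core
whose centroid sits exactly on the superhelix axis.  Because every
quantity of the construction is known in closed form, the analysis
coordinates and the sliding-invariant hydrogen-bond potential can be
validated against exact expectations.

Key idealizations (documented, all configurable):

* DNA twist is exactly 10.0 bp/turn so a screw-like advance of 1 bp
  rotates the tracked phosphate by exactly 36 degrees;
* the two strands' beads sit on diametrically opposite spokes of the
  DNA tube (grooves are not modelled), which makes the structure an
  exact C2-symmetric bead set;
* the pseudo-histone core consists of 14 donor triplets, a scaffold
  chain tracing the wrapped DNA centerline, and azimuthally mirrored
  copies of both (rotated by 180 degrees about the superhelix axis).
  The mirrored copies balance the core's center of geometry onto the
  superhelix axis, so the rotation coordinate of a jump-like (phase
  preserving) trajectory is constant by construction.

Trajectories are kinematic: a screw event advances the base-pair
register along the fixed spatial path (positions of the path never
move), a jump event advances the register while holding the rotational
phase, and a loop event propagates a bulge defect stage by stage across
the wrap.  No forces are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NucleoslideError, WindowError
from .structures import Bead, CGStructure, SequenceConstruct, Trajectory

DEG = np.pi / 180.0


@dataclass(frozen=True)
class SuperhelixSpec:
    """Geometry of the ideal superhelical nucleosome fixture.

    Lengths in Angstrom.  ``dna_twist`` is in bp per helical turn; the
    default 10.0 (rather than the physical ~10.17) gives closed-form
    rotation-coupling expectations.  ``path_margin`` is the number of
    extra path slots reserved beyond each DNA end so the register can
    slide without falling off the path.
    """

    n_wrapped_bp: int = 147
    radius: float = 41.9        # superhelix radius
    pitch: float = 25.9         # superhelix rise per superhelical turn
    dna_twist: float = 10.0     # bp per DNA helical turn
    dna_radius: float = 9.4     # phosphate distance from the DNA axis
    linker_bp: int = 38
    rise: float = 3.4           # path length per bp
    path_margin: int = 15
    sugar_radius: float = 7.0
    base_radius: float = 2.5
    donor_offset: float = 5.0   # donor CA distance inward of its phosphate
    hb_shl_max: float = 6.5     # donors at +-0.5 ... +-hb_shl_max
    phase0_deg: float = 90.0    # strand-1 phase at the dyad; 90 makes the
                                # C2 rotation swap the two strands exactly

    def __post_init__(self):
        for name in ("radius", "pitch", "dna_twist", "dna_radius", "rise",
                     "sugar_radius", "base_radius", "donor_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_wrapped_bp < 31 or self.linker_bp < 0 or self.path_margin < 0:
            raise ValueError("bad bp counts in superhelix spec")
        if self.wrapped_turns > 2.0:
            raise NucleoslideError(
                f"{self.n_wrapped_bp} wrapped bp make {self.wrapped_turns:.2f} "
                "superhelical turns; the single-path construction supports <= 2"
            )

    @property
    def delta_alpha(self) -> float:
        """Superhelical angle advanced per bp (radians)."""
        c = self.pitch / (2.0 * np.pi)
        return self.rise / np.hypot(self.radius, c)

    @property
    def wrapped_turns(self) -> float:
        return self.n_wrapped_bp * self.delta_alpha / (2.0 * np.pi)

    @property
    def total_bp(self) -> int:
        return self.n_wrapped_bp + 2 * self.linker_bp

    @property
    def dyad_bp(self) -> int:
        return (self.total_bp - 1) // 2

    @property
    def bp_per_superhelix_turn(self) -> float:
        return 2.0 * np.pi / self.delta_alpha


def _path_frame(spec: SuperhelixSpec, s: float):
    """Path point and orthonormal frame (e1 radial-out, e2, tangent) at
    slot offset ``s`` from the dyad; straight tangents beyond the wrap."""
    half = (spec.n_wrapped_bp - 1) / 2.0
    c = spec.pitch / (2.0 * np.pi)
    sc = float(np.clip(s, -half, half))
    alpha = sc * spec.delta_alpha
    norm = np.hypot(spec.radius, c)
    point = np.array([spec.radius * np.cos(alpha),
                      spec.radius * np.sin(alpha), -c * alpha])
    tangent = np.array([-spec.radius * np.sin(alpha),
                        spec.radius * np.cos(alpha), -c]) / norm
    e1 = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    if s != sc:
        point = point + (s - sc) * spec.rise * tangent
    e2 = np.cross(tangent, e1)
    return point, e1, e2, tangent


def _dna_coords(spec: SuperhelixSpec, register: float = 0.0,
                phase_offset_deg: float = 0.0, slot_of_bp=None):
    """Positions for the six DNA beads of every base pair.

    Returns dict ``(strand, bp, kind) -> position``.  ``slot_of_bp``
    optionally maps bp index to a fractional path slot (defaults to
    ``bp - dyad + register``); the rotational phase is tied to the slot
    (screw-like placement) plus ``phase_offset_deg``.
    """
    out = {}
    dyad = spec.dyad_bp
    tpb = 360.0 / spec.dna_twist  # degrees of twist per slot
    for b in range(spec.total_bp):
        s = (b - dyad + register) if slot_of_bp is None else slot_of_bp(b)
        point, e1, e2, _ = _path_frame(spec, s)
        phi = (tpb * s + spec.phase0_deg + phase_offset_deg) * DEG
        spoke = np.cos(phi) * e1 + np.sin(phi) * e2
        for strand, sgn in ((1, 1.0), (2, -1.0)):
            out[(strand, b, "P")] = point + sgn * spec.dna_radius * spoke
            out[(strand, b, "S")] = point + sgn * spec.sugar_radius * spoke
            out[(strand, b, "B")] = point + sgn * spec.base_radius * spoke
    # 5' termini carry no phosphate
    del out[(1, 0, "P")]
    del out[(2, spec.total_bp - 1, "P")]
    return out


def _donor_slots(spec: SuperhelixSpec):
    """Positive path slots (offsets from the dyad) of the hydrogen-bond
    donors, one per positive half-integer superhelical location; the
    negative-SHL sites are their C2 images."""
    ks = np.arange(0.5, spec.hb_shl_max + 1e-9, 1.0)
    return [int(round(spec.dna_twist * k)) for k in ks]


def build_ideal_nucleosome(spec: SuperhelixSpec = None) -> CGStructure:
    """Construct the ideal fixture.

    Chains: ``A``/``B`` DNA strands 1/2; ``D``/``E`` donor-site CA
    triplets at the positive/negative half-integer SHLs (donor at the
    middle residue of each triplet; the two chains are exact C2
    partners with matching residue indices, so the default symmetry
    pairing applies); ``F``/``G`` the two halves of a scaffold chain
    tracing the wrapped DNA centerline, plus the single dyad scaffold
    bead ``O``; ``I``/``J`` azimuthally mirrored copies of the
    scaffold and donor sets that balance the core centroid onto the
    superhelix axis.  ``meta`` carries the spec, the current
    register/phase and the native donor/phosphate pair list.
    """
    spec = spec or SuperhelixSpec()
    beads = []
    dyad = spec.dyad_bp
    half = (spec.n_wrapped_bp - 1) // 2
    mirror = np.diag([-1.0, -1.0, 1.0])  # 180 deg about the superhelix axis

    dna = _dna_coords(spec)
    for b in range(spec.total_bp):
        for kind in ("P", "S", "B"):
            if (1, b, kind) in dna:
                beads.append(Bead("A", b + 1, kind, dna[(1, b, kind)]))
    for b in range(spec.total_bp):
        resid = spec.total_bp - b  # antiparallel numbering
        for kind in ("P", "S", "B"):
            if (2, b, kind) in dna:
                beads.append(Bead("B", resid, kind, dna[(2, b, kind)]))

    # Donor triplets: positive-SHL sites bond strand-1 phosphates,
    # negative-SHL sites bond strand-2 (their exact C2 images), so the
    # donor set is C2 symmetric and the flank ordering of chain E is
    # reversed to keep identical residue indices on C2 partners.
    hb_pairs = []
    donor_beads = []
    for m, slot in enumerate(_donor_slots(spec)):
        for chain, sgn in (("D", +1), ("E", -1)):
            sslot = sgn * slot
            _, _, _, tangent = _path_frame(spec, sslot)
            if sgn > 0:
                p_pos = dna[(1, dyad + sslot, "P")]
                hb_pairs.append((("D", 10 * m + 2), ("A", dyad + sslot + 1)))
            else:
                p_pos = dna[(2, dyad + sslot, "P")]
                hb_pairs.append((("E", 10 * m + 2),
                                 ("B", spec.total_bp - (dyad + sslot))))
            inward = -np.array([p_pos[0], p_pos[1], 0.0])
            inward /= np.linalg.norm(inward)
            donor = p_pos + spec.donor_offset * inward
            offsets = (-3.8, 0.0, 3.8) if sgn > 0 else (3.8, 0.0, -3.8)
            for j, off in enumerate(offsets):
                donor_beads.append(Bead(chain, 10 * m + 1 + j, "CA",
                                        donor + off * tangent))
    beads.extend(donor_beads)

    scaffold = [Bead("O", 1, "CA", _path_frame(spec, 0)[0])]
    for s in range(1, half + 1):
        scaffold.append(Bead("G", s, "CA", _path_frame(spec, s)[0]))
        scaffold.append(Bead("F", s, "CA", _path_frame(spec, -s)[0]))
    beads.extend(scaffold)

    beads.extend(Bead("I", i + 1, "CA", mirror @ bd.position)
                 for i, bd in enumerate(scaffold))
    beads.extend(Bead("J", i + 1, "CA", mirror @ bd.position)
                 for i, bd in enumerate(donor_beads))

    structure = CGStructure(beads)
    structure.meta.update({
        "superhelix": spec, "register": 0.0, "phase_offset_deg": 0.0,
        "dyad_bp": dyad, "hb_pairs": hb_pairs,
    })
    return structure


def _regenerate_dna(structure: CGStructure, register: float,
                    phase_offset_deg: float, slot_of_bp=None) -> CGStructure:
    spec = structure.meta["superhelix"]
    dna = _dna_coords(spec, register, phase_offset_deg, slot_of_bp)
    pos = structure.positions.copy()
    for strand, bp_map in ((1, structure.strand1), (2, structure.strand2)):
        for b, kinds in bp_map.items():
            for kind, idx in kinds.items():
                pos[idx] = dna[(strand, b, kind)]
    new = structure.with_positions(pos)
    new.meta = dict(structure.meta)
    new.meta["register"] = register
    new.meta["phase_offset_deg"] = phase_offset_deg
    return new


def advance_screw(structure: CGStructure, n_bp: float) -> CGStructure:
    """Corkscrew the DNA by ``n_bp`` along its own path.

    The spatial path is unchanged; the base-pair register advances so
    the base pair initially at the dyad moves toward higher-index
    positions for positive ``n_bp``.  The rotational phase follows the
    path twist, so the operation is exactly rotation-coupled.
    """
    if "superhelix" not in structure.meta:
        raise NucleoslideError("advance_screw needs an ideal-fixture structure")
    spec = structure.meta["superhelix"]
    register = structure.meta["register"] + n_bp
    if abs(register) > spec.path_margin:
        raise WindowError(
            f"register {register} exceeds the path margin ({spec.path_margin} bp)")
    return _regenerate_dna(structure, register,
                           structure.meta["phase_offset_deg"])


def advance_jump(structure: CGStructure, n_bp: float) -> CGStructure:
    """Advance the register by ``n_bp`` while holding the rotational
    phase of every base pair fixed (rotation-uncoupled motion)."""
    if "superhelix" not in structure.meta:
        raise NucleoslideError("advance_jump needs an ideal-fixture structure")
    spec = structure.meta["superhelix"]
    register = structure.meta["register"] + n_bp
    if abs(register) > spec.path_margin:
        raise WindowError(
            f"register {register} exceeds the path margin ({spec.path_margin} bp)")
    phase = structure.meta["phase_offset_deg"] - (360.0 / spec.dna_twist) * n_bp
    return _regenerate_dna(structure, register, phase)


@dataclass
class TrajectorySpec:
    """Recipe for a synthetic sliding trajectory."""

    mode: str                     # static | screw | jump | loop
    n_frames: int = 100
    step_bp: int | None = None    # default: 1 (screw), 5 (jump), 10 (loop)
    event_prob: float = None      # default: 1.0 (screw), 0.2 (jump)
    noise_sigma: float = 0.0      # Angstrom, per bead per frame
    seed: int = 0
    schedule: list = None         # explicit cumulative bp shifts (overrides RNG)
    bulge_amplitude: float = 3.0  # Angstrom, loop mode
    bulge_width: float = 3.0      # bp, loop mode

    def __post_init__(self):
        if self.mode not in ("static", "screw", "jump", "loop"):
            raise ValueError(f"unknown trajectory mode {self.mode!r}")
        if self.step_bp is None:
            self.step_bp = {"static": 0, "screw": 1, "jump": 5, "loop": 10}[self.mode]
        if self.event_prob is None:
            self.event_prob = {"static": 0.0, "screw": 1.0,
                               "jump": 0.2, "loop": 0.0}[self.mode]
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _shift_walk(spec: SuperhelixSpec, tspec: TrajectorySpec, rng) -> np.ndarray:
    """Cumulative register shifts for screw/jump random walks, reflected
    at the path margin."""
    if tspec.schedule is not None:
        return np.asarray(tspec.schedule, dtype=float)
    shifts = np.zeros(tspec.n_frames)
    s = 0.0
    for i in range(tspec.n_frames):
        if i and rng.random() < tspec.event_prob:
            step = tspec.step_bp * rng.choice([-1, 1])
            if abs(s + step) > spec.path_margin:
                step = -step
            s += step
        shifts[i] = s
    return shifts


def make_trajectory(structure: CGStructure,
                    tspec: TrajectorySpec) -> Trajectory:
    """Generate a synthetic trajectory over the ideal fixture.

    * ``screw``: rotation-coupled ±step random walk (or an explicit
      ``schedule``), phase tied to the path;
    * ``jump``: rotation-uncoupled ±step register jumps with the phase
      held fixed — the rotation coordinate is constant by construction;
    * ``loop``: a bulge defect of ``step_bp`` extra base pairs enters at
      the high-index end and propagates stage by stage to the other
      end, shifting each superhelical location as it passes;
    * ``static``: no motion.

    Gaussian positional noise of ``noise_sigma`` is added independently
    per bead per frame.  ``meta['truth']`` records the ground-truth
    register shift per frame.
    """
    if "superhelix" not in structure.meta:
        raise NucleoslideError("make_trajectory needs an ideal-fixture structure")
    spec = structure.meta["superhelix"]
    rng = np.random.default_rng(tspec.seed)
    frames, truth = [], []

    if tspec.mode in ("static", "screw", "jump"):
        shifts = (np.zeros(tspec.n_frames) if tspec.mode == "static"
                  else _shift_walk(spec, tspec, rng))
        for i, s in enumerate(shifts):
            if tspec.mode == "jump":
                frame = advance_jump(structure, s - structure.meta["register"])
            else:
                frame = advance_screw(structure, s - structure.meta["register"])
            frames.append(frame.positions)
            truth.append({"frame": i, "true_bp_shift": s})
    else:  # loop: staged bulge propagation, high end -> low end
        dyad = spec.dyad_bp
        half = (spec.n_wrapped_bp - 1) // 2
        boundaries = np.linspace(half + tspec.step_bp, -half - tspec.step_bp,
                                 tspec.n_frames)
        for i, bound in enumerate(boundaries):
            def slot_of_bp(b, bound=bound):
                s = b - dyad
                shifted = tspec.step_bp if s > bound else 0.0
                return s + shifted
            frame = _regenerate_dna(structure, 0.0, 0.0, slot_of_bp)
            pos = frame.positions.copy()
            # radial bulge at the propagating boundary
            for b in range(spec.total_bp):
                s = b - dyad
                amp = tspec.bulge_amplitude * np.exp(
                    -0.5 * ((s - bound) / tspec.bulge_width) ** 2)
                if amp < 1e-3:
                    continue
                point, e1, _, _ = _path_frame(spec, s)
                for strand_map in (structure.strand1, structure.strand2):
                    for kind, idx in strand_map.get(b, {}).items():
                        pos[idx] = pos[idx] + amp * e1
            frames.append(pos)
            truth.append({"frame": i, "true_bp_shift": np.nan,
                          "loop_boundary_bp": bound + dyad})

    coords = np.stack(frames)
    if tspec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, tspec.noise_sigma, coords.shape)
    return Trajectory(topology=structure, coords=coords,
                      meta={"truth": pd.DataFrame(truth), "spec": tspec})


# ---------------------------------------------------------------------
# Sequence constructs
# ---------------------------------------------------------------------

#: Central +-4 superhelical locations (81 bp) of the four constructs.
SEQ_601_SHL4 = ("TCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCGCTGTCCCCCGCG"
                "TTTTAACCGCCAAGGGGATTACTCCCTAGT")
SEQ_POLYCG_601_SHL4 = ("CGCGCGCGCGCGCGCGCGCGCGTTAAAGCGCGCGCGCGCGCGCGCGCGCGCG"
                       "TTTAAGCGCGCGCGCGCGCGCGCGCGCGC")

#: Offsets of the positioning motifs within the 81-bp region.
MOTIF_OFFSETS = {"TTAAA": 22, "TTTAA": 52}


def polycg(length: int) -> str:
    """Alternating C/G starting with C."""
    return ("CG" * (length // 2 + 1))[:length]


def polyaa(length: int) -> str:
    return "A" * length


def polycg_601(length: int = 81) -> str:
    """polyCG with the two positioning motifs inserted at their native
    offsets (only meaningful at the default 81-bp region length)."""
    s = list(polycg(length))
    for motif, off in MOTIF_OFFSETS.items():
        if off + len(motif) <= length:
            s[off:off + len(motif)] = motif
    return "".join(s)


def make_sequences(length: int = 81) -> dict:
    """The four nucleosomal DNA constructs over the ±4-SHL region.

    The 601 and polyCG-601 regions are fixed 81-bp sequences; polyCG
    and polyAA generate to the requested length.
    """
    return {
        "601": SequenceConstruct("601", SEQ_601_SHL4),
        "polyCG": SequenceConstruct("polyCG", polycg(length)),
        "polyAA": SequenceConstruct("polyAA", polyaa(length)),
        "polyCG-601": SequenceConstruct("polyCG-601", SEQ_POLYCG_601_SHL4),
    }
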