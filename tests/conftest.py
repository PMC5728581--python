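"""Shared fixtures: ideal nucleosome structures and small toys."""

import numpy as np
import pytest

from nucleoslide import hbond, synthetic
from nucleoslide.structures import Bead, CGStructure


@pytest.fixture(scope="session")
def ideal():
    """Default ideal nucleosome: 147 wrapped bp + 38-bp linkers."""
    return synthetic.build_ideal_nucleosome()


@pytest.fixture(scope="session")
def ideal_nolinker():
    """Fully wrapped fixture (no linker arms)."""
    return synthetic.build_ideal_nucleosome(
        synthetic.SuperhelixSpec(linker_bp=0))


@pytest.fixture(scope="session")
def native_model(ideal):
    """Hydrogen-bond model extracted from the ideal fixture itself."""
    return hbond.extract_hbond_model(ideal, ideal.meta["hb_pairs"],
                                     symmetrize=False)


def make_hb_toy(p_offset=(0.0, 5.0, 0.0), s_offset=(0.0, 5.0, 3.0),
                extra_nucleotides=()):
    """A minimal donor/phosphate system.

    Protein chain ``X`` has three collinear CA beads along x with the
    donor (resid 2) at the origin; the first nucleotide's P/S sit at
    the given offsets from the donor.  ``extra_nucleotides`` adds more
    (P, S) position pairs.
    """
    beads = [
        Bead("X", 1, "CA", (-3.8, 0.0, 0.0)),
        Bead("X", 2, "CA", (0.0, 0.0, 0.0)),
        Bead("X", 3, "CA", (3.8, 0.0, 0.0)),
        Bead("N", 1, "P", p_offset),
        Bead("N", 1, "S", s_offset),
        Bead("N", 1, "B", np.add(s_offset, (0.0, 0.0, 1.0))),
    ]
    for i, (p, s) in enumerate(extra_nucleotides, start=2):
        beads.append(Bead("N", i, "P", p))
        beads.append(Bead("N", i, "S", s))
        beads.append(Bead("N", i, "B", np.add(s, (0.0, 0.0, 1.0))))
    return CGStructure(beads)


def straight_bdna(n_bp=60, radius=9.4, twist_bp=10.0, rise=3.4):
    """Ideal straight double helix along z (strand beads on opposite
    spokes, 3 beads per nucleotide)."""
    beads = []
    for strand, chain, sgn in ((1, "A", 1.0), (2, "B", -1.0)):
        for b in range(n_bp):
            resid = b + 1 if strand == 1 else n_bp - b
            phi = 2 * np.pi * b / twist_bp
            spoke = sgn * np.array([np.cos(phi), np.sin(phi), 0.0])
            z = np.array([0.0, 0.0, b * rise])
            if not (strand == 1 and b == 0) and not (strand == 2 and b == n_bp - 1):
                beads.append(Bead(chain, resid, "P", z + radius * spoke))
            beads.append(Bead(chain, resid, "S", z + 7.0 * spoke))
            beads.append(Bead(chain, resid, "B", z + 2.5 * spoke))
    return CGStructure(beads)


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-50.0, 50.0, 3)
    return rot, trans
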