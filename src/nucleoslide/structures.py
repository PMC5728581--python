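"""Domain types and I/O for coarse-grained nucleosome structures.

The coarse-grained representation uses one bead per protein residue
(``CA``, at the C-alpha position) and three beads per nucleotide
(``P`` phosphate, ``S`` sugar, ``B`` base).  Structures can be read and
written as multi-model PDB (via MDAnalysis) or as a documented
tab-separated bead table.

Conventions
-----------
* Residue indices are 1-based within each chain.
* Base-pair indices are 0-based at the first base pair of strand 1.
* Strand 2 is antiparallel: its residue ``n_bp - b`` pairs with strand-1
  residue ``b + 1`` (base pair index ``b``).
* Lengths in Angstrom throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParseError, TopologyError

BEAD_KINDS = ("CA", "P", "S", "B")
PROTEIN_KINDS = frozenset({"CA"})
DNA_KINDS = frozenset({"P", "S", "B"})

#: Generic per-kind excluded-volume radii (Angstrom).  Forcefield radii
#: are inherited from prior parameterizations and are user-replaceable;
#: these defaults only need to be of the right magnitude for toy work.
DEFAULT_RADII = {"CA": 3.0, "P": 2.9, "S": 3.1, "B": 2.7}


@dataclass(frozen=True)
class Bead:
    """A single coarse-grained site.

    ``kind`` is one of ``CA`` (protein), ``P``/``S``/``B`` (DNA).
    ``charge`` in elementary-charge units, ``radius`` in Angstrom.
    ``flexible_tail`` marks disordered histone-tail residues, which are
    excluded from the hydrogen-bond machinery and the structured core.
    """

    chain_id: str
    residue_index: int
    kind: str
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    flexible_tail: bool = False

    def __post_init__(self):
        if self.kind not in BEAD_KINDS:
            raise TopologyError(f"unknown bead kind {self.kind!r}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        radius = self.radius if self.radius > 0 else DEFAULT_RADII[self.kind]
        object.__setattr__(self, "radius", float(radius))


class CGStructure:
    """An ordered collection of beads with derived DNA/protein topology.

    Parameters
    ----------
    beads
        Ordered beads.  Chains must be homogeneous: protein chains
        contain only CA beads, DNA chains only P/S/B beads.
    symmetric_pairs
        Optional list of ``(bead_index, bead_index)`` pairs across the
        two copies of each histone, used for the symmetry-axis fit.
        Members must be non-tail CA beads.  When omitted, pairs are
        assigned by the default convention: protein chains with an
        identical residue layout are paired in order of appearance and
        their non-tail residues matched by identical residue index
        (e.g. residue 51 of the two H3 copies).
    meta
        Free-form provenance dictionary (copied by reference).
    """

    def __init__(self, beads, symmetric_pairs=None, meta=None):
        self.beads = list(beads)
        if not self.beads:
            raise TopologyError("structure has no beads")
        self.positions = np.array([b.position for b in self.beads], dtype=float)
        self.meta = dict(meta or {})
        self._index = {}
        chains: dict[str, list[int]] = {}
        for i, b in enumerate(self.beads):
            self._index[(b.chain_id, b.residue_index, b.kind)] = i
            chains.setdefault(b.chain_id, []).append(i)
        self.chains = chains

        protein_chains, dna_chains = [], []
        for cid, idx in chains.items():
            kinds = {self.beads[i].kind for i in idx}
            if kinds <= PROTEIN_KINDS:
                protein_chains.append(cid)
            elif kinds <= DNA_KINDS:
                dna_chains.append(cid)
            else:
                raise TopologyError(f"chain {cid!r} mixes protein and DNA bead kinds")
        self.protein_chains = protein_chains
        self.dna_chains = dna_chains
        self.histone_core = frozenset(
            i for cid in protein_chains for i in chains[cid]
            if not self.beads[i].flexible_tail
        )
        self._build_bp_maps()
        if symmetric_pairs is None:
            symmetric_pairs = default_symmetric_pairs(self)
        for i, j in symmetric_pairs:
            for k in (i, j):
                b = self.beads[k]
                if b.kind != "CA" or b.flexible_tail:
                    raise TopologyError(
                        "symmetric_pairs must reference non-tail CA beads"
                    )
        self.symmetric_pairs = [(int(i), int(j)) for i, j in symmetric_pairs]

    def _build_bp_maps(self):
        """Map base-pair index -> {kind: bead index} for both strands."""
        self.strand1, self.strand2 = {}, {}
        if not self.dna_chains:
            self.n_bp = 0
            return
        if len(self.dna_chains) not in (1, 2):
            raise TopologyError("expected one or two DNA chains")

        def resids(cid):
            r = sorted({self.beads[i].residue_index for i in self.chains[cid]})
            if r != list(range(r[0], r[0] + len(r))):
                raise TopologyError(f"DNA chain {cid!r} has non-contiguous residues")
            return r

        c1 = self.dna_chains[0]
        r1 = resids(c1)
        self.n_bp = len(r1)
        for b, resid in enumerate(r1):
            self.strand1[b] = {
                k: self._index[(c1, resid, k)]
                for k in DNA_KINDS if (c1, resid, k) in self._index
            }
        if len(self.dna_chains) == 2:
            c2 = self.dna_chains[1]
            r2 = resids(c2)
            if len(r2) != self.n_bp:
                raise TopologyError("strand 1 and strand 2 differ in base-pair count")
            # antiparallel pairing: strand-2 residue order reversed
            for b, resid in enumerate(reversed(r2)):
                self.strand2[b] = {
                    k: self._index[(c2, resid, k)]
                    for k in DNA_KINDS if (c2, resid, k) in self._index
                }

    # -- lookups -------------------------------------------------------
    def __len__(self):
        return len(self.beads)

    def bead_index(self, chain_id, residue_index, kind):
        try:
            return self._index[(chain_id, residue_index, kind)]
        except KeyError:
            raise KeyError(
                f"no bead ({chain_id!r}, {residue_index}, {kind!r})"
            ) from None

    def phosphate_indices(self, strand=1):
        """Bead indices of phosphates, ordered by base pair (ascending)."""
        m = self.strand1 if strand == 1 else self.strand2
        return [m[b]["P"] for b in sorted(m) if "P" in m[b]]

    @property
    def all_phosphates(self):
        return self.phosphate_indices(1) + self.phosphate_indices(2)

    def sugar_of_phosphate(self, p_index):
        b = self.beads[p_index]
        return self._index[(b.chain_id, b.residue_index, "S")]

    def bp_center(self, bp, positions=None):
        """Centroid of all available beads of a base pair (both strands)."""
        pos = self.positions if positions is None else positions
        idx = list(self.strand1.get(bp, {}).values()) + \
            list(self.strand2.get(bp, {}).values())
        if not idx:
            raise KeyError(f"base pair {bp} not in structure")
        return pos[idx].mean(axis=0)

    def core_centroid(self, positions=None):
        pos = self.positions if positions is None else positions
        idx = sorted(self.histone_core)
        if not idx:
            raise TopologyError("structure has no histone core beads")
        return pos[idx].mean(axis=0)

    def with_positions(self, positions):
        """A shallow copy sharing topology, with new coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != self.positions.shape:
            raise ValueError("position array shape mismatch")
        new = object.__new__(CGStructure)
        new.__dict__.update(self.__dict__)
        new.beads = [replace(b, position=positions[i]) for i, b in enumerate(self.beads)]
        new.positions = positions
        return new

    @property
    def charges(self):
        return np.array([b.charge for b in self.beads])

    @property
    def radii(self):
        return np.array([b.radius for b in self.beads])

    @property
    def kinds(self):
        return np.array([b.kind for b in self.beads])


def default_symmetric_pairs(structure: "CGStructure") -> list:
    """Default histone symmetry pairing.

    Protein chains with identical residue layouts are grouped; within
    each group, consecutive chains (in order of appearance) are paired
    and their non-tail residues matched by identical residue index.
    Chains without a same-layout partner contribute no pairs.
    """
    groups: dict[tuple, list[str]] = {}
    for cid in structure.protein_chains:
        resids = tuple(sorted(structure.beads[i].residue_index
                              for i in structure.chains[cid]))
        groups.setdefault(resids, []).append(cid)
    pairs = []
    for resids, cids in groups.items():
        for a, b in zip(cids[0::2], cids[1::2]):
            for r in resids:
                i = structure._index[(a, r, "CA")]
                j = structure._index[(b, r, "CA")]
                if structure.beads[i].flexible_tail or \
                        structure.beads[j].flexible_tail:
                    continue
                pairs.append((i, j))
    return pairs


@dataclass
class Trajectory:
    """Per-frame coordinates over a fixed topology."""

    topology: CGStructure
    coords: np.ndarray  # (n_frames, n_beads, 3)
    frame_stride: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.topology):
            raise TopologyError("frames do not match topology bead count")
        if self.frame_stride <= 0:
            raise ValueError("frame_stride must be positive")

    def __len__(self):
        return self.coords.shape[0]

    def __iter__(self):
        return iter(self.coords)


# ---------------------------------------------------------------------
# Sequence constructs
# ---------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def complement(seq: str) -> str:
    """Watson-Crick complement (same 5'->3' orientation kept; not reversed)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class SequenceConstruct:
    """A nucleosomal DNA construct: core sequence plus two linkers."""

    name: str
    core: str
    linker5: str = ""
    linker3: str = ""

    @property
    def sequence(self) -> str:
        return self.linker5 + self.core + self.linker3

    @property
    def total_length(self) -> int:
        return len(self.sequence)

    @property
    def complement_strand(self) -> str:
        return reverse_complement(self.sequence)


def _polycg(n: int, end_with_g: bool = False) -> str:
    """Alternating C/G of length n; optionally phased to end with G."""
    if n == 0:
        return ""
    s = "CG" * (n // 2 + 1)
    return s[-n:] if end_with_g else s[:n]


def read_sequence(path) -> SequenceConstruct:
    """Read a DNA sequence from FASTA (via Biopython) or plain text."""
    text = open(path).read()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO
        rec = next(SeqIO.parse(str(path), "fasta"))
        return SequenceConstruct(name=rec.id, core=str(rec.seq).upper())
    seq = "".join(text.split()).upper()
    return SequenceConstruct(name=str(path), core=seq)


def build_construct(core, linker_length: int, name: str | None = None) -> SequenceConstruct:
    """Flank a core sequence with alternating-CG linkers of equal length.

    The 5' linker is phased to end with G and the 3' linker to start
    with C, so each linker alternates internally.  Core lengths other
    than the canonical 145/147 bp are allowed with a warning.
    """
    if isinstance(core, SequenceConstruct):
        name = name or core.name
        core = core.core
    core = core.upper()
    if linker_length < 0:
        raise ValueError("linker length must be non-negative")
    if len(core) not in (145, 147):
        warnings.warn(
            f"core length {len(core)} is not a canonical nucleosome core (145/147 bp)",
            stacklevel=2,
        )
    return SequenceConstruct(
        name=name or "construct",
        core=core,
        linker5=_polycg(linker_length, end_with_g=True),
        linker3=_polycg(linker_length),
    )


# ---------------------------------------------------------------------
# Bead-table (TSV) dialect
# ---------------------------------------------------------------------

TSV_COLUMNS = ["chain", "resid", "kind", "x", "y", "z", "charge", "radius", "tail"]


def _beads_from_table(df: pd.DataFrame, path="<table>") -> list[Bead]:
    beads = []
    for row in df.itertuples(index=True):
        try:
            charge = 0.0 if row.charge in (".", None) or pd.isna(row.charge) \
                else float(row.charge)
            radius = 0.0 if row.radius in (".", None) or pd.isna(row.radius) \
                else float(row.radius)
            tail = str(row.tail).strip().lower() in ("1", "true", "yes")
            beads.append(Bead(
                chain_id=str(row.chain), residue_index=int(row.resid),
                kind=str(row.kind).strip(),
                position=(float(row.x), float(row.y), float(row.z)),
                charge=charge, radius=radius, flexible_tail=tail,
            ))
        except (ValueError, TopologyError) as exc:
            raise ParseError(f"{path}: bad record at data row {row.Index}: {exc}") from exc
    return beads


def read_bead_tsv(path) -> CGStructure:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return CGStructure(_beads_from_table(df, path))


def write_bead_tsv(structure: CGStructure, path) -> None:
    rows = []
    for b in structure.beads:
        rows.append({
            "chain": b.chain_id, "resid": b.residue_index, "kind": b.kind,
            "x": f"{b.position[0]:.3f}", "y": f"{b.position[1]:.3f}",
            "z": f"{b.position[2]:.3f}",
            "charge": f"{b.charge:.4f}", "radius": f"{b.radius:.3f}",
            "tail": int(b.flexible_tail),
        })
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# PDB dialect (via MDAnalysis)
# ---------------------------------------------------------------------

def _mda():
    import MDAnalysis as mda
    return mda


def _universe_from_structure(structure: CGStructure, coords=None):
    mda = _mda()
    n = len(structure)
    chain_ids = [b.chain_id for b in structure.beads]
    # one MDAnalysis "residue" per (chain, resid)
    res_keys, res_of_bead = [], []
    seen = {}
    for b in structure.beads:
        key = (b.chain_id, b.residue_index)
        if key not in seen:
            seen[key] = len(res_keys)
            res_keys.append(key)
        res_of_bead.append(seen[key])
    seg_keys = sorted({c for c in chain_ids})
    seg_of_res = [seg_keys.index(c) for c, _ in res_keys]
    u = mda.Universe.empty(
        n_atoms=n, n_residues=len(res_keys), n_segments=len(seg_keys),
        atom_resindex=res_of_bead, residue_segindex=seg_of_res,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [b.kind for b in structure.beads])
    u.add_TopologyAttr("resids", [r for _, r in res_keys])
    u.add_TopologyAttr("resnames", ["BEA"] * len(res_keys))
    u.add_TopologyAttr("segids", seg_keys)
    u.add_TopologyAttr("chainIDs", [c[:1] for c in chain_ids])
    u.atoms.positions = structure.positions if coords is None else coords
    return u


def write_pdb(structure: CGStructure, path, coords_list=None) -> None:
    """Write a structure (or a list of frames) as (multi-model) PDB."""
    mda = _mda()
    u = _universe_from_structure(structure)
    frames = [structure.positions] if coords_list is None else list(coords_list)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=len(u.atoms), multiframe=len(frames) > 1) as w:
            for xyz in frames:
                u.atoms.positions = xyz
                w.write(u.atoms)


def read_pdb(path) -> tuple[CGStructure, np.ndarray]:
    """Read a (multi-model) coarse-grained PDB.

    Returns the structure built from the first model and the stacked
    coordinates of all models.
    """
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
    beads = []
    for atom in u.atoms:
        kind = atom.name.strip()
        if kind not in BEAD_KINDS:
            raise ParseError(
                f"{path}: atom name {atom.name!r} is not a bead kind {BEAD_KINDS}"
            )
        chain = getattr(atom, "chainID", "") or atom.segid or "A"
        beads.append(Bead(
            chain_id=str(chain).strip(), residue_index=int(atom.resid),
            kind=kind, position=atom.position.astype(float),
        ))
    coords = np.stack([u.atoms.positions.copy().astype(float) for _ in u.trajectory])
    structure = CGStructure(beads)
    structure.positions = coords[0]
    return structure, coords


def read_structure(path, dialect: str | None = None) -> CGStructure:
    """Read a coarse-grained structure from PDB or bead-TSV.

    ``dialect`` is ``"pdb"`` or ``"bead-tsv"``; inferred from the file
    extension when omitted.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect == "pdb":
        structure, _ = read_pdb(path)
        return structure
    if dialect == "bead-tsv":
        return read_bead_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_structure(structure: CGStructure, path, dialect: str | None = None) -> None:
    dialect = dialect or _infer_dialect(path)
    if dialect == "pdb":
        write_pdb(structure, path)
    elif dialect == "bead-tsv":
        write_bead_tsv(structure, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_trajectory(path, frame_stride: int = 1) -> Trajectory:
    """Read a multi-model PDB as a trajectory."""
    structure, coords = read_pdb(path)
    return Trajectory(topology=structure, coords=coords, frame_stride=frame_stride)


def write_trajectory(traj: Trajectory, path) -> None:
    write_pdb(traj.topology, path, coords_list=list(traj.coords))


def _infer_dialect(path) -> str:
    p = str(path).lower()
    if p.endswith(".pdb"):
        return "pdb"
    if p.endswith((".tsv", ".txt")):
        return "bead-tsv"
    raise ValueError(f"cannot infer dialect from {path!r}; pass dialect=")


# ---------------------------------------------------------------------
# All-atom -> CG mapping
# ---------------------------------------------------------------------

_PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}


def coarse_grain(source) -> CGStructure:
    """Map an all-atom structure to the CA / P-S-B representation.

    ``source`` is an MDAnalysis Universe or a path to a structure file.
    Protein residues become a single CA bead at the C-alpha position;
    nucleotides become P (at the phosphorus), S (sugar heavy-atom
    centroid) and B (base heavy-atom centroid) beads.  Residues missing
    a C-alpha are skipped and reported in ``meta['missing_ca']``;
    5'-terminal nucleotides without phosphorus simply omit the P bead
    (reported in ``meta['missing_p']``).
    """
    mda = _mda()
    u = source if hasattr(source, "atoms") else mda.Universe(str(source))
    beads, missing_ca, missing_p = [], [], []
    for res in u.residues:
        heavy = res.atoms[[not a.name.startswith("H") for a in res.atoms]]
        names = {a.name for a in heavy}
        chain = (getattr(res.atoms[0], "chainID", "") or res.segid or "A").strip()
        is_nuc = bool(names & {"C1'", "C1*"}) or bool(names & _PHOSPHATE_ATOMS)
        if not is_nuc:
            if "CA" in names:
                ca = heavy[[a.name == "CA" for a in heavy]][0]
                beads.append(Bead(chain, int(res.resid), "CA", ca.position.astype(float)))
            else:
                missing_ca.append((chain, int(res.resid)))
            continue
        p_sel = heavy[[a.name == "P" for a in heavy]]
        if len(p_sel):
            beads.append(Bead(chain, int(res.resid), "P", p_sel[0].position.astype(float)))
        else:
            missing_p.append((chain, int(res.resid)))
        sugar = heavy[[("'" in a.name or "*" in a.name) for a in heavy]]
        base = heavy[[
            a.name not in _PHOSPHATE_ATOMS and "'" not in a.name and "*" not in a.name
            for a in heavy]]
        if len(sugar):
            beads.append(Bead(chain, int(res.resid), "S",
                              sugar.positions.mean(axis=0).astype(float)))
        if len(base):
            beads.append(Bead(chain, int(res.resid), "B",
                              base.positions.mean(axis=0).astype(float)))
    structure = CGStructure(beads, meta={"missing_ca": missing_ca,
                                         "missing_p": missing_p})
    return structure
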