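"""DNA duplex geometry and protein-DNA contact footprints.

Register convention (transcription coordinates): +1 is the template base at
the RNA 3'-end position in the active site; positions upstream of the
transcription bubble are negative.  A translocase footprint of, say, −34…−14
therefore sits on the upstream duplex.

Base-pair frames are built from paired C1′ atoms; the local helical axis at
pair *i* is the unit vector from midpoint(i−w) to midpoint(i+w) with
half-window w (default 2; one-sided at the ends).  The global bend is the
angle between the first and last local axes; the kink is the largest angle
between consecutive local axes.  Minor-groove widths use the short-diagonal
phosphate convention: the minimum cross-strand P–P distance over offsets
+2…+5, minus 5.8 Å for the two phosphate van-der-Waals radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import CoordinateSet, StructureModel

__all__ = [
    "BasePairFrame",
    "DuplexGeometry",
    "Contact",
    "ContactFootprint",
    "build_frames",
    "bend_and_kink",
    "minor_groove_widths",
    "contact_footprint",
    "footprint_shift",
]

# distance-only contact classes (no angle criteria)
HBOND_CUTOFF = 3.5  # Å, donor/acceptor-capable heavy atoms
IONIC_CUTOFF = 4.5  # Å, charged group vs phosphate oxygen
VDW_CUTOFF = 4.0  # Å, any heavy-atom pair

MINOR_GROOVE_OFFSETS = (2, 3, 4, 5)
PHOSPHATE_RADIUS_CORRECTION = 5.8  # Å, two phosphate vdW radii

# protein side-chain atoms bearing formal charge
_CHARGED_PROTEIN_ATOMS = {
    ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}
_PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O3'", "O5'"}
_BACKBONE_SUGAR_ATOMS = _PHOSPHATE_ATOMS | {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'"}


@dataclass
class BasePairFrame:
    register: int
    midpoint: np.ndarray  # mean of the paired C1′ atoms, Å
    axis_point: np.ndarray
    axis_vector: np.ndarray  # unit

    def __post_init__(self) -> None:
        assert abs(np.linalg.norm(self.axis_vector) - 1.0) < 1e-6


@dataclass
class DuplexGeometry:
    frames: list[BasePairFrame]
    global_bend_deg: float
    kink: tuple[int, float] | None  # (register, degrees)
    minor_groove_widths: dict[int, float | None]
    half_window: int

    @property
    def axis_polyline(self) -> np.ndarray:
        return np.array([f.midpoint for f in self.frames])


@dataclass
class Contact:
    protein_residue: tuple[str, int]  # (chain, residue number)
    register: int
    strand: str  # "t" or "nt"
    distance: float  # min heavy-atom distance, Å
    contact_class: str  # "hbond" | "ionic" | "vdw"


@dataclass
class ContactFootprint:
    contacts: list[Contact]
    t_strand_fraction: float | None
    register_span: tuple[int, int] | None

    @property
    def registers(self) -> list[int]:
        return sorted({c.register for c in self.contacts})

    def weighted_mean_register(self) -> float:
        if not self.contacts:
            raise ValueError("empty footprint")
        regs = np.array([c.register for c in self.contacts], dtype=float)
        return float(regs.mean())


def _c1_positions(
    model: StructureModel, chain: str
) -> dict[int, np.ndarray]:
    out = {}
    for a in model.atoms:
        if a.chain_id == chain and a.atom_name == "C1'":
            out[a.residue_number] = a.position
    return out


def build_frames(
    model: StructureModel,
    t_chain: str,
    nt_chain: str,
    register_map: Mapping[int, tuple[int, int]],
    half_window: int = 2,
) -> list[BasePairFrame]:
    """One frame per paired register; ``register_map`` maps register →
    (t-strand residue number, nt-strand residue number)."""
    w = half_window
    t_c1 = _c1_positions(model, t_chain)
    nt_c1 = _c1_positions(model, nt_chain)
    registers = sorted(register_map)
    mids: list[np.ndarray] = []
    kept: list[int] = []
    for reg in registers:
        t_res, nt_res = register_map[reg]
        if t_res not in t_c1 or nt_res not in nt_c1:
            continue
        mids.append(0.5 * (t_c1[t_res] + nt_c1[nt_res]))
        kept.append(reg)
    if len(kept) < 2 * w + 1:
        raise ValueError(
            f"need at least {2 * w + 1} paired registers with C1' atoms, got {len(kept)}"
        )
    frames: list[BasePairFrame] = []
    n = len(kept)
    for i in range(n):
        lo = max(0, i - w)
        hi = min(n - 1, i + w)
        v = mids[hi] - mids[lo]
        v = v / np.linalg.norm(v)
        frames.append(
            BasePairFrame(register=kept[i], midpoint=mids[i], axis_point=mids[i], axis_vector=v)
        )
    return frames


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(u @ v, -1.0, 1.0))
    return math.degrees(math.acos(c))


def bend_and_kink(frames: Sequence[BasePairFrame]) -> tuple[float, tuple[int, float]]:
    """Global bend (first vs last local axis) and the sharpest local kink
    (largest angle between consecutive local axes, with its register)."""
    if len(frames) < 4:
        raise ValueError("need at least 4 frames")
    bend = _angle_deg(frames[0].axis_vector, frames[-1].axis_vector)
    best = (frames[0].register, 0.0)
    for a, b in zip(frames, frames[1:]):
        ang = _angle_deg(a.axis_vector, b.axis_vector)
        if ang > best[1]:
            best = (a.register, ang)
    return bend, best


def minor_groove_widths(
    model: StructureModel,
    t_chain: str,
    nt_chain: str,
    register_map: Mapping[int, tuple[int, int]],
    offsets: Sequence[int] = MINOR_GROOVE_OFFSETS,
    correction: float = PHOSPHATE_RADIUS_CORRECTION,
) -> dict[int, float | None]:
    """Short-diagonal minor-groove width per register.

    Width at register i = min over cross-strand offsets of the P(t, i) to
    P(nt, i+k) distance, minus ``correction``.  Registers with missing
    phosphates get None (reported, never fabricated).
    """
    t_p = {a.residue_number: a.position for a in model.atoms
           if a.chain_id == t_chain and a.atom_name == "P"}
    nt_p = {a.residue_number: a.position for a in model.atoms
            if a.chain_id == nt_chain and a.atom_name == "P"}
    out: dict[int, float | None] = {}
    for reg in sorted(register_map):
        t_res, _ = register_map[reg]
        if t_res not in t_p:
            out[reg] = None
            continue
        dists = []
        for k in offsets:
            partner = reg + k
            if partner in register_map:
                _, nt_res = register_map[partner]
                if nt_res in nt_p:
                    dists.append(float(np.linalg.norm(t_p[t_res] - nt_p[nt_res])))
        out[reg] = (min(dists) - correction) if dists else None
    return out


def contact_footprint(
    model: StructureModel,
    protein_set: CoordinateSet,
    t_chain: str,
    nt_chain: str,
    register_map: Mapping[int, tuple[int, int]],
    hbond_cutoff: float = HBOND_CUTOFF,
    ionic_cutoff: float = IONIC_CUTOFF,
    vdw_cutoff: float = VDW_CUTOFF,
    backbone_only: bool = False,
) -> ContactFootprint:
    """Enumerate protein-DNA contacts per (protein residue, register, strand).

    Each triple keeps its minimum heavy-atom distance and is classed by the
    tightest satisfied criterion: hydrogen bond (≤ hbond_cutoff between N/O
    atoms), ionic (≤ ionic_cutoff between a charged protein group and a
    phosphate oxygen), or generic van der Waals (≤ vdw_cutoff).  An empty
    footprint is a valid result, not an error.
    """
    # invert the register map per strand
    t_reg = {t_res: reg for reg, (t_res, _) in register_map.items()}
    nt_reg = {nt_res: reg for reg, (_, nt_res) in register_map.items()}

    dna_atoms = []
    for a in model.atoms:
        if a.element == "H":
            continue
        if a.chain_id == t_chain and a.residue_number in t_reg:
            strand, reg = "t", t_reg[a.residue_number]
        elif a.chain_id == nt_chain and a.residue_number in nt_reg:
            strand, reg = "nt", nt_reg[a.residue_number]
        else:
            continue
        if backbone_only and a.atom_name not in _BACKBONE_SUGAR_ATOMS:
            continue
        dna_atoms.append((a, strand, reg))
    if not dna_atoms or len(protein_set) == 0:
        return ContactFootprint(contacts=[], t_strand_fraction=None, register_span=None)

    dna_coords = np.array([a.position for a, _, _ in dna_atoms])
    tree = cKDTree(dna_coords)
    max_cut = max(hbond_cutoff, ionic_cutoff, vdw_cutoff)

    best: dict[tuple[tuple[str, int], int, str], tuple[float, str]] = {}
    protein_resnames = protein_set.residue_names
    for i, (key, pos) in enumerate(zip(protein_set.keys, protein_set.coords)):
        chain, resnum, _icode, atom_name = key
        if protein_set.elements[i] == "H":
            continue
        resname = protein_resnames[i]
        p_polar = protein_set.elements[i] in ("N", "O")
        p_charged = (resname, atom_name) in _CHARGED_PROTEIN_ATOMS
        for j in tree.query_ball_point(pos, max_cut):
            da, strand, reg = dna_atoms[j]
            d = float(np.linalg.norm(pos - da.position))
            d_polar = da.element in ("N", "O")
            d_phos_ox = da.atom_name in ("OP1", "OP2", "O3'", "O5'")
            if d <= hbond_cutoff and p_polar and d_polar:
                cls = "hbond"
            elif d <= ionic_cutoff and p_charged and d_phos_ox:
                cls = "ionic"
            elif d <= vdw_cutoff:
                cls = "vdw"
            else:
                continue
            k = ((chain, resnum), reg, strand)
            prev = best.get(k)
            if prev is None or d < prev[0]:
                best[k] = (d, cls)

    contacts = [
        Contact(protein_residue=res, register=reg, strand=strand, distance=d, contact_class=cls)
        for (res, reg, strand), (d, cls) in sorted(best.items())
    ]
    if contacts:
        n_t = sum(1 for c in contacts if c.strand == "t")
        frac = n_t / len(contacts)
        regs = [c.register for c in contacts]
        span = (min(regs), max(regs))
    else:
        frac, span = None, None
    return ContactFootprint(contacts=contacts, t_strand_fraction=frac, register_span=span)


def footprint_shift(a: ContactFootprint, b: ContactFootprint) -> tuple[int, float]:
    """Register shift between two footprints (b − a, positive = downstream).

    Uses the contact-weighted mean register of each footprint; returns the
    nearest-integer base-pair shift and the underlying fractional value.
    """
    if not a.contacts or not b.contacts:
        raise ValueError("both footprints must be non-empty")
    frac = b.weighted_mean_register() - a.weighted_mean_register()
    return int(round(frac)), frac
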