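"""Synthetic structures with known ground truth.

Everything the analysis stages measure can be planted here: multi-domain Cα
models under exact rigid motions with optional Gaussian coordinate noise,
ideal and kinked B-form DNA duplexes with controllable minor-groove widths,
protein probe atoms planted at chosen DNA registers, and scaffold sequences
with a specified hybrid/bubble architecture.  Every generator is
deterministic per (spec, seed) and returns a manifest entry recording the
planted parameters.

Protein fixtures are Cα-only; DNA fixtures carry C1', P, OP1, OP2 per
nucleotide — sufficient for every geometric metric in the package.  The
noise model is isotropic Gaussian per atom, the simplest stand-in for the
coordinate uncertainty of intermediate-resolution (3-4 Å) cryo-EM models.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import (
    AtomSite,
    DomainRegistry,
    EnsembleSet,
    Selection,
    SelectionTerm,
    StateAnnotation,
    StructureModel,
)

__all__ = [
    "make_multidomain",
    "apply_motion",
    "make_bdna",
    "make_scaffold",
    "make_ensemble",
    "rotation_matrix",
    "make_fixture_suite",
    "PackingError",
]

CA_BOND = 3.8  # Å, virtual Cα-Cα bond
MIN_CLEARANCE = 2.5  # Å, hard-sphere clearance within a fixture

# synthetic B-DNA fiber geometry (cylindrical coordinates, helix along +z)
BDNA_RISE = 3.4  # Å per base pair
BDNA_TWIST = 36.0  # degrees per base pair
C1_RADIUS = 5.8  # Å; C1' offsets at ±90° so base-pair midpoints sit on the axis
C1_OFFSET_DEG = 90.0
P_RADIUS = 8.91  # Å
P_OFFSET_DEG = 72.0  # chosen so the short-diagonal P-P distance is ~11.6 Å
OP_LENGTH = 1.48  # Å, P->OP bond


class PackingError(RuntimeError):
    pass


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a (normalized) axis."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    a = math.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


# ---------------------------------------------------------------------------
# protein fixtures

def make_multidomain(
    n_domains: int,
    residues_per_domain: int,
    seed: int,
    chain_id: str = "A",
    domain_spacing: float = 30.0,
    max_step_retries: int = 200,
    max_domain_retries: int = 20,
) -> tuple[StructureModel, DomainRegistry, dict]:
    """Self-avoiding Cα traces, one per domain, 3.8 Å virtual bonds.

    Domains are labeled dom1..domN in the returned registry; residue
    numbering is contiguous across domains.  Packing failure after bounded
    retries raises PackingError.
    """
    if residues_per_domain < 8:
        raise ValueError("need at least 8 residues per domain")
    rng = np.random.default_rng(seed)
    atoms: list[AtomSite] = []
    placed: list[np.ndarray] = []
    registry = DomainRegistry()
    resnum = 0
    for d in range(n_domains):
        start_res = resnum + 1
        base_origin = np.array([d * domain_spacing, 0.0, 0.0])
        for attempt in range(max_domain_retries):
            # jitter the start point on retries in case it clashes with
            # already-placed domains
            jitter = rng.normal(scale=5.0, size=3) if attempt else np.zeros(3)
            trace = _self_avoiding_trace(
                rng, residues_per_domain, base_origin + jitter, placed, max_step_retries
            )
            if trace is not None:
                break
        else:
            raise PackingError(
                f"could not pack domain {d + 1} after {max_domain_retries} retries"
            )
        for pos in trace:
            resnum += 1
            atoms.append(
                AtomSite(chain_id, resnum, "", "ALA", "CA", "C", pos)
            )
            placed.append(pos)
        registry.add(
            Selection(
                name=f"dom{d + 1}",
                terms=[SelectionTerm(chain=chain_id, ranges=((start_res, resnum),), atom_names=("CA",))],
            ),
            "synthetic",
        )
    model = StructureModel(model_id=f"multidomain_seed{seed}", atoms=atoms)
    manifest = {
        "kind": "multidomain",
        "seed": seed,
        "n_domains": n_domains,
        "residues_per_domain": residues_per_domain,
        "chain_id": chain_id,
    }
    return model, registry, manifest


def _self_avoiding_trace(
    rng: np.random.Generator,
    n: int,
    origin: np.ndarray,
    external: list[np.ndarray],
    max_step_retries: int,
) -> list[np.ndarray] | None:
    ext = np.array(external) if external else np.empty((0, 3))
    trace = [origin.copy()]
    if len(ext) and np.min(np.linalg.norm(ext - origin, axis=1)) < MIN_CLEARANCE:
        return None
    for _ in range(n - 1):
        for _ in range(max_step_retries):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * CA_BOND
            cand = trace[-1] + v
            own = np.array(trace[:-1]) if len(trace) > 1 else np.empty((0, 3))
            ok = True
            if len(own) and np.min(np.linalg.norm(own - cand, axis=1)) < MIN_CLEARANCE:
                ok = False
            if ok and len(ext) and np.min(np.linalg.norm(ext - cand, axis=1)) < MIN_CLEARANCE:
                ok = False
            if ok:
                trace.append(cand)
                break
        else:
            return None
    return trace


def apply_motion(
    model: StructureModel,
    registry: DomainRegistry,
    domain: str,
    angle_deg: float,
    axis: Sequence[float],
    translation: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    pivot: Sequence[float] | None = None,
    new_id: str | None = None,
) -> tuple[StructureModel, dict]:
    """Exact rigid transform of one registered domain plus optional Gaussian
    noise on *all* atoms.  Rotation is about ``pivot`` (default: the domain
    centroid), so with zero translation the domain COM is unmoved."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-9:
        warnings.warn("non-unit rotation axis normalized")
    axis = axis / norm
    translation = np.asarray(translation, dtype=float)
    sel = registry.get(domain)
    term_ranges = [r for t in sel.terms for r in (t.ranges or [])]
    dom_chains = {t.chain for t in sel.terms}

    def in_domain(a: AtomSite) -> bool:
        return a.chain_id in dom_chains and any(lo <= a.residue_number <= hi for lo, hi in term_ranges)

    R = rotation_matrix(axis, angle_deg)
    if pivot is None:
        dom_pos = np.array([a.position for a in model.atoms if in_domain(a)])
        pivot = dom_pos.mean(axis=0)
    pivot = np.asarray(pivot, dtype=float)

    rng = np.random.default_rng(seed)
    moving = angle_deg != 0.0 or np.any(translation != 0.0)
    atoms: list[AtomSite] = []
    for a in model.atoms:
        pos = a.position
        if moving and in_domain(a):
            # skip the rotation entirely at angle 0 so a zero motion is
            # bit-identical, not merely close
            pos = (R @ (pos - pivot) + pivot if angle_deg != 0.0 else pos) + translation
        if noise_sigma > 0:
            pos = pos + rng.normal(scale=noise_sigma, size=3)
        atoms.append(AtomSite(a.chain_id, a.residue_number, a.insertion_code,
                              a.residue_name, a.atom_name, a.element, pos,
                              a.occupancy, a.b_factor))
    out = StructureModel(new_id or f"{model.model_id}_moved", atoms)
    manifest = {
        "kind": "motion",
        "domain": domain,
        "angle_deg": float(angle_deg),
        "axis": axis.tolist(),
        "translation": translation.tolist(),
        "noise_sigma": float(noise_sigma),
        "seed": seed,
        "pivot": pivot.tolist(),
    }
    return out, manifest


def make_ensemble(
    states: list[tuple[str, StructureModel, str]],
    registry: DomainRegistry,
    chain_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> EnsembleSet:
    """Wrap (label, model, nucleotide) triples into an EnsembleSet."""
    return EnsembleSet(
        states=[(StateAnnotation(label=l, nucleotide=n), m) for l, m, n in states],
        registry=registry,
        chain_maps={k: dict(v) for k, v in (chain_maps or {}).items()},
    )


# ---------------------------------------------------------------------------
# DNA fixtures

def make_bdna(
    sequence: str,
    rise: float = BDNA_RISE,
    twist: float = BDNA_TWIST,
    start_register: int = -1,
    t_chain: str = "T",
    nt_chain: str = "N",
    kink: tuple[float, int] | None = None,
    groove_widening: tuple[float, tuple[int, int]] | None = None,
) -> tuple[StructureModel, dict[int, tuple[int, int]], dict]:
    """Ideal fiber-model B-DNA duplex (C1', P, OP1, OP2 per nucleotide).

    ``sequence`` is the t-strand 5'->3'; registers run from
    ``start_register`` downward going 3' on the t-strand... specifically the
    first (5') t-strand base sits at ``start_register`` and the register
    DECREASES by one per base (transcription coordinates: upstream more
    negative, so a duplex spanning −14…−43 is built from sequence[0] at −14).
    Returns (model, register_map, manifest); register_map maps register →
    (t residue number, nt residue number).

    ``kink=(angle_deg, register)`` bends the helix axis by the given angle
    between that register and the next more-negative one.
    ``groove_widening=(delta, (lo, hi))`` widens the short-diagonal minor
    groove by ``delta`` Å at every register in [lo, hi] (solved exactly per
    register by displacing the t-strand phosphate away from its cross-strand
    partners).
    """
    seq = sequence.upper()
    if len(seq) < 10:
        raise ValueError("sequence must be at least 10 nt")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence alphabet must be A, C, G, T")
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n = len(seq)
    registers = [start_register - i for i in range(n)]
    # base-pair centers and phases on a straight helix
    z = np.array([i * rise for i in range(n)], dtype=float)
    phase = np.array([math.radians(i * twist) for i in range(n)])

    def cyl(radius: float, ang: float, zz: float) -> np.ndarray:
        return np.array([radius * math.cos(ang), radius * math.sin(ang), zz])

    d_c1 = math.radians(C1_OFFSET_DEG)
    d_p = math.radians(P_OFFSET_DEG)
    atoms: list[AtomSite] = []
    register_map: dict[int, tuple[int, int]] = {}
    positions: dict[tuple[str, int, str], np.ndarray] = {}
    for i, reg in enumerate(registers):
        t_res = i + 1
        nt_res = i + 1
        register_map[reg] = (t_res, nt_res)
        t_base = seq[i]
        nt_base = comp[t_base]
        # sign convention: with registers decreasing along +z, the t-strand
        # phosphates at −δ face the nt-strand phosphates 2-5 registers
        # upstream at +δ across the minor groove (short diagonal)
        for chain, res, base, sign in (
            (t_chain, t_res, t_base, -1),
            (nt_chain, nt_res, nt_base, +1),
        ):
            c1 = cyl(C1_RADIUS, phase[i] + sign * d_c1, z[i])
            p = cyl(P_RADIUS, phase[i] + sign * d_p, z[i])
            u_out = np.array([math.cos(phase[i] + sign * d_p), math.sin(phase[i] + sign * d_p), 0.0])
            op1 = p + OP_LENGTH * u_out
            op2 = p + OP_LENGTH * np.array([0.0, 0.0, 1.0])
            resname = "D" + base
            for name, pos, elem in (("P", p, "P"), ("OP1", op1, "O"), ("OP2", op2, "O"), ("C1'", c1, "C")):
                atoms.append(AtomSite(chain, res, "", resname, name, elem, pos))

    # optional kink: rotate everything beyond the kink step about an in-plane axis
    kink_manifest = None
    if kink is not None:
        kangle, kreg = kink
        if kreg not in register_map:
            raise ValueError(f"kink register {kreg} outside the duplex")
        k_idx = registers.index(kreg)
        pivot = np.array([0.0, 0.0, z[k_idx] + 0.5 * rise])
        R = rotation_matrix(np.array([1.0, 0.0, 0.0]), kangle)
        for a in atoms:
            # atoms of base pairs past the kink step (larger z = more 3' on t)
            idx = a.residue_number - 1
            if idx > k_idx:
                a.position = R @ (a.position - pivot) + pivot
        kink_manifest = {"angle_deg": float(kangle), "register": int(kreg)}

    model = StructureModel(model_id="bdna", atoms=atoms)

    groove_manifest = None
    if groove_widening is not None:
        delta, (lo, hi) = groove_widening
        widened = _widen_minor_groove(model, t_chain, nt_chain, register_map, delta, lo, hi)
        groove_manifest = {"delta": float(delta), "registers": [int(lo), int(hi)],
                          "achieved": widened}

    manifest = {
        "kind": "bdna",
        "sequence": seq,
        "rise": float(rise),
        "twist": float(twist),
        "start_register": int(start_register),
        "kink": kink_manifest,
        "groove_widening": groove_manifest,
    }
    return model, register_map, manifest


def _widen_minor_groove(
    model: StructureModel,
    t_chain: str,
    nt_chain: str,
    register_map: Mapping[int, tuple[int, int]],
    delta: float,
    lo: int,
    hi: int,
    offsets: Sequence[int] = (2, 3, 4, 5),
) -> dict[int, float]:
    """Displace t-strand phosphates so the short-diagonal width at each
    register in [lo, hi] grows by exactly ``delta`` Å (per-register brentq
    solve; each t-strand P only enters its own register's width)."""
    t_p_atoms = {a.residue_number: a for a in model.atoms
                 if a.chain_id == t_chain and a.atom_name == "P"}
    nt_p = {a.residue_number: a.position for a in model.atoms
            if a.chain_id == nt_chain and a.atom_name == "P"}
    achieved: dict[int, float] = {}
    for reg in sorted(register_map):
        if not lo <= reg <= hi:
            continue
        t_res, _ = register_map[reg]
        partners = []
        for k in offsets:
            if reg + k in register_map:
                _, nt_res = register_map[reg + k]
                if nt_res in nt_p:
                    partners.append(nt_p[nt_res])
        if not partners:
            continue
        atom = t_p_atoms[t_res]
        p0 = atom.position.copy()
        base = min(np.linalg.norm(p0 - q) for q in partners)
        u = p0 - np.mean(partners, axis=0)
        u = u / np.linalg.norm(u)

        def width_gain(d: float) -> float:
            p = p0 + d * u
            return min(np.linalg.norm(p - q) for q in partners) - base - delta

        d_star = brentq(width_gain, 0.0, 10.0 + 2 * delta, xtol=1e-10)
        shift = d_star * u
        atom.position = p0 + shift
        # carry the attached phosphate oxygens along
        for name in ("OP1", "OP2"):
            for a in model.atoms:
                if a.chain_id == t_chain and a.residue_number == t_res and a.atom_name == name:
                    a.position = a.position + shift
        achieved[reg] = float(
            min(np.linalg.norm(atom.position - q) for q in partners) - base
        )
    return achieved


def add_contact_probes(
    model: StructureModel,
    register_map: Mapping[int, tuple[int, int]],
    t_chain: str,
    nt_chain: str,
    t_registers: Sequence[int],
    nt_registers: Sequence[int],
    distance: float = 3.0,
    probe_chain: str = "E",
) -> tuple[StructureModel, dict]:
    """Plant arginine-like probe atoms ``distance`` Å radially outward from
    the OP1 phosphate oxygen at the given registers of each strand.

    Each probe is one NH1 nitrogen of a pseudo-ARG residue, so the planted
    contacts class as hydrogen bonds under the distance-only criteria.
    """
    op1 = {}
    for a in model.atoms:
        if a.atom_name == "OP1":
            op1[(a.chain_id, a.residue_number)] = a.position
    atoms = list(model.atoms)
    resnum = 0
    for strand_chain, regs, which in ((t_chain, t_registers, 0), (nt_chain, nt_registers, 1)):
        for reg in regs:
            res_pair = register_map[reg]
            res = res_pair[which]
            pos = op1[(strand_chain, res)]
            u = pos.copy()
            u[2] = 0.0
            u = u / np.linalg.norm(u)
            resnum += 1
            atoms.append(
                AtomSite(probe_chain, resnum, "", "ARG", "NH1", "N", pos + distance * u)
            )
    out = StructureModel(model_id=model.model_id + "_probes", atoms=atoms)
    manifest = {
        "kind": "contact_probes",
        "t_registers": [int(r) for r in t_registers],
        "nt_registers": [int(r) for r in nt_registers],
        "distance": float(distance),
        "probe_chain": probe_chain,
    }
    return out, manifest


# ---------------------------------------------------------------------------
# scaffold sequences

def make_scaffold(
    upstream_bp: int,
    bubble_nt: int,
    downstream_bp: int,
    hybrid_bp: int,
    seed: int,
    max_retries: int = 200,
) -> tuple[dict[str, str], dict]:
    """Random scaffold sequences honoring the requested architecture.

    nt-strand (5'->3'): upstream duplex | bubble (non-complementary) |
    downstream duplex.  The RNA 3' end pairs the t-strand under the bubble,
    flush with the bubble's downstream edge.  The generated sequences are
    rejected and resampled until the sequence-level analysis recovers the
    spec exactly (longest 3'-anchored hybrid run, bubble boundaries).
    """
    if upstream_bp < 0 or bubble_nt < 0 or downstream_bp < 0 or hybrid_bp < 0:
        raise ValueError("contradictory spec: negative lengths")
    if hybrid_bp > bubble_nt:
        raise ValueError("contradictory spec: hybrid longer than the bubble")
    if bubble_nt > 0 and (upstream_bp < 2 or downstream_bp < 2):
        raise ValueError("contradictory spec: a bubble needs flanking duplexes (≥2 bp)")
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    to_rna = {"A": "U", "T": "A", "G": "C", "C": "G"}
    bases = "ACGT"
    rng = np.random.default_rng(seed)
    L = upstream_bp + bubble_nt + downstream_bp
    rna_extra = 4  # non-pairing 5' tail on the RNA

    from . import scaffold as _sc

    for _ in range(max_retries):
        t = "".join(rng.choice(list(bases), size=L))
        # nt-strand: reverse complement, then scramble the bubble positions
        nt = [comp[b] for b in t[::-1]]
        # bubble occupies nt positions [upstream, upstream+bubble)
        for i in range(upstream_bp, upstream_bp + bubble_nt):
            t_pos = L - 1 - i
            bad = comp[t[t_pos]]
            nt[i] = rng.choice([b for b in bases if b != bad])
        nt = "".join(nt)
        if hybrid_bp > 0:
            # hybrid t-strand segment: starts at t index = downstream_bp,
            # i.e. flush with the downstream edge of the bubble
            j0 = downstream_bp
            hyb = "".join(to_rna[t[j0 + k]] for k in range(hybrid_bp))[::-1]
            tail = "".join(rng.choice(list(bases.replace("T", "U")), size=rna_extra))
            rna = tail + hyb
            # the base 5' of the hybrid must not extend the run
            ext = to_rna[t[j0 + hybrid_bp]] if j0 + hybrid_bp < L else None
            if ext is not None and rna[-hybrid_bp - 1] == ext:
                continue
        else:
            rna = "".join(rng.choice(list("ACG"), size=rna_extra))
        # verify the spec is recovered exactly
        hlen, _, _ = _sc.hybrid_length(rna, t) if hybrid_bp > 0 else (0, None, None)
        if hybrid_bp > 0 and hlen != hybrid_bp:
            continue
        segs, up_len, _ = _sc.duplex_segmentation(nt, t, upstream="left")
        if bubble_nt > 0:
            kinds = [s.kind for s in segs]
            if kinds != ["duplex", "bubble", "duplex"]:
                continue
            if segs[0].length != upstream_bp or segs[1].length != bubble_nt:
                continue
        else:
            if [s.kind for s in segs] != ["duplex"]:
                continue
        seqs = {"t_strand": t, "nt_strand": nt, "rna": rna}
        manifest = {
            "kind": "scaffold",
            "upstream_bp": upstream_bp,
            "bubble_nt": bubble_nt,
            "downstream_bp": downstream_bp,
            "hybrid_bp": hybrid_bp,
            "seed": seed,
        }
        return seqs, manifest
    raise RuntimeError("could not generate a scaffold matching the spec")


def make_study_like_ensemble(seed: int) -> tuple[EnsembleSet, dict]:
    """Seven synthetic states shaped like a loading-plus-cycle ensemble.

    Two 'loading' states (L1, L2) place the mobile domain far from its
    cycle position (large rotations plus tens-of-Å translations), and five
    'cycle' states (C1-C5) differ only by small successive rotations, so the
    ensemble has the planted structure: a tight C cluster, outlying L
    states, and a minimal-cumulative-RMSD chain L1-L2-C1-C2-C3-C4-C5.
    """
    base, registry, _ = make_multidomain(2, 90, seed=seed)
    from .model import Selection, SelectionTerm
    registry.add(Selection("whole", [SelectionTerm("A", atom_names=("CA",))]), "synthetic")
    axis = [0.0, 1.0, 0.0]
    placements = {
        "L1": (-60.0, [28.0, 20.0, 5.0], "atp"),
        "L2": (-30.0, [18.0, 8.0, 2.0], "adp"),
        "C1": (0.0, [0.0, 0.0, 0.0], "ATP"),
        "C2": (4.0, [0.0, 0.0, 0.0], "ATP"),
        "C3": (8.0, [0.0, 0.0, 0.0], "adp"),
        "C4": (12.0, [0.0, 0.0, 0.0], "ADP"),
        "C5": (16.0, [0.0, 0.0, 0.0], "ATP"),
    }
    states = []
    for label, (angle, shift, nuc) in placements.items():
        model, _ = apply_motion(base, registry, "dom2", angle, axis, shift,
                                new_id=label)
        states.append((label, model, nuc))
    ens = make_ensemble(states, registry)
    truth = {
        "path": ["L1", "L2", "C1", "C2", "C3", "C4", "C5"],
        "loading": ["L1", "L2"],
        "cycle": ["C1", "C2", "C3", "C4", "C5"],
        "placements": {k: {"angle_deg": v[0], "translation": v[1]}
                       for k, v in placements.items()},
    }
    return ens, truth


# ---------------------------------------------------------------------------
# the standard recovery batch

def make_fixture_suite(seed: int) -> list[dict]:
    """The package's standard batch of 20 ground-truth fixtures.

    Each entry is {"name", "kind", "truth", ...payload}.  The planted
    parameters mirror the study conditions the package is built to analyze:
    a 16° translocase-domain rotation with a 3.5 Å axial COM shift (one
    base-pair rise of B-DNA), clamp-style openings up to 17.3°, DNA kinks of
    7-20°, minor-groove widenings, a +9-register footprint walk, and
    scaffolds with a 9-bp 3'-hybrid in a non-complementary bubble.
    """
    rng = np.random.default_rng(seed)
    fixtures: list[dict] = []

    def sub() -> int:
        return int(rng.integers(0, 2**31 - 1))

    dna_axis = np.array([0.0, 0.0, 1.0])
    perp_axis = np.array([1.0, 0.0, 0.0])

    # -- rigid domain rotations (anchor dom1, mobile dom2) -------------------
    inchworm = [
        ("inchworm_16deg_clean", 16.0, 3.5, 0.0),
        ("inchworm_16deg_noisy", 16.0, 3.5, 0.3),
    ]
    for name, ang, shift, sigma in inchworm:
        s = sub()
        base, reg, _ = make_multidomain(2, 150, seed=s)
        moved, man = apply_motion(
            base, reg, "dom2", ang, perp_axis, shift * dna_axis,
            noise_sigma=sigma, seed=s + 1, new_id="B",
        )
        ens = make_ensemble([("A", base, "ATP"), ("B", moved, "ADP")], reg)
        fixtures.append({
            "name": name, "kind": "domain_motion", "ensemble": ens,
            "anchor": "dom1", "domain": "dom2", "reference_axis": dna_axis,
            "truth": {"angle_deg": ang, "axial_shift": shift, "noise_sigma": sigma,
                      "motion_manifest": man},
        })
    for ang in (37.0, 43.0, 102.0, 148.0):
        s = sub()
        base, reg, _ = make_multidomain(2, 120, seed=s)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        moved, man = apply_motion(base, reg, "dom2", ang, axis, [0, 0, 0],
                                  seed=s + 1, new_id="B")
        ens = make_ensemble([("A", base, "atp"), ("B", moved, "adp")], reg)
        fixtures.append({
            "name": f"rotation_{ang:g}deg", "kind": "domain_motion", "ensemble": ens,
            "anchor": "dom1", "domain": "dom2", "reference_axis": None,
            "truth": {"angle_deg": ang, "axial_shift": None, "noise_sigma": 0.0,
                      "motion_manifest": man},
        })

    # -- clamp-style opening series vs a reference state ---------------------
    s = sub()
    base, reg, _ = make_multidomain(2, 100, seed=s)
    openings = {"C1": 0.0, "C2": 5.0, "C3": 17.3}
    states = []
    for label, ang in openings.items():
        m, _ = apply_motion(base, reg, "dom2", ang, perp_axis, [0, 0, 0],
                            seed=s + 2, new_id=label)
        states.append((label, m, "ATP"))
    ens = make_ensemble(states, reg)
    fixtures.append({
        "name": "clamp_opening_series", "kind": "reference_zero",
        "ensemble": ens, "anchor": "dom1", "domain": "dom2", "reference": "C1",
        "truth": {"angles": dict(openings)},
    })

    # -- wobble: whole-body rocking across three states ----------------------
    s = sub()
    base, reg, _ = make_multidomain(2, 100, seed=s)
    wobbles = {"C1": 0.0, "C2": 15.0, "C3": 31.0}
    states = []
    for label, ang in wobbles.items():
        m, _ = apply_motion(base, reg, "dom2", ang, perp_axis, [0, 0, 0],
                            seed=s + 3, new_id=label)
        states.append((label, m, "ATP"))
    ens = make_ensemble(states, reg)
    fixtures.append({
        "name": "wobble_series", "kind": "wobble", "ensemble": ens,
        "anchor": "dom1", "body": "dom2",
        "truth": {"max_angle": max(wobbles.values())},
    })

    # -- DNA kinks -----------------------------------------------------------
    for kink in (7.0, 10.0, 15.0, 20.0):
        srng = np.random.default_rng(sub())
        seq = "".join(srng.choice(list("ACGT"), size=30))
        model, regmap, man = make_bdna(seq, start_register=-14, kink=(kink, -24))
        fixtures.append({
            "name": f"kink_{kink:g}deg", "kind": "dna_kink",
            "model": model, "register_map": regmap,
            "truth": {"kink_deg": kink, "kink_register": -24, "manifest": man},
        })

    # -- minor-groove widening ----------------------------------------------
    for delta in (2.0, 3.0):
        srng = np.random.default_rng(sub())
        seq = "".join(srng.choice(list("ACGT"), size=30))
        model, regmap, man = make_bdna(
            seq, start_register=-14, groove_widening=(delta, (-30, -27))
        )
        baseline_model, baseline_map, _ = make_bdna(seq, start_register=-14)
        fixtures.append({
            "name": f"groove_plus_{delta:g}A", "kind": "groove",
            "model": model, "register_map": regmap,
            "baseline_model": baseline_model,
            "truth": {"delta": delta, "registers": (-30, -27), "manifest": man},
        })

    # -- footprint register walk --------------------------------------------
    for name, regs_a, regs_b, shift in (
        ("footprint_walk_plus9",
         list(range(-38, -26)), list(range(-29, -17)), 9),
        ("footprint_walk_minus3",
         list(range(-30, -20)), list(range(-33, -23)), -3),
    ):
        srng = np.random.default_rng(sub())
        seq = "".join(srng.choice(list("ACGT"), size=44))
        dna, regmap, _ = make_bdna(seq, start_register=-4)
        # ~60% of planted contacts on the t-strand, as in the study system
        def split(regs):
            nt = [r for i, r in enumerate(regs) if i % 5 in (0, 2)]
            t = [r for i, r in enumerate(regs) if i % 5 not in (0, 2)]
            return t, nt

        t_a, nt_a = split(regs_a)
        t_b, nt_b = split(regs_b)
        model_a, _ = add_contact_probes(dna, regmap, "T", "N", t_a, nt_a)
        model_b, _ = add_contact_probes(dna, regmap, "T", "N", t_b, nt_b)
        fixtures.append({
            "name": name, "kind": "footprint_shift",
            "model_a": model_a, "model_b": model_b, "register_map": regmap,
            "truth": {"shift": shift, "registers_a": regs_a, "registers_b": regs_b},
        })

    # -- scaffolds -----------------------------------------------------------
    for spec in ((40, 11, 11, 9), (20, 12, 8, 6)):
        s = sub()
        seqs, man = make_scaffold(*spec, seed=s)
        fixtures.append({
            "name": f"scaffold_{spec[0]}_{spec[1]}_{spec[2]}_{spec[3]}",
            "kind": "scaffold", "sequences": seqs,
            "truth": {"upstream_bp": spec[0], "bubble_nt": spec[1],
                      "downstream_bp": spec[2], "hybrid_bp": spec[3],
                      "manifest": man},
        })

    assert len(fixtures) == 18
    # two extra single-rotation recoveries at random angles to round out the batch
    for i in range(2):
        s = sub()
        ang = float(np.round(rng.uniform(5, 175), 1))
        base, reg, _ = make_multidomain(2, 80, seed=s)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        moved, man = apply_motion(base, reg, "dom2", ang, axis, [0, 0, 0],
                                  seed=s + 1, new_id="B")
        ens = make_ensemble([("A", base, "ATP"), ("B", moved, "ADP")], reg)
        fixtures.append({
            "name": f"rotation_random_{i + 1}", "kind": "domain_motion",
            "ensemble": ens, "anchor": "dom1", "domain": "dom2",
            "reference_axis": None,
            "truth": {"angle_deg": ang, "axial_shift": None, "noise_sigma": 0.0,
                      "motion_manifest": man},
        })
    assert len(fixtures) == 20
    return fixtures
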