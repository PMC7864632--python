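"""Rigid-body motion of a named domain between two conformational states.

The procedure is fixed: (1) anchor state B onto state A by iterative
superposition over the anchor selection; (2) Kabsch-fit the domain's paired
Cα between the two anchored placements; (3) extract rotation angle/axis and
a screw decomposition; (4) report the domain center-of-mass displacement and
its signed projection onto an optional reference axis (e.g. the upstream DNA
helical axis, positive pointing downstream).

Rotation angles are reported in [0, 180°].  A corkscrew winding of more than
half a turn around an axis (such as a 259° walk around a DNA duplex) is not
distinguishable from its 360°-complement by a single rotation matrix; the
descriptor therefore also carries a winding sense (the sign of the screw
axis projected on the reference axis) so callers can reconstruct the handed
interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import EnsembleSet, pair_common_residues
from .superpose import RigidTransform, iterative_align, kabsch

__all__ = [
    "MotionDescriptor",
    "rotation_angle_axis",
    "anchored_domain_motion",
    "reference_zero_angles",
    "wobble_angle",
]


@dataclass
class MotionDescriptor:
    domain_name: str
    state_from: str
    state_to: str
    angle_deg: float  # in [0, 180]
    axis: np.ndarray  # unit 3-vector
    screw_point: np.ndarray  # point on the rotation axis, Å
    screw_translation: float  # translation along the axis, Å
    com_displacement: np.ndarray  # 3-vector, Å
    com_displacement_norm: float
    axial_projection: float | None  # signed Å along the reference axis
    winding_sense: float | None  # sign(axis · reference axis); handedness hint
    anchor_selection: str
    anchor_rmsd: float
    anchor_provenance: str = ""

    def __post_init__(self) -> None:
        assert -1e-9 <= self.angle_deg <= 180 + 1e-9
        assert abs(np.linalg.norm(self.axis) - 1.0) < 1e-6
        if self.axial_projection is not None:
            assert abs(self.axial_projection) <= self.com_displacement_norm + 1e-9


def rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, [0, 180]) and unit axis of a proper rotation matrix.

    Near 180° the antisymmetric part vanishes, so the axis is taken from the
    +1 eigenvector with a deterministic sign (largest-magnitude component
    made positive).
    """
    R = np.asarray(R, dtype=float)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = math.degrees(math.acos(cos_theta))
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(v)
    if norm > 1e-8 and angle < 179.0:
        axis = v / norm
    else:
        # eigenvector of R for eigenvalue +1
        w, vec = np.linalg.eigh((R + R.T) / 2.0)
        axis = vec[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)
        i = int(np.argmax(np.abs(axis)))
        if axis[i] < 0:
            axis = -axis
        if norm > 1e-12 and float(v @ axis) < 0:
            axis = -axis
    if angle < 1e-10:
        axis = np.array([1.0, 0.0, 0.0])  # conventional axis for identity
    return angle, axis


def _screw_point(R: np.ndarray, t: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Point on the rotation axis minimizing the translation norm.

    Solves (I − R) p = t⊥ in least squares; (I − R) is singular along the
    axis, so the minimum-norm solution pins the axial component to zero.
    """
    t_perp = t - (t @ axis) * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return p - (p @ axis) * axis


def anchored_domain_motion(
    ensemble: EnsembleSet,
    anchor_selection: str,
    domain_selection: str,
    state_from: str,
    state_to: str,
    reference_axis: np.ndarray | None = None,
    cycles: int = 5,
    reject_factor: float = 2.0,
) -> MotionDescriptor:
    """Quantify the motion of ``domain_selection`` from one state to another
    after anchoring both states on ``anchor_selection``."""
    anchor_from = ensemble.resolve(state_from, anchor_selection)
    anchor_to = ensemble.resolve(state_to, anchor_selection)
    Pa, Qa, _, _ = pair_common_residues(anchor_from, anchor_to)
    anchored = iterative_align(Pa, Qa, cycles=cycles, reject_factor=reject_factor)

    dom_from = ensemble.resolve(state_from, domain_selection)
    dom_to = ensemble.resolve(state_to, domain_selection)
    Pd, Qd, _, _ = pair_common_residues(dom_from, dom_to)
    if len(Pd) < 3:
        raise ValueError(f"degenerate domain {domain_selection!r} (<3 paired Cα)")
    Qd_anchored = anchored.transform.apply(Qd)

    # transform carrying the from-placement onto the anchored to-placement
    move, _ = kabsch(Qd_anchored, Pd)
    angle, axis = rotation_angle_axis(move.rotation)
    screw_t = float(move.translation @ axis)
    spoint = _screw_point(move.rotation, move.translation, axis)

    com_disp = Qd_anchored.mean(axis=0) - Pd.mean(axis=0)
    com_norm = float(np.linalg.norm(com_disp))
    axial = None
    winding = None
    if reference_axis is not None:
        u = np.asarray(reference_axis, dtype=float)
        u = u / np.linalg.norm(u)
        axial = float(com_disp @ u)
        winding = float(np.sign(axis @ u)) if angle > 1e-6 else 0.0

    return MotionDescriptor(
        domain_name=domain_selection,
        state_from=state_from,
        state_to=state_to,
        angle_deg=angle,
        axis=axis,
        screw_point=spoint,
        screw_translation=screw_t,
        com_displacement=com_disp,
        com_displacement_norm=com_norm,
        axial_projection=axial,
        winding_sense=winding,
        anchor_selection=anchor_selection,
        anchor_rmsd=anchored.rmsd_kept,
        anchor_provenance=ensemble.registry.provenance.get(anchor_selection, ""),
    )


def reference_zero_angles(
    ensemble: EnsembleSet,
    domain_selection: str,
    anchor_selection: str = "RNAP_core",
    reference_state: str = "C1",
    **kwargs,
) -> dict[str, float]:
    """Per-state rotation angle of a domain relative to a reference state.

    The reference state's own entry is exactly 0 by convention (clamp
    opening and βlobe-Si1 rotation are defined as zero in the reference).
    """
    if reference_state not in ensemble.labels:
        raise KeyError(f"reference state {reference_state!r} not in ensemble")
    out: dict[str, float] = {}
    for label in ensemble.labels:
        if label == reference_state:
            out[label] = 0.0
            continue
        desc = anchored_domain_motion(
            ensemble, anchor_selection, domain_selection,
            reference_state, label, **kwargs,
        )
        out[label] = desc.angle_deg
    return out


def wobble_angle(
    ensemble: EnsembleSet,
    body_selection: str,
    anchor_selection: str = "RNAP_core",
    labels: list[str] | None = None,
    **kwargs,
) -> tuple[float, tuple[str, str]]:
    """Maximum pairwise rigid-body rotation of ``body_selection`` across the
    given states (default: all) after anchoring each pair on the anchor.

    Measures how much a body (e.g. the whole translocase plus the upstream
    DNA) rocks back and forth on the face of the anchored core.
    """
    labels = list(labels) if labels is not None else list(ensemble.labels)
    if len(labels) < 2:
        raise ValueError("need at least two states")
    best = 0.0
    best_pair = (labels[0], labels[1])
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            desc = anchored_domain_motion(
                ensemble, anchor_selection, body_selection,
                labels[i], labels[j], **kwargs,
            )
            if desc.angle_deg > best:
                best = desc.angle_deg
                best_pair = (labels[i], labels[j])
    return best, best_pair
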