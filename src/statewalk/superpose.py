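"""Least-squares superposition and pairwise RMSD matrices.

Two RMSD flavors are computed throughout, mirroring the two conventions used
when comparing cryo-EM states:

* ``rmsd_kept`` — after iterative outlier rejection, over the retained pairs
  (the "align"-style value);
* ``rmsd_all`` — over *all* initially paired atoms under the final transform
  (the "rms_cur"-style value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EnsembleSet, pair_common_residues

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "RMSDMatrix",
    "kabsch",
    "iterative_align",
    "pairwise_rmsd_matrix",
    "DegenerateGeometryError",
]

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant is not +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd_kept: float
    rmsd_all: float
    n_start: int
    n_kept: int
    cycles_run: int
    kept_mask: np.ndarray = field(repr=False, default=None)


def _check_nondegenerate(X: np.ndarray) -> None:
    """≥3 points that are not all (nearly) collinear."""
    if len(X) < 3:
        raise DegenerateGeometryError("fewer than 3 pairs; superposition undefined")
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-8:
        raise DegenerateGeometryError("degenerate configuration (collinear points)")


def kabsch(
    P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None
) -> tuple[RigidTransform, float]:
    """Optimal proper rotation + translation mapping Q onto P.

    Minimizes the (weighted) sum of squared deviations ``|T(Q) - P|²``;
    reflections are excluded by flipping the sign of the smallest singular
    direction when the raw solution has determinant −1.  Returns the
    transform and the resulting RMSD in Å.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    _check_nondegenerate(P)
    _check_nondegenerate(Q)
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    pc = (w[:, None] * P).sum(axis=0) / wsum
    qc = (w[:, None] * Q).sum(axis=0) / wsum
    Pc, Qc = P - pc, Q - qc
    H = (w[:, None] * Qc).T @ Pc  # 3x3 covariance, maps Q-frame to P-frame
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    transform = RigidTransform(R, t)
    dev = transform.apply(Q) - P
    rmsd = math.sqrt(float((w * (dev**2).sum(axis=1)).sum() / wsum))
    return transform, rmsd


def iterative_align(
    P: np.ndarray,
    Q: np.ndarray,
    cycles: int = 5,
    reject_factor: float = 2.0,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Kabsch fit with iterative outlier rejection.

    Each cycle fits, then drops pairs whose deviation exceeds
    ``reject_factor × rmsd`` of the current fit.  Stops when no pair is
    dropped, cycles are exhausted, or fewer than 3 pairs would remain (the
    previous set is then kept).  ``rmsd_all`` is evaluated over the original
    full pairing under the final transform.
    """
    if reject_factor <= 0:
        raise ValueError("reject_factor must be positive")
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    n = len(P)
    keep = np.ones(n, dtype=bool)
    transform, rmsd = kabsch(P, Q, weights)
    cycles_run = 0
    for _ in range(max(cycles, 0)):
        dev = np.linalg.norm(transform.apply(Q) - P, axis=1)
        # numerical floor keeps an (almost) exact fit from rejecting
        # everything once rmsd underflows
        threshold = reject_factor * max(rmsd, 1e-6)
        new_keep = keep & (dev <= threshold)
        if new_keep.sum() == keep.sum():
            break
        if new_keep.sum() < 3:
            break
        keep = new_keep
        cycles_run += 1
        w = None if weights is None else np.asarray(weights)[keep]
        transform, rmsd = kabsch(P[keep], Q[keep], w)
    dev_all = np.linalg.norm(transform.apply(Q) - P, axis=1)
    rmsd_all = math.sqrt(float((dev_all**2).mean()))
    return SuperpositionResult(
        transform=transform,
        rmsd_kept=rmsd,
        rmsd_all=rmsd_all,
        n_start=n,
        n_kept=int(keep.sum()),
        cycles_run=cycles_run,
        kept_mask=keep,
    )


@dataclass
class RMSDMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, Å
    mode: str  # "kept" or "all"
    selection_name: str
    max_asymmetry: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.abs(np.diag(self.values)).max() > 1e-9:
            raise ValueError("diagonal must be zero")
        if np.abs(self.values - self.values.T).max() > 1e-9:
            raise ValueError("matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("rmsd entries must be non-negative")

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, mode: str = "all", selection_name: str = "") -> "RMSDMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), mode, selection_name)


def pairwise_rmsd_matrix(
    ensemble: EnsembleSet,
    selection_name: str,
    mode: str = "kept",
    cycles: int = 5,
    reject_factor: float = 2.0,
) -> RMSDMatrix:
    """All-against-all RMSD over one registry selection.

    Entry (i, j) averages the j-onto-i and i-onto-j alignments (outlier
    rejection makes the two directions differ slightly); the maximum
    asymmetry observed before averaging is recorded on the matrix.
    """
    if mode not in ("kept", "all"):
        raise ValueError("mode must be 'kept' or 'all'")
    labels = ensemble.labels
    sets = {lab: ensemble.resolve(lab, selection_name) for lab in labels}
    n = len(labels)
    values = np.zeros((n, n))
    max_asym = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                P, Q, _, _ = pair_common_residues(sets[labels[i]], sets[labels[j]])
                fwd = iterative_align(P, Q, cycles=cycles, reject_factor=reject_factor)
                rev = iterative_align(Q, P, cycles=cycles, reject_factor=reject_factor)
            except Exception as exc:
                raise RuntimeError(
                    f"superposition failed for state pair "
                    f"({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            a = fwd.rmsd_kept if mode == "kept" else fwd.rmsd_all
            b = rev.rmsd_kept if mode == "kept" else rev.rmsd_all
            max_asym = max(max_asym, abs(a - b))
            values[i, j] = values[j, i] = 0.5 * (a + b)
    return RMSDMatrix(
        labels=list(labels),
        values=values,
        mode=mode,
        selection_name=selection_name,
        max_asymmetry=max_asym,
    )
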