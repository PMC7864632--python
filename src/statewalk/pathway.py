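"""Pathway ordering of a conformational ensemble.

Given a pairwise RMSD matrix and an anchor state (chosen as the state most
similar to an external reference structure, e.g. the free/apo form of the
mobile factor), the ensemble is ordered by exhaustively enumerating every
open path starting at the anchor and keeping the one with the smallest
cumulative RMSD.  Exact enumeration only — no heuristic fallback.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import EnsembleSet, StructureModel, Selection, pair_common_residues, select_coordinates
from .superpose import RMSDMatrix, iterative_align

__all__ = [
    "PathOrder",
    "anchor_state",
    "min_cumulative_path",
    "loading_vs_cycle_partition",
    "AmbiguousAnchorError",
    "NoGapError",
]

MAX_EXACT_STATES = 12


class AmbiguousAnchorError(ValueError):
    pass


class NoGapError(ValueError):
    pass


@dataclass
class PathOrder:
    labels: list[str]  # permutation of the ensemble labels
    cumulative_rmsd: float
    anchor_label: str
    anchor_reference_rmsd: float | None
    enumeration_size: int
    top_paths: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


def anchor_state(
    ensemble: EnsembleSet,
    reference: StructureModel,
    selection: Selection | str,
    reference_chain_map: dict[str, str] | None = None,
    cycles: int = 5,
    reject_factor: float = 2.0,
    tie_tol: float = 1e-6,
) -> tuple[str, dict[str, float]]:
    """State with minimal full-pairing RMSD to an external reference model.

    Returns the chosen label and the full label → RMSD table.  A tie within
    ``tie_tol`` Å is an error demanding an explicit choice.
    """
    if isinstance(selection, str):
        selection = ensemble.registry.get(selection)
    ref_set = select_coordinates(reference, selection, chain_map=reference_chain_map)
    table: dict[str, float] = {}
    for label in ensemble.labels:
        state_set = ensemble.resolve(label, selection)
        P, Q, _, _ = pair_common_residues(ref_set, state_set)
        res = iterative_align(P, Q, cycles=cycles, reject_factor=reject_factor)
        table[label] = res.rmsd_all
    ordered = sorted(table.items(), key=lambda kv: kv[1])
    if len(ordered) > 1 and ordered[1][1] - ordered[0][1] < tie_tol:
        raise AmbiguousAnchorError(
            f"anchor tie between {ordered[0][0]!r} and {ordered[1][0]!r} "
            f"(Δrmsd < {tie_tol} Å); choose explicitly"
        )
    return ordered[0][0], table


def min_cumulative_path(
    matrix: RMSDMatrix,
    start_label: str,
    closed: bool = False,
    n_top: int = 10,
) -> PathOrder:
    """Exact minimal-cumulative-RMSD ordering starting at ``start_label``.

    Enumerates all (n−1)! orderings of the remaining states; ties are broken
    lexicographically by the ordered label sequence, so the result is
    independent of the input label order.  ``closed`` additionally charges
    the return leg to the start (a conformational cycle rather than a path).
    """
    labels = list(matrix.labels)
    if start_label not in labels:
        raise KeyError(f"start label {start_label!r} not in matrix")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two states")
    if n > MAX_EXACT_STATES:
        raise ValueError(
            f"{n} states exceeds the exact-enumeration limit of {MAX_EXACT_STATES}"
        )
    rest = sorted(l for l in labels if l != start_label)  # lexicographic base order
    idx = {l: i for i, l in enumerate(labels)}
    V = matrix.values

    best_cost = math.inf
    best_seq: tuple[str, ...] | None = None
    scored: list[tuple[float, tuple[str, ...]]] = []
    count = 0
    for perm in itertools.permutations(rest):
        count += 1
        seq = (start_label,) + perm
        cost = 0.0
        for a, b in zip(seq, seq[1:]):
            cost += V[idx[a], idx[b]]
        if closed:
            cost += V[idx[seq[-1]], idx[start_label]]
        scored.append((cost, seq))
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and (best_seq is None or seq < best_seq)
        ):
            best_cost = cost
            best_seq = seq
    scored.sort(key=lambda cs: (cs[0], cs[1]))
    top = [(seq, cost) for cost, seq in scored[:n_top]]
    assert count == math.factorial(n - 1)
    return PathOrder(
        labels=list(best_seq),
        cumulative_rmsd=best_cost,
        anchor_label=start_label,
        anchor_reference_rmsd=None,
        enumeration_size=count,
        top_paths=top,
    )


def loading_vs_cycle_partition(
    matrix: RMSDMatrix, gap_tol: float = 1e-9
) -> tuple[list[str], list[str], dict[str, float]]:
    """Split the ensemble into two groups by single-linkage clustering.

    Designed for ensembles whose states fall into a loosely-related group
    (e.g. loading intermediates) and a tight cluster (e.g. the hydrolysis-
    cycle states): the dendrogram is cut at its final merge, and the
    separation between the two groups must exceed the spread within them,
    otherwise a NoGapError is raised.

    Returns (group_1, group_2, stats) where stats reports within-group max
    and between-group min distances and their gap.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("need at least three states to partition")
    condensed = squareform(matrix.values, checks=False)
    Z = linkage(condensed, method="single")
    assignment = fcluster(Z, t=2, criterion="maxclust")
    if len(set(assignment)) < 2:
        raise NoGapError("single-linkage produced no 2-way split (all distances tied)")
    g1 = [l for l, c in zip(matrix.labels, assignment) if c == 1]
    g2 = [l for l, c in zip(matrix.labels, assignment) if c == 2]
    within = 0.0
    between = math.inf
    for i in range(n):
        for j in range(i + 1, n):
            same = assignment[i] == assignment[j]
            v = matrix.values[i, j]
            if same:
                within = max(within, v)
            else:
                between = min(between, v)
    gap = between - within
    if gap <= gap_tol:
        raise NoGapError(
            f"no gap: between-group min {between:.3g} Å does not exceed "
            f"within-group max {within:.3g} Å"
        )
    stats = {"within_max": within, "between_min": between, "gap": gap}
    return g1, g2, stats
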