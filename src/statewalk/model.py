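"""Core data model: atomic sites, structure models, selections, ensembles.

Everything downstream (superposition, domain motions, DNA geometry, interface
areas) consumes the containers defined here.  Residue numbering is always the
author numbering of the deposited model — no renumbering is ever performed,
because all domain anchors used in this package (e.g. the Mfd relay helix
548-577, the TD1 core 580-780) are author numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "AtomSite",
    "StructureModel",
    "SelectionTerm",
    "Selection",
    "DomainRegistry",
    "StateAnnotation",
    "EnsembleSet",
    "CoordinateSet",
    "select_coordinates",
    "pair_common_residues",
    "SelectionError",
]


class SelectionError(ValueError):
    """A selection failed to resolve on a model."""


@dataclass
class AtomSite:
    """One atomic site of a coordinate model (author numbering, 1-based)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.atom_name)


@dataclass
class StructureModel:
    """Ordered atomic sites of one coordinate model."""

    model_id: str
    atoms: list[AtomSite]
    source: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom site {a.key} in model {self.model_id!r}")
            seen.add(a.key)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every position mapped through x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            dataclasses.replace(a, position=R @ a.position + t) for a in self.atoms
        ]
        return StructureModel(self.model_id, atoms, source=self.source, metadata=dict(self.metadata))


@dataclass
class SelectionTerm:
    """One clause of a selection: a chain (ID or role name), optional inclusive
    1-based residue ranges, optional atom-name filter."""

    chain: str
    ranges: tuple[tuple[int, int], ...] | None = None  # None = all residues
    atom_names: tuple[str, ...] | None = None  # None = all atoms

    def __post_init__(self) -> None:
        if self.ranges is not None:
            self.ranges = tuple((int(a), int(b)) for a, b in self.ranges)
            for lo, hi in self.ranges:
                if hi < lo:
                    raise ValueError(f"empty residue range {lo}-{hi}")
        if self.atom_names is not None:
            self.atom_names = tuple(self.atom_names)

    def covers_residue(self, resnum: int) -> bool:
        if self.ranges is None:
            return True
        return any(lo <= resnum <= hi for lo, hi in self.ranges)

    def expected_residues(self) -> list[int] | None:
        if self.ranges is None:
            return None
        out: list[int] = []
        for lo, hi in self.ranges:
            out.extend(range(lo, hi + 1))
        return out


@dataclass
class Selection:
    name: str
    terms: list[SelectionTerm]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"selection {self.name!r} has no terms")


@dataclass
class DomainRegistry:
    """Named residue-range selections plus a provenance note per entry."""

    entries: dict[str, Selection] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    MANDATORY = (
        "D1a", "D2", "D1b", "D3", "D4_RID", "D5_TD1", "D6_TD2", "D7", "RH",
        "TD1_superposition_core", "TD2_mobile", "clamp", "beta_protrusion",
        "beta_lobe_Si1", "RNAP_core",
    )

    def add(self, selection: Selection, provenance: str) -> None:
        self.entries[selection.name] = selection
        self.provenance[selection.name] = provenance

    def get(self, name: str) -> Selection:
        try:
            return self.entries[name]
        except KeyError:
            raise SelectionError(f"registry has no entry named {name!r}") from None

    def validate_mandatory(self) -> None:
        missing = [n for n in self.MANDATORY if n not in self.entries]
        if missing:
            raise ValueError(f"registry is missing mandatory entries: {missing}")


@dataclass
class StateAnnotation:
    """Label + nucleotide status of one ensemble member.

    Lowercase nucleotide codes ('atp'/'adp') mark states whose nucleotide was
    inferred rather than directly observed in the density.
    """

    label: str
    nucleotide: str = "unknown"
    pathway_index: int | None = None

    VALID_NUCLEOTIDES = {"ATP", "ADP", "atp", "adp", "unknown"}

    def __post_init__(self) -> None:
        if self.nucleotide not in self.VALID_NUCLEOTIDES:
            raise ValueError(f"invalid nucleotide code {self.nucleotide!r}")


@dataclass
class CoordinateSet:
    """Resolved coordinates of a selection on one model.

    ``keys`` carry (chain role-or-ID, residue_number, insertion_code,
    atom_name) identities so two sets from different models can be paired.
    """

    selection_name: str
    keys: list[tuple[str, int, str, str]]
    coords: np.ndarray  # (n, 3)
    elements: list[str]
    residue_names: list[str]
    n_expected: int | None = None
    missing_residues: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def coverage(self) -> float | None:
        if self.n_expected is None or self.n_expected == 0:
            return None
        return len(self.keys) / self.n_expected

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def _resolve_chain(term_chain: str, chain_map: Mapping[str, str] | None) -> tuple[str, str]:
    """Return (actual chain id, role-or-id key used for pairing)."""
    if chain_map is not None and term_chain in chain_map:
        return chain_map[term_chain], term_chain
    return term_chain, term_chain


def select_coordinates(
    model: StructureModel,
    selection: Selection,
    chain_map: Mapping[str, str] | None = None,
) -> CoordinateSet:
    """Resolve a selection on a model.

    Atoms are returned in (chain, residue_number, insertion_code) order within
    each term.  Residues named in the selection but absent from the model are
    silently dropped and reported through ``missing_residues`` / ``coverage``.
    Resolving to zero atoms is an error naming the selection.
    """
    keys: list[tuple[str, int, str, str]] = []
    coords: list[np.ndarray] = []
    elements: list[str] = []
    resnames: list[str] = []
    missing: list[tuple[str, int]] = []
    n_expected = 0
    have_expected = True

    by_chain: dict[str, list[AtomSite]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain_id, []).append(a)

    for term in selection.terms:
        chain_id, pair_key = _resolve_chain(term.chain, chain_map)
        atoms = by_chain.get(chain_id, [])
        picked = [
            a for a in atoms
            if term.covers_residue(a.residue_number)
            and (term.atom_names is None or a.atom_name in term.atom_names)
        ]
        picked.sort(key=lambda a: (a.residue_number, a.insertion_code, a.atom_name))
        for a in picked:
            keys.append((pair_key, a.residue_number, a.insertion_code, a.atom_name))
            coords.append(a.position)
            elements.append(a.element)
            resnames.append(a.residue_name)
        expected = term.expected_residues()
        if expected is None:
            have_expected = False
        else:
            n_expected += len(expected) * (len(term.atom_names) if term.atom_names else 1)
            present = {a.residue_number for a in picked}
            missing.extend((pair_key, r) for r in expected if r not in present)

    if not keys:
        raise SelectionError(
            f"selection {selection.name!r} resolves to 0 atoms on model {model.model_id!r}"
        )
    return CoordinateSet(
        selection_name=selection.name,
        keys=keys,
        coords=np.array(coords, dtype=float),
        elements=elements,
        residue_names=resnames,
        n_expected=n_expected if have_expected else None,
        missing_residues=missing,
    )


def pair_common_residues(
    a: CoordinateSet, b: CoordinateSet
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str, str]], int]:
    """Pair two coordinate sets on (chain role, residue, insertion code, atom).

    Returns (P, Q, paired_keys, n_dropped) with P from ``a`` and Q from ``b``
    in a deterministic sorted key order.  Fewer than 3 pairs is an error
    (superposition is undefined below that).
    """
    index_a = {k: i for i, k in enumerate(a.keys)}
    index_b = {k: i for i, k in enumerate(b.keys)}
    common = sorted(set(index_a) & set(index_b))
    n_dropped = (len(a) - len(common)) + (len(b) - len(common))
    if len(common) < 3:
        raise SelectionError(
            f"only {len(common)} common atoms between coordinate sets "
            f"{a.selection_name!r} / {b.selection_name!r}; superposition undefined"
        )
    P = a.coords[[index_a[k] for k in common]]
    Q = b.coords[[index_b[k] for k in common]]
    return P, Q, common, n_dropped


@dataclass
class EnsembleSet:
    """Ordered conformational states sharing one domain registry.

    ``chain_maps`` gives, per state label, the mapping from entity role
    (e.g. 'Mfd', 'RNAP_beta', 't_strand') to the author chain ID of that
    state's model.  Chain roles are never guessed from chain letters.
    """

    states: list[tuple[StateAnnotation, StructureModel]]
    registry: DomainRegistry
    chain_maps: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [ann.label for ann, _ in self.states]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate state labels in ensemble: {sorted(dupes)}")

    @property
    def labels(self) -> list[str]:
        return [ann.label for ann, _ in self.states]

    def annotation(self, label: str) -> StateAnnotation:
        for ann, _ in self.states:
            if ann.label == label:
                return ann
        raise KeyError(f"no state labeled {label!r}")

    def model(self, label: str) -> StructureModel:
        for ann, m in self.states:
            if ann.label == label:
                return m
        raise KeyError(f"no state labeled {label!r}")

    def resolve(self, label: str, selection: Selection | str) -> CoordinateSet:
        if isinstance(selection, str):
            selection = self.registry.get(selection)
        return select_coordinates(
            self.model(label), selection, chain_map=self.chain_maps.get(label)
        )
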