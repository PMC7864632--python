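"""Structure and configuration I/O.

PDB and mmCIF parsing/writing go through gemmi; only the first model of a
multi-model file is read, alternate locations are collapsed to the
highest-occupancy conformer (ties: first encountered), and heteroatoms
(nucleotides, ATP/ADP ligands) are retained.

The domain registry defaults ship here as an editable YAML document.  The
residue anchors that are fixed by the Mfd structural literature (relay helix
548-577, TD1 superposition core 580-780, mobile TD2 N-portion 781-939, the
1148-residue E. coli Mfd sequence) carry provenance "structure anchor"; the
remaining boundaries — including the RNAP clamp / βprotrusion / βlobe-Si1
module limits, which have no single canonical definition — are package
defaults and every downstream angle report records the provenance used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import gemmi
import yaml

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
    "read_structure",
    "write_structure",
    "load_registry",
    "default_registry",
    "load_ensemble",
    "DEFAULT_REGISTRY_YAML",
    "FormatError",
]


class FormatError(ValueError):
    """Unparseable or empty structure file."""


def _detect_format(path: str | Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    All atom sites with coordinates are retained, including heteroatoms.
    Alternate locations resolve to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise FormatError(f"{path}: no models in file")
    gmodel = st[0]
    atoms: list[AtomSite] = []
    for chain in gmodel:
        for residue in chain:
            # collapse altlocs: keep highest occupancy per atom name, first wins ties
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in residue:  # preserve file order of first-kept atoms
                if best.get(atom.name) is not atom:
                    continue
                atoms.append(
                    AtomSite(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=[atom.pos.x, atom.pos.y, atom.pos.z],
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                    )
                )
    if not atoms:
        raise FormatError(f"{path}: no atoms")
    return StructureModel(model_id=path.stem, atoms=atoms, source=str(path))


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    # group atoms by chain, then by residue, preserving encounter order
    chain_order: list[str] = []
    grouped: dict[str, dict[tuple[int, str, str], list[AtomSite]]] = {}
    for a in model.atoms:
        if a.chain_id not in grouped:
            grouped[a.chain_id] = {}
            chain_order.append(a.chain_id)
        rkey = (a.residue_number, a.insertion_code, a.residue_name)
        grouped[a.chain_id].setdefault(rkey, []).append(a)

    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain_id in chain_order:
        ch = gemmi.Chain(chain_id)
        for (resnum, icode, resname), site_list in grouped[chain_id].items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            for a in site_list:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "pdb") -> None:
    """Write a StructureModel to disk (PDB)."""
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    st = _to_gemmi(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Domain registry

DEFAULT_REGISTRY_YAML = """\
# Default domain registry for Mfd-EC ensemble analysis.
# Chains are entity roles resolved through each state's chain map.
# Residue numbers are author numbers of the 1148-residue E. coli Mfd sequence.
# provenance "structure anchor": boundary fixed by the structural annotation
#   of Mfd (relay helix, TD1 core, mobile TD2 N-portion).
# provenance "package default": editable boundary chosen by this package.
entries:
  D1a:   {chain: Mfd, ranges: [[1, 127]],    atoms: [CA], provenance: package default}
  D2:    {chain: Mfd, ranges: [[128, 213]],  atoms: [CA], provenance: package default}
  D1b:   {chain: Mfd, ranges: [[214, 332]],  atoms: [CA], provenance: package default}
  D3:    {chain: Mfd, ranges: [[333, 434]],  atoms: [CA], provenance: package default}
  D4_RID: {chain: Mfd, ranges: [[435, 547]], atoms: [CA], provenance: package default}
  RH:    {chain: Mfd, ranges: [[548, 577]],  atoms: [CA], provenance: structure anchor}
  D5_TD1: {chain: Mfd, ranges: [[578, 790]], atoms: [CA], provenance: package default}
  D6_TD2: {chain: Mfd, ranges: [[791, 997]], atoms: [CA], provenance: package default}
  D7:    {chain: Mfd, ranges: [[1005, 1148]], atoms: [CA], provenance: package default}
  TD1_superposition_core: {chain: Mfd, ranges: [[580, 780]], atoms: [CA], provenance: structure anchor}
  TD2_mobile: {chain: Mfd, ranges: [[781, 939]], atoms: [CA], provenance: structure anchor}
  clamp: {chain: RNAP_betaprime, ranges: [[1, 342]], atoms: [CA], provenance: package default}
  beta_protrusion: {chain: RNAP_beta, ranges: [[405, 550]], atoms: [CA], provenance: package default}
  beta_lobe_Si1: {chain: RNAP_beta, ranges: [[151, 445]], atoms: [CA], provenance: package default}
  RNAP_core:
    terms:
      - {chain: RNAP_beta, atoms: [CA]}
      - {chain: RNAP_betaprime, atoms: [CA]}
    provenance: package default
"""

MFD_RESIDUE_LIMIT = 1148  # length of the E. coli Mfd primary sequence


def _term_from_dict(d: Mapping) -> SelectionTerm:
    ranges = d.get("ranges")
    atoms = d.get("atoms")
    return SelectionTerm(
        chain=d["chain"],
        ranges=tuple(tuple(r) for r in ranges) if ranges else None,
        atom_names=tuple(atoms) if atoms else None,
    )


def _registry_from_dict(doc: Mapping, provenance_override: str | None = None) -> DomainRegistry:
    reg = DomainRegistry()
    for name, entry in doc.get("entries", {}).items():
        prov = provenance_override or entry.get("provenance", "user")
        if "terms" in entry:
            terms = [_term_from_dict(t) for t in entry["terms"]]
        else:
            terms = [_term_from_dict(entry)]
        for t in terms:
            if t.chain == "Mfd" and t.ranges is not None:
                for lo, hi in t.ranges:
                    if lo < 1 or hi > MFD_RESIDUE_LIMIT:
                        raise ValueError(
                            f"registry entry {name!r}: Mfd residues must lie in "
                            f"[1, {MFD_RESIDUE_LIMIT}], got {lo}-{hi}"
                        )
        reg.add(Selection(name=name, terms=terms), prov)
    return reg


def default_registry() -> DomainRegistry:
    """The registry shipped with the package (all mandatory entries present)."""
    reg = _registry_from_dict(yaml.safe_load(DEFAULT_REGISTRY_YAML))
    reg.validate_mandatory()
    return reg


def load_registry(config: str | Path | Mapping, require_mandatory: bool = True) -> DomainRegistry:
    """Load a registry config; entries override the package defaults.

    ``config`` may be a YAML file path, a YAML string, or a mapping.  Entries
    supplied by the user get provenance "user" unless they state their own.
    """
    if isinstance(config, Mapping):
        doc = config
    else:
        text = Path(config).read_text() if Path(str(config)).exists() else str(config)
        doc = yaml.safe_load(text) or {}
    reg = default_registry()
    user = _registry_from_dict(doc)
    for name, sel in user.entries.items():
        prov = user.provenance[name]
        reg.add(sel, "user" if prov == "package default" else prov)
    if require_mandatory:
        reg.validate_mandatory()
    return reg


# ---------------------------------------------------------------------------
# Ensemble manifest

def load_ensemble(manifest: str | Path | Mapping, base_dir: str | Path | None = None) -> EnsembleSet:
    """Load an ensemble from a manifest.

    Manifest schema (YAML)::

        registry: optional path / inline mapping with entry overrides
        states:
          - label: C1
            file: models/c1.pdb
            nucleotide: ATP          # ATP/ADP observed; atp/adp inferred
            chains: {Mfd: A, RNAP_beta: B, RNAP_betaprime: C,
                     t_strand: T, nt_strand: N, RNA: R}
    """
    if isinstance(manifest, Mapping):
        doc = dict(manifest)
        root = Path(base_dir) if base_dir else Path.cwd()
    else:
        mpath = Path(manifest)
        doc = yaml.safe_load(mpath.read_text())
        root = mpath.parent if base_dir is None else Path(base_dir)

    reg_cfg = doc.get("registry")
    if reg_cfg is None:
        registry = default_registry()
    elif isinstance(reg_cfg, str):
        registry = load_registry(root / reg_cfg)
    else:
        registry = load_registry(reg_cfg)

    states: list[tuple[StateAnnotation, StructureModel]] = []
    chain_maps: dict[str, dict[str, str]] = {}
    seen: set[str] = set()
    for entry in doc.get("states", []):
        label = entry["label"]
        if label in seen:
            raise ValueError(f"duplicate state label {label!r} in manifest")
        seen.add(label)
        ann = StateAnnotation(
            label=label,
            nucleotide=entry.get("nucleotide", "unknown"),
            pathway_index=entry.get("pathway_index"),
        )
        fpath = Path(entry["file"])
        if not fpath.is_absolute():
            fpath = root / fpath
        model = read_structure(fpath, format=entry.get("format", "auto"))
        model.model_id = label
        states.append((ann, model))
        chain_maps[label] = dict(entry.get("chains", {}))
    if not states:
        raise ValueError("manifest defines no states")
    return EnsembleSet(states=states, registry=registry, chain_maps=chain_maps)
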