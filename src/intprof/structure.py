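"""Core molecular data model: atoms, bonds, residues, typed systems.

A :class:`TypedMolecularSystem` is the in-memory container every other
module consumes.  Atoms carry SYBYL atom types (element + hybridization,
e.g. ``C.3``, ``O.2``, ``N.ar``) and template partial charges; bonds carry
SYBYL bond types (``1``, ``2``, ``3``, ``am``, ``ar``).  Residues are keyed
by ``(chain_id, resseq, icode)`` exactly as found in the input file — no
renumbering ever happens.

Partner classes drive descriptor naming:

``M``   residue(s) designated for analysis (the mutation site),
``Ab``  antibody environment, ``Ag`` antigen environment,
``S``   solvent water, ``other`` anything unmapped (e.g. bare ions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import yaml

from .geometry import RingSystem, ring_center_normal, GeometryError

__all__ = [
    "Atom",
    "Residue",
    "TypedMolecularSystem",
    "StructureError",
    "ResidueKey",
    "parse_residue_key",
    "load_target_spec",
    "assign_partner_classes",
    "WATER_RESIDUE_NAMES",
    "BACKBONE_ATOM_NAMES",
]

ResidueKey = Tuple[str, int, str]

WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT"})

#: protein backbone atom names (heavy + amide/alpha hydrogens); everything
#: else in an amino-acid residue counts as side chain
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3"}
)

METAL_ELEMENTS = frozenset({"FE", "ZN", "CA", "MG", "NI"})
ION_ELEMENTS = frozenset({"NA", "K", "CL"})


class StructureError(ValueError):
    """Inconsistent molecular structure or configuration."""


def _element_of_sybyl(sybyl_type: str) -> str:
    return sybyl_type.split(".")[0].upper()


@dataclass
class Atom:
    serial: int
    pdb_name: str
    element: str
    coords: np.ndarray
    sybyl_type: str = ""
    partial_charge: Optional[float] = None
    residue_key: ResidueKey = ("", 0, "")

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial}: coordinates must be 3 finite numbers")
        self.element = self.element.upper()
        if self.sybyl_type:
            lead = _element_of_sybyl(self.sybyl_type)
            if lead != self.element:
                raise StructureError(
                    f"atom {self.serial} ({self.pdb_name}): SYBYL type "
                    f"{self.sybyl_type!r} does not match element {self.element!r}"
                )

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    chain_id: str
    resseq: int
    icode: str = ""
    name: str = ""
    atoms: List[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, pdb_name: str) -> Atom:
        for a in self.atoms:
            if a.pdb_name == pdb_name:
                return a
        raise StructureError(f"residue {format_residue_key(self.key)} has no atom {pdb_name!r}")

    def has_atom(self, pdb_name: str) -> bool:
        return any(a.pdb_name == pdb_name for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESIDUE_NAMES

    def sidechain_atoms(self) -> List[Atom]:
        if self.is_water:
            return list(self.atoms)
        return [a for a in self.atoms if a.pdb_name not in BACKBONE_ATOM_NAMES]


def format_residue_key(key: ResidueKey) -> str:
    chain, seq, icode = key
    return f"{chain}:{seq}{icode}"


def parse_residue_key(text: str) -> ResidueKey:
    """Parse ``chain:resseq[icode]`` (e.g. ``H:57``, ``L:52A``)."""
    try:
        chain, rest = text.split(":")
    except ValueError as exc:
        raise StructureError(f"bad residue key {text!r}: expected chain:resseq") from exc
    rest = rest.strip()
    icode = ""
    if rest and rest[-1].isalpha():
        icode = rest[-1]
        rest = rest[:-1]
    return (chain.strip(), int(rest), icode)


class TypedMolecularSystem:
    """Atoms, bonds and residues of one (possibly multi-chain) complex."""

    def __init__(self, name: str = "system"):
        self.name = name
        self.residues: Dict[ResidueKey, Residue] = {}
        self._atoms_by_serial: Dict[int, Atom] = {}
        self._bonds: Dict[frozenset, str] = {}
        self._adjacency: Dict[int, List[int]] = {}
        self.partner_class_map: Dict[ResidueKey, str] = {}
        self.water_residue_names = set(WATER_RESIDUE_NAMES)
        self._ring_cache: Optional[List[RingSystem]] = None

    # -- construction -------------------------------------------------
    def add_residue(self, residue: Residue) -> Residue:
        if residue.key in self.residues:
            raise StructureError(f"duplicate residue {format_residue_key(residue.key)}")
        self.residues[residue.key] = residue
        for atom in residue.atoms:
            self._register_atom(atom, residue)
        return residue

    def add_atom(self, residue: Residue, atom: Atom) -> Atom:
        residue.atoms.append(atom)
        self._register_atom(atom, residue)
        return atom

    def _register_atom(self, atom: Atom, residue: Residue):
        if atom.serial in self._atoms_by_serial:
            raise StructureError(f"duplicate atom serial {atom.serial}")
        atom.residue_key = residue.key
        self._atoms_by_serial[atom.serial] = atom
        self._adjacency.setdefault(atom.serial, [])

    def add_bond(self, a: Atom, b: Atom, sybyl_bond_type: str = "1"):
        if a.serial == b.serial:
            raise StructureError("self-bonds are not allowed")
        key = frozenset((a.serial, b.serial))
        if key in self._bonds:
            return
        self._bonds[key] = str(sybyl_bond_type)
        self._adjacency[a.serial].append(b.serial)
        self._adjacency[b.serial].append(a.serial)
        self._ring_cache = None

    # -- queries ------------------------------------------------------
    @property
    def atoms(self) -> List[Atom]:
        return [a for res in self.residues.values() for a in res.atoms]

    def atom_by_serial(self, serial: int) -> Atom:
        return self._atoms_by_serial[serial]

    @property
    def bonds(self) -> Dict[frozenset, str]:
        return dict(self._bonds)

    def bond_type(self, a: Atom, b: Atom) -> Optional[str]:
        return self._bonds.get(frozenset((a.serial, b.serial)))

    def neighbors(self, atom: Atom) -> List[Atom]:
        return [self._atoms_by_serial[s] for s in self._adjacency.get(atom.serial, [])]

    def heavy_neighbors(self, atom: Atom) -> List[Atom]:
        return [n for n in self.neighbors(atom) if n.is_heavy]

    def bonded_hydrogens(self, atom: Atom) -> List[Atom]:
        return [n for n in self.neighbors(atom) if n.is_hydrogen]

    def residue(self, key: ResidueKey) -> Residue:
        try:
            return self.residues[key]
        except KeyError as exc:
            raise StructureError(f"no residue {format_residue_key(key)} in structure") from exc

    def partner_class(self, key: ResidueKey) -> str:
        return self.partner_class_map.get(key, "other")

    def target_residues(self) -> List[Residue]:
        return [self.residues[k] for k, c in self.partner_class_map.items() if c == "M"]

    # -- aromatic rings ----------------------------------------------
    def aromatic_rings(self) -> List[RingSystem]:
        """Perceive aromatic rings from the ``ar`` bond subgraph.

        Uses the minimum cycle basis of the aromatic-bond subgraph, so a
        fused system such as indole yields its 5- and 6-membered rings
        separately.  Rings failing the planarity gate are skipped.
        """
        if self._ring_cache is not None:
            return self._ring_cache
        g = nx.Graph()
        for key, btype in self._bonds.items():
            if btype == "ar":
                a, b = tuple(key)
                g.add_edge(a, b)
        rings: List[RingSystem] = []
        for cycle in nx.minimum_cycle_basis(g):
            if len(cycle) < 5:
                continue
            ordered = _order_cycle(g, cycle)
            coords = np.array([self._atoms_by_serial[s].coords for s in ordered])
            try:
                rings.append(ring_center_normal(coords, member_serials=tuple(ordered)))
            except GeometryError:
                continue
        rings.sort(key=lambda r: min(r.member_serials))
        self._ring_cache = rings
        return rings

    def validate(self):
        """Cheap consistency checks (hydrogen valence, water composition)."""
        for atom in self.atoms:
            if atom.is_hydrogen and atom.sybyl_type:
                n = len(self._adjacency.get(atom.serial, []))
                if n != 1:
                    raise StructureError(
                        f"hydrogen atom {atom.serial} has {n} covalent bonds (expected 1)"
                    )
        for res in self.residues.values():
            if res.is_water:
                n_o = sum(1 for a in res.atoms if a.element == "O")
                if n_o != 1:
                    raise StructureError(
                        f"water {format_residue_key(res.key)} has {n_o} oxygens"
                    )


def _order_cycle(g: nx.Graph, cycle: List[int]) -> List[int]:
    """Order a cycle-basis node set into a ring walk, lowest serial first."""
    members = set(cycle)
    start = min(members)
    walk = [start]
    prev = None
    cur = start
    while len(walk) < len(members):
        nxt = [n for n in sorted(g.neighbors(cur)) if n in members and n != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        walk.append(cur)
    return walk


# -- partner classes ---------------------------------------------------

def load_target_spec(path) -> dict:
    """Read the target-molecule specification (YAML).

    Expected layout::

        targets: [H:57]            # one residue for SPM, two for DPM
        chains:  {H: Ab, L: Ab, T: Ag}
        default_class: other       # optional fallback for unmapped chains
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise StructureError("target specification must be a mapping")
    return spec


def assign_partner_classes(system: TypedMolecularSystem, spec: dict) -> TypedMolecularSystem:
    """Fill ``partner_class_map`` from a target specification.

    Waters always class ``S``; listed target residues class ``M``; other
    residues take the class mapped to their chain (Ab/Ag), the optional
    ``default_class``, or raise when unmapped.
    """
    targets = spec.get("targets") or []
    if not targets:
        raise StructureError("target specification lists no target residues")
    chains = {str(k): str(v) for k, v in (spec.get("chains") or {}).items()}
    default = spec.get("default_class")
    target_keys = [parse_residue_key(t) if isinstance(t, str) else tuple(t) for t in targets]
    for tk in target_keys:
        if tk not in system.residues:
            raise StructureError(f"target residue {format_residue_key(tk)} absent from structure")
    cmap: Dict[ResidueKey, str] = {}
    for key, res in system.residues.items():
        if res.is_water:
            cmap[key] = "S"
        elif key in target_keys:
            cmap[key] = "M"
        elif res.name in METAL_ELEMENTS or res.name in ION_ELEMENTS:
            cmap[key] = chains.get(res.chain_id, default or "other")
        elif res.chain_id in chains:
            cmap[key] = chains[res.chain_id]
        elif default is not None:
            cmap[key] = default
        else:
            raise StructureError(
                f"chain {res.chain_id!r} of residue {format_residue_key(key)} "
                "is not mapped to a partner class and no default_class is set"
            )
    system.partner_class_map = cmap
    return system
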