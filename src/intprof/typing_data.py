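"""Residue typing dictionary: SYBYL atom types, template charges, bonds.

The profiler consumes MOL2-style typed systems; when the input is a PDB
file (with hydrogens already added) every atom's SYBYL type and partial
charge are looked up in a dictionary keyed by ``(residue name, PDB atom
name)`` and intra-residue bonds are instantiated from per-residue bond
templates.  Two hydrogen-naming dialects are shipped: ``pdb2pqr``
(PDB v3 names such as HB2/HB3) and ``gmx_ff99SBildn`` (GROMACS-style
HB1/HB2).

Partial charges are a self-consistent Gasteiger-like template set.  The
only charge-sensitive predicates downstream are the bond-dipole gates
(|q+ - q-| >= 0.2), so what matters is that genuinely polar bonds
(C=O, C-O(H), C-N) clear the gate while apolar C-C/C-H bonds do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .structure import (
    Atom,
    Residue,
    StructureError,
    TypedMolecularSystem,
    format_residue_key,
)

__all__ = [
    "TypingError",
    "TypingDictionary",
    "default_typing_dictionary",
    "apply_typing",
    "read_typing_dictionary",
    "write_typing_dictionary",
    "DIALECTS",
]

DIALECTS = ("pdb2pqr", "gmx_ff99SBildn")


class TypingError(StructureError):
    """An atom/residue pair missing from the typing dictionary."""


# ---------------------------------------------------------------------
# template charges by SYBYL type, with a few context overrides
_CHARGE_BY_TYPE = {
    "N.am": -0.35, "N.4": -0.30, "N.pl3": -0.30, "N.ar": -0.25,
    "N.2": -0.28, "N.3": -0.32,
    "O.2": -0.27, "O.co2": -0.28, "O.3": -0.38,
    "C.3": 0.03, "C.2": 0.24, "C.ar": -0.06, "C.cat": 0.30,
    "S.3": -0.11, "S.2": -0.11,
}
_H_CHARGE_BY_HOST = {"C.3": 0.03, "C.2": 0.05, "C.ar": 0.06, "C.cat": 0.06,
                     "N": 0.17, "N+": 0.25, "O": 0.21, "S": 0.10}


def _heavy_charge(resname: str, name: str, sybyl: str, bonded_names) -> float:
    if resname in ("HOH", "WAT"):
        return -0.41
    if name == "CA":
        return 0.08
    return _CHARGE_BY_TYPE[sybyl]


def _h_charge(resname: str, host_sybyl: str, host_name: str) -> float:
    if resname in ("HOH", "WAT"):
        return 0.205
    el = host_sybyl.split(".")[0]
    if el == "N":
        return _H_CHARGE_BY_HOST["N+"] if host_sybyl in ("N.4", "N.pl3") else _H_CHARGE_BY_HOST["N"]
    if el in ("O", "S"):
        return _H_CHARGE_BY_HOST[el]
    return _H_CHARGE_BY_HOST.get(host_sybyl, 0.03)


# ---------------------------------------------------------------------
# side-chain templates: heavy atoms (name, SYBYL), hydrogens per heavy
# atom (pdb2pqr / PDB v3 names), heavy-heavy bonds (a, b, type)
_SC: Dict[str, dict] = {
    "ALA": dict(atoms=[("CB", "C.3")], h={"CB": ["HB1", "HB2", "HB3"]}, bonds=[]),
    "ARG": dict(
        atoms=[("CB", "C.3"), ("CG", "C.3"), ("CD", "C.3"), ("NE", "N.pl3"),
               ("CZ", "C.cat"), ("NH1", "N.pl3"), ("NH2", "N.pl3")],
        h={"CB": ["HB2", "HB3"], "CG": ["HG2", "HG3"], "CD": ["HD2", "HD3"],
           "NE": ["HE"], "NH1": ["HH11", "HH12"], "NH2": ["HH21", "HH22"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD", "1"), ("CD", "NE", "1"),
               ("NE", "CZ", "ar"), ("CZ", "NH1", "ar"), ("CZ", "NH2", "ar")]),
    "ASN": dict(
        atoms=[("CB", "C.3"), ("CG", "C.2"), ("OD1", "O.2"), ("ND2", "N.am")],
        h={"CB": ["HB2", "HB3"], "ND2": ["HD21", "HD22"]},
        bonds=[("CB", "CG", "1"), ("CG", "OD1", "2"), ("CG", "ND2", "am")]),
    "ASP": dict(
        atoms=[("CB", "C.3"), ("CG", "C.2"), ("OD1", "O.co2"), ("OD2", "O.co2")],
        h={"CB": ["HB2", "HB3"]},
        bonds=[("CB", "CG", "1"), ("CG", "OD1", "ar"), ("CG", "OD2", "ar")]),
    "CYS": dict(atoms=[("CB", "C.3"), ("SG", "S.3")],
                h={"CB": ["HB2", "HB3"], "SG": ["HG"]}, bonds=[("CB", "SG", "1")]),
    # disulfide-bonded cysteine: no thiol hydrogen
    "CYX": dict(atoms=[("CB", "C.3"), ("SG", "S.3")],
                h={"CB": ["HB2", "HB3"]}, bonds=[("CB", "SG", "1")]),
    "GLN": dict(
        atoms=[("CB", "C.3"), ("CG", "C.3"), ("CD", "C.2"), ("OE1", "O.2"), ("NE2", "N.am")],
        h={"CB": ["HB2", "HB3"], "CG": ["HG2", "HG3"], "NE2": ["HE21", "HE22"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD", "1"), ("CD", "OE1", "2"), ("CD", "NE2", "am")]),
    "GLU": dict(
        atoms=[("CB", "C.3"), ("CG", "C.3"), ("CD", "C.2"), ("OE1", "O.co2"), ("OE2", "O.co2")],
        h={"CB": ["HB2", "HB3"], "CG": ["HG2", "HG3"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD", "1"), ("CD", "OE1", "ar"), ("CD", "OE2", "ar")]),
    "GLY": dict(atoms=[], h={}, bonds=[]),
    # neutral His tautomer with the proton on NE2 (pdb2pqr default)
    "HIS": dict(
        atoms=[("CB", "C.3"), ("CG", "C.ar"), ("ND1", "N.ar"), ("CE1", "C.ar"),
               ("NE2", "N.ar"), ("CD2", "C.ar")],
        h={"CB": ["HB2", "HB3"], "CE1": ["HE1"], "NE2": ["HE2"], "CD2": ["HD2"]},
        bonds=[("CB", "CG", "1"), ("CG", "ND1", "ar"), ("ND1", "CE1", "ar"),
               ("CE1", "NE2", "ar"), ("NE2", "CD2", "ar"), ("CD2", "CG", "ar")]),
    "ILE": dict(
        atoms=[("CB", "C.3"), ("CG1", "C.3"), ("CG2", "C.3"), ("CD1", "C.3")],
        h={"CB": ["HB"], "CG1": ["HG12", "HG13"],
           "CG2": ["HG21", "HG22", "HG23"], "CD1": ["HD11", "HD12", "HD13"]},
        bonds=[("CB", "CG1", "1"), ("CB", "CG2", "1"), ("CG1", "CD1", "1")]),
    "LEU": dict(
        atoms=[("CB", "C.3"), ("CG", "C.3"), ("CD1", "C.3"), ("CD2", "C.3")],
        h={"CB": ["HB2", "HB3"], "CG": ["HG"],
           "CD1": ["HD11", "HD12", "HD13"], "CD2": ["HD21", "HD22", "HD23"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD1", "1"), ("CG", "CD2", "1")]),
    "LYS": dict(
        atoms=[("CB", "C.3"), ("CG", "C.3"), ("CD", "C.3"), ("CE", "C.3"), ("NZ", "N.4")],
        h={"CB": ["HB2", "HB3"], "CG": ["HG2", "HG3"], "CD": ["HD2", "HD3"],
           "CE": ["HE2", "HE3"], "NZ": ["HZ1", "HZ2", "HZ3"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD", "1"), ("CD", "CE", "1"), ("CE", "NZ", "1")]),
    "MET": dict(
        atoms=[("CB", "C.3"), ("CG", "C.3"), ("SD", "S.3"), ("CE", "C.3")],
        h={"CB": ["HB2", "HB3"], "CG": ["HG2", "HG3"], "CE": ["HE1", "HE2", "HE3"]},
        bonds=[("CB", "CG", "1"), ("CG", "SD", "1"), ("SD", "CE", "1")]),
    "PHE": dict(
        atoms=[("CB", "C.3"), ("CG", "C.ar"), ("CD1", "C.ar"), ("CD2", "C.ar"),
               ("CE1", "C.ar"), ("CE2", "C.ar"), ("CZ", "C.ar")],
        h={"CB": ["HB2", "HB3"], "CD1": ["HD1"], "CD2": ["HD2"],
           "CE1": ["HE1"], "CE2": ["HE2"], "CZ": ["HZ"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD1", "ar"), ("CD1", "CE1", "ar"),
               ("CE1", "CZ", "ar"), ("CZ", "CE2", "ar"), ("CE2", "CD2", "ar"),
               ("CD2", "CG", "ar")]),
    "PRO": dict(
        atoms=[("CB", "C.3"), ("CG", "C.3"), ("CD", "C.3")],
        h={"CB": ["HB2", "HB3"], "CG": ["HG2", "HG3"], "CD": ["HD2", "HD3"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD", "1"), ("CD", "N", "1")]),
    "SER": dict(atoms=[("CB", "C.3"), ("OG", "O.3")],
                h={"CB": ["HB2", "HB3"], "OG": ["HG"]}, bonds=[("CB", "OG", "1")]),
    "THR": dict(
        atoms=[("CB", "C.3"), ("OG1", "O.3"), ("CG2", "C.3")],
        h={"CB": ["HB"], "OG1": ["HG1"], "CG2": ["HG21", "HG22", "HG23"]},
        bonds=[("CB", "OG1", "1"), ("CB", "CG2", "1")]),
    "TRP": dict(
        atoms=[("CB", "C.3"), ("CG", "C.ar"), ("CD1", "C.ar"), ("CD2", "C.ar"),
               ("NE1", "N.ar"), ("CE2", "C.ar"), ("CE3", "C.ar"), ("CZ2", "C.ar"),
               ("CZ3", "C.ar"), ("CH2", "C.ar")],
        h={"CB": ["HB2", "HB3"], "CD1": ["HD1"], "NE1": ["HE1"], "CE3": ["HE3"],
           "CZ2": ["HZ2"], "CZ3": ["HZ3"], "CH2": ["HH2"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD1", "ar"), ("CD1", "NE1", "ar"),
               ("NE1", "CE2", "ar"), ("CE2", "CD2", "ar"), ("CD2", "CG", "ar"),
               ("CD2", "CE3", "ar"), ("CE3", "CZ3", "ar"), ("CZ3", "CH2", "ar"),
               ("CH2", "CZ2", "ar"), ("CZ2", "CE2", "ar")]),
    "TYR": dict(
        atoms=[("CB", "C.3"), ("CG", "C.ar"), ("CD1", "C.ar"), ("CD2", "C.ar"),
               ("CE1", "C.ar"), ("CE2", "C.ar"), ("CZ", "C.ar"), ("OH", "O.3")],
        h={"CB": ["HB2", "HB3"], "CD1": ["HD1"], "CD2": ["HD2"],
           "CE1": ["HE1"], "CE2": ["HE2"], "OH": ["HH"]},
        bonds=[("CB", "CG", "1"), ("CG", "CD1", "ar"), ("CD1", "CE1", "ar"),
               ("CE1", "CZ", "ar"), ("CZ", "CE2", "ar"), ("CE2", "CD2", "ar"),
               ("CD2", "CG", "ar"), ("CZ", "OH", "1")]),
    "VAL": dict(
        atoms=[("CB", "C.3"), ("CG1", "C.3"), ("CG2", "C.3")],
        h={"CB": ["HB"], "CG1": ["HG11", "HG12", "HG13"], "CG2": ["HG21", "HG22", "HG23"]},
        bonds=[("CB", "CG1", "1"), ("CB", "CG2", "1")]),
}

_WATER = dict(atoms=[("O", "O.3")], h={"O": ["H1", "H2"]}, bonds=[])

_BACKBONE_ATOMS = [("N", "N.am"), ("CA", "C.3"), ("C", "C.2"), ("O", "O.2")]
_BACKBONE_BONDS = [("N", "CA", "1"), ("CA", "C", "1"), ("C", "O", "2")]

AMINO_ACIDS = tuple(sorted(_SC))  # includes CYX


def _gmx_h_names(names: List[str]) -> List[str]:
    """GROMACS ff99SB-ildn dialect: HB2/HB3 pairs become HB1/HB2."""
    if len(names) == 2 and names[0].endswith("2") and names[1].endswith("3"):
        stem = names[0][:-1]
        return [stem + "1", stem + "2"]
    return list(names)


@dataclass
class TypingDictionary:
    """(residue, atom) -> (SYBYL type, charge) plus per-residue bonds."""

    dialect: str = "pdb2pqr"
    entries: Dict[Tuple[str, str], Tuple[str, float]] = field(default_factory=dict)
    bond_templates: Dict[str, List[Tuple[str, str, str]]] = field(default_factory=dict)

    def lookup(self, residue_name: str, atom_name: str) -> Tuple[str, float]:
        try:
            return self.entries[(residue_name, atom_name)]
        except KeyError as exc:
            raise TypingError(
                f"typing dictionary ({self.dialect}) has no entry for "
                f"({residue_name}, {atom_name})"
            ) from exc

    def covers(self, residue_name: str) -> bool:
        return residue_name in self.bond_templates


def default_typing_dictionary(dialect: str = "pdb2pqr") -> TypingDictionary:
    if dialect not in DIALECTS:
        raise TypingError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    d = TypingDictionary(dialect=dialect)
    for resname, sc in _SC.items():
        atoms = list(_BACKBONE_ATOMS) + sc["atoms"]
        hydrogens = dict(sc["h"])
        if resname == "GLY":
            hydrogens["CA"] = ["HA2", "HA3"]
        else:
            hydrogens["CA"] = ["HA"]
        if resname != "PRO":
            hydrogens["N"] = ["H"]
        bonds = list(_BACKBONE_BONDS) + sc["bonds"]
        if sc["atoms"]:
            bonds.append(("CA", "CB", "1"))
        _install(d, resname, atoms, hydrogens, bonds, dialect)
    for wname in ("HOH", "WAT"):
        _install(d, wname, _WATER["atoms"], _WATER["h"], _WATER["bonds"], dialect)
    return d


def _install(d, resname, atoms, hydrogens, bonds, dialect):
    sybyl_of = dict(atoms)
    bond_list = list(bonds)
    for name, sybyl in atoms:
        d.entries[(resname, name)] = (sybyl, round(_heavy_charge(resname, name, sybyl, None), 4))
    for host, hnames in hydrogens.items():
        if dialect == "gmx_ff99SBildn":
            hnames = _gmx_h_names(hnames)
        for hname in hnames:
            d.entries[(resname, hname)] = ("H", round(_h_charge(resname, sybyl_of[host], host), 4))
            bond_list.append((host, hname, "1"))
    d.bond_templates[resname] = bond_list


# ---------------------------------------------------------------------
# applying the dictionary to a parsed (untyped) system

def apply_typing(
    system: TypedMolecularSystem,
    dictionary: Optional[TypingDictionary] = None,
    *,
    skip_unknown_residues: bool = False,
    match_h_by_attachment: bool = False,
    disulfides="auto",
) -> TypedMolecularSystem:
    """Assign SYBYL types, charges and bonds to every residue in place.

    ``disulfides`` is either ``"auto"`` (CYS SG pairs within 2.5 A become
    disulfide-bonded CYX) or an explicit list of residue-key pairs.
    Unknown ``(residue, atom)`` pairs raise :class:`TypingError` unless
    ``match_h_by_attachment`` resolves a hydrogen via its nearest heavy
    atom, or ``skip_unknown_residues`` drops the residue wholesale.
    """
    dictionary = dictionary or default_typing_dictionary()
    cyx_keys = _resolve_disulfides(system, disulfides)

    for res in list(system.residues.values()):
        resname = res.name
        if res.is_water:
            resname = res.name  # HOH/WAT both covered
        elif res.key in cyx_keys:
            resname = "CYX"
        if not dictionary.covers(resname):
            if skip_unknown_residues:
                continue
            raise TypingError(
                f"residue {res.name} {format_residue_key(res.key)} not covered "
                "by the typing dictionary"
            )
        for atom in res.atoms:
            try:
                sybyl, charge = dictionary.lookup(resname, atom.pdb_name)
            except TypingError:
                if match_h_by_attachment and atom.element == "H":
                    host = _nearest_heavy(res, atom)
                    sybyl = "H"
                    charge = _h_charge(resname, host.sybyl_type or "C.3", host.pdb_name)
                else:
                    raise
            atom.sybyl_type = sybyl
            atom.partial_charge = charge
            atom.element = sybyl.split(".")[0].upper()
        # intra-residue bonds from the template (skip pairs with absent atoms)
        for a_name, b_name, btype in dictionary.bond_templates[resname]:
            if res.has_atom(a_name) and res.has_atom(b_name):
                system.add_bond(res.atom(a_name), res.atom(b_name), btype)
        if match_h_by_attachment:
            for atom in res.atoms:
                if atom.element == "H" and not system.neighbors(atom):
                    system.add_bond(_nearest_heavy(res, atom), atom, "1")

    _add_peptide_bonds(system)
    # explicit CONECT records (hetero groups, declared disulfides)
    for s1, s2 in getattr(system, "declared_conect", []):
        try:
            a1, a2 = system.atom_by_serial(s1), system.atom_by_serial(s2)
        except KeyError:
            continue
        if system.bond_type(a1, a2) is None:
            system.add_bond(a1, a2, "1")
    for k1, k2 in _pairs_from(cyx_keys):
        r1, r2 = system.residue(k1), system.residue(k2)
        if r1.has_atom("SG") and r2.has_atom("SG"):
            system.add_bond(r1.atom("SG"), r2.atom("SG"), "1")
    system.validate()
    return system


def _nearest_heavy(res: Residue, h: Atom) -> Atom:
    import numpy as np

    heavies = [a for a in res.atoms if a.is_heavy]
    if not heavies:
        raise TypingError(f"hydrogen {h.pdb_name} has no heavy atom in its residue")
    return min(heavies, key=lambda a: float(np.linalg.norm(a.coords - h.coords)))


def _resolve_disulfides(system, disulfides):
    import numpy as np

    if disulfides is None:
        return {}
    if disulfides != "auto":
        keys = {}
        for k1, k2 in disulfides:
            keys[k1] = k2
            keys[k2] = k1
        return keys
    sgs = []
    for res in system.residues.values():
        if res.name in ("CYS", "CYX") and res.has_atom("SG"):
            sgs.append((res.key, res.atom("SG")))
    keys = {}
    for i, (k1, a1) in enumerate(sgs):
        for k2, a2 in sgs[i + 1:]:
            if float(np.linalg.norm(a1.coords - a2.coords)) < 2.5:
                keys[k1] = k2
                keys[k2] = k1
    return keys


def _pairs_from(cyx_map):
    seen = set()
    for k1, k2 in cyx_map.items():
        pair = tuple(sorted((k1, k2)))
        if pair not in seen:
            seen.add(pair)
            yield pair


def _add_peptide_bonds(system: TypedMolecularSystem):
    """Bond C(i)-N(i+1) for consecutive residues of a chain (< 2.0 A)."""
    import numpy as np

    by_chain: Dict[str, List[Residue]] = {}
    for res in system.residues.values():
        if res.is_water or not res.has_atom("CA"):
            continue
        by_chain.setdefault(res.chain_id, []).append(res)
    for chain_residues in by_chain.values():
        for prev, nxt in zip(chain_residues, chain_residues[1:]):
            if not (prev.has_atom("C") and nxt.has_atom("N")):
                continue
            c, n = prev.atom("C"), nxt.atom("N")
            if float(np.linalg.norm(c.coords - n.coords)) < 2.0:
                system.add_bond(c, n, "am")


# ---------------------------------------------------------------------
# structured-text serialization of a dictionary

def write_typing_dictionary(dictionary: TypingDictionary, path):
    with open(path, "w") as fh:
        fh.write(f"# intprof typing dictionary\ndialect {dictionary.dialect}\n")
        for resname in sorted(dictionary.bond_templates):
            fh.write(f"RESIDUE {resname}\n")
            for (rn, an), (sy, q) in sorted(dictionary.entries.items()):
                if rn == resname:
                    fh.write(f"ATOM {an} {sy} {q:.4f}\n")
            for a, b, t in dictionary.bond_templates[resname]:
                fh.write(f"BOND {a} {b} {t}\n")
            fh.write("END\n")


def read_typing_dictionary(path) -> TypingDictionary:
    d = TypingDictionary()
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            try:
                if tok[0] == "dialect":
                    d.dialect = tok[1]
                elif tok[0] == "RESIDUE":
                    current = tok[1]
                    d.bond_templates.setdefault(current, [])
                elif tok[0] == "ATOM":
                    d.entries[(current, tok[1])] = (tok[2], float(tok[3]))
                elif tok[0] == "BOND":
                    d.bond_templates[current].append((tok[1], tok[2], tok[3]))
                elif tok[0] == "END":
                    current = None
                else:
                    raise ValueError(f"unknown record {tok[0]!r}")
            except (IndexError, ValueError) as exc:
                raise TypingError(f"{path}:{lineno}: malformed dictionary line: {exc}") from exc
    return d
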