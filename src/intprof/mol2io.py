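"""TRIPOS MOL2 reading and writing.

MOL2 is the profiler's native interchange format: it carries coordinates,
SYBYL atom types, per-atom partial charges (mandatory here), SYBYL bond
types and a substructure id per residue.  Substructure names are written
as ``<resname><resseq><icode>`` with the chain kept in a trailing comment
column so that ``read_mol2(write_mol2(sys))`` is the identity on residue
keys, types, charges (1e-4) and coordinates (1e-3 A).
"""

from __future__ import annotations

from typing import Dict, List

from .structure import Atom, Residue, StructureError, TypedMolecularSystem

__all__ = ["Mol2FormatError", "read_mol2", "write_mol2"]


class Mol2FormatError(StructureError):
    pass


def write_mol2(system: TypedMolecularSystem, path):
    atoms = system.atoms
    for a in atoms:
        if not a.sybyl_type:
            raise Mol2FormatError(f"atom {a.serial} has no SYBYL type; type the system first")
        if a.partial_charge is None:
            raise Mol2FormatError(f"atom {a.serial} has no partial charge (charges are mandatory)")
    serial_to_idx = {a.serial: i + 1 for i, a in enumerate(atoms)}
    residues = list(system.residues.values())
    res_index = {res.key: i + 1 for i, res in enumerate(residues)}
    bonds = sorted(
        (tuple(sorted(serial_to_idx[s] for s in key)) + (btype,)
         for key, btype in system.bonds.items()),
        key=lambda x: (x[0], x[1]),
    )
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\n")
        fh.write(f"{system.name}\n")
        fh.write(f"{len(atoms)} {len(bonds)} {len(residues)} 0 0\n")
        fh.write("PROTEIN\nUSER_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for i, a in enumerate(atoms, 1):
            res = system.residues[a.residue_key]
            subst = f"{res.name}{res.resseq}{res.icode}"
            fh.write(
                f"{i:>7d} {a.pdb_name:<8s}{a.coords[0]:>10.4f}{a.coords[1]:>10.4f}"
                f"{a.coords[2]:>10.4f} {a.sybyl_type:<8s}{res_index[res.key]:>4d} "
                f"{subst:<8s}{a.partial_charge:>10.4f} CHAIN={res.chain_id}\n"
            )
        fh.write("@<TRIPOS>BOND\n")
        for i, (a, b, t) in enumerate(bonds, 1):
            fh.write(f"{i:>6d}{a:>6d}{b:>6d} {t}\n")


def read_mol2(path) -> TypedMolecularSystem:
    section = None
    mol_lines: List[str] = []
    atom_lines: List[tuple] = []
    bond_lines: List[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("@<TRIPOS>"):
                section = line[9:].strip().upper()
                continue
            if not line.strip() or line.startswith("#"):
                continue
            if section == "MOLECULE":
                mol_lines.append(line.strip())
            elif section == "ATOM":
                atom_lines.append((lineno, line))
            elif section == "BOND":
                bond_lines.append((lineno, line))
    if not atom_lines:
        raise Mol2FormatError(f"{path}: missing @<TRIPOS>ATOM section")

    system = TypedMolecularSystem(name=mol_lines[0] if mol_lines else "mol2")
    residues: Dict[tuple, Residue] = {}
    order: List[tuple] = []
    serial_map: Dict[int, Atom] = {}
    for lineno, line in atom_lines:
        fields = line.split()
        if len(fields) < 9:
            raise Mol2FormatError(
                f"{path}:{lineno}: ATOM line needs id, name, x, y, z, type, "
                "substructure id, substructure name and charge (charge column is mandatory)"
            )
        try:
            serial = int(fields[0])
            name = fields[1]
            x, y, z = (float(v) for v in fields[2:5])
            sybyl = fields[5]
            subst_name = fields[7]
            charge = float(fields[8])
        except ValueError as exc:
            raise Mol2FormatError(f"{path}:{lineno}: unparsable ATOM line: {exc}") from exc
        chain = ""
        for extra in fields[9:]:
            if extra.startswith("CHAIN="):
                chain = extra[6:]
        resname, resseq, icode = _split_subst(subst_name)
        key = (chain, resseq, icode)
        if key not in residues:
            residues[key] = Residue(chain_id=chain, resseq=resseq, icode=icode, name=resname)
            order.append(key)
        atom = Atom(serial=serial, pdb_name=name, element=sybyl.split(".")[0].upper(),
                    coords=(x, y, z), sybyl_type=sybyl, partial_charge=charge)
        residues[key].atoms.append(atom)
        serial_map[serial] = atom
    for key in order:
        system.add_residue(residues[key])
    for lineno, line in bond_lines:
        fields = line.split()
        try:
            a, b, t = int(fields[1]), int(fields[2]), fields[3]
        except (IndexError, ValueError) as exc:
            raise Mol2FormatError(f"{path}:{lineno}: unparsable BOND line: {exc}") from exc
        system.add_bond(serial_map[a], serial_map[b], t)
    return system


def _split_subst(subst: str):
    """``ASN57A`` -> (ASN, 57, 'A'); trailing letter is the icode."""
    i = 0
    while i < len(subst) and not (subst[i].isdigit() or subst[i] == "-"):
        i += 1
    resname = subst[:i] or subst
    rest = subst[i:]
    icode = ""
    if rest and rest[-1].isalpha():
        icode = rest[-1]
        rest = rest[:-1]
    try:
        resseq = int(rest)
    except ValueError:
        resseq = 0
    return resname, resseq, icode
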