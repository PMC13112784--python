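"""PDB reading/writing (ATOM/HETATM/TER/CONECT).

Reading produces an *untyped* :class:`TypedMolecularSystem`: atoms are
grouped into residues by ``(chain, resseq, icode)``; SYBYL types, charges
and bonds are added afterwards by :func:`intprof.typing_data.apply_typing`.

Alternate-location policy follows crystallographic practice for this
pipeline: blank and ``'A'`` locations are kept, any residue containing
*only* other altLocs is an error (``altloc="reduce"`` silently drops the
extra locations instead).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple

from .structure import (
    Atom,
    Residue,
    StructureError,
    TypedMolecularSystem,
    format_residue_key,
)

__all__ = ["PdbFormatError", "read_pdb", "write_pdb"]


class PdbFormatError(StructureError):
    """Malformed PDB record; message carries the line number."""


_ELEMENT_FROM_NAME_HINTS = {"FE", "ZN", "MG", "NA", "CL", "CA", "NI", "BR", "SE"}


def _guess_element(name: str, resname: str) -> str:
    """Element from columns 77-78 fallback: strip digits from the name."""
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in _ELEMENT_FROM_NAME_HINTS \
            and resname.strip().upper() == stripped[:2].upper():
        return stripped[:2].upper()
    return stripped[:1].upper()


def read_pdb(path, *, altloc: str = "strict") -> TypedMolecularSystem:
    """Parse ATOM/HETATM records into an untyped system.

    ``altloc='strict'`` rejects residues whose atoms all carry non-A
    alternate-location indicators; ``'reduce'`` keeps the A/blank subset
    and drops the rest silently.
    """
    if altloc not in ("strict", "reduce"):
        raise ValueError("altloc must be 'strict' or 'reduce'")
    system = TypedMolecularSystem(name=str(path))
    order: List[Tuple] = []
    kept: Dict[Tuple, Residue] = {}
    dropped_only: Dict[Tuple, str] = {}
    seen_names: Dict[Tuple, Set[str]] = {}
    conect: List[Tuple[int, int]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    alt = line[16]
                    resname = line[17:20].strip()
                    chain = line[21].strip()
                    resseq = int(line[22:26])
                    icode = line[26].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    element = line[76:78].strip().upper() if len(line) >= 78 else ""
                except (ValueError, IndexError) as exc:
                    raise PdbFormatError(
                        f"{path}:{lineno}: unparsable {rec.strip()} record: {exc}"
                    ) from exc
                if not element:
                    element = _guess_element(line[12:16], resname)
                key = (chain, resseq, icode)
                if alt not in (" ", "A"):
                    dropped_only.setdefault(key, resname)
                    continue
                if key not in kept:
                    res = Residue(chain_id=chain, resseq=resseq, icode=icode, name=resname)
                    kept[key] = res
                    seen_names[key] = set()
                    order.append(key)
                if name in seen_names[key]:
                    raise PdbFormatError(
                        f"{path}:{lineno}: duplicate atom name {name!r} in residue "
                        f"{resname} {format_residue_key(key)}"
                    )
                seen_names[key].add(name)
                kept[key].atoms.append(
                    Atom(serial=serial, pdb_name=name, element=element, coords=(x, y, z))
                )
            elif rec == "CONECT":
                fields = line[6:].split()
                if len(fields) >= 2:
                    base = int(fields[0])
                    for other in fields[1:]:
                        conect.append((base, int(other)))

    if altloc == "strict":
        orphans = [k for k in dropped_only if k not in kept]
        if orphans:
            k = orphans[0]
            raise PdbFormatError(
                f"residue {dropped_only[k]} {format_residue_key(k)} has only "
                "alternate locations other than blank/'A'"
            )
    for key in order:
        system.add_residue(kept[key])
    system.declared_conect = conect  # consumed by typing for hetero bonds
    return system


def write_pdb(system: TypedMolecularSystem, path):
    """Write ATOM/HETATM records (fixed columns, icode preserved)."""
    with open(path, "w") as fh:
        last_chain: Optional[str] = None
        for res in system.residues.values():
            rec = "HETATM" if (res.is_water or len(res.atoms) == 1) else "ATOM  "
            if last_chain is not None and res.chain_id != last_chain and rec == "ATOM  ":
                fh.write("TER\n")
            last_chain = res.chain_id
            for a in res.atoms:
                name = a.pdb_name if len(a.pdb_name) == 4 else f" {a.pdb_name:<3s}"
                fh.write(
                    f"{rec}{a.serial:>5d} {name}{'':1s}{res.name:>3s} "
                    f"{res.chain_id:1s}{res.resseq:>4d}{res.icode or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
                )
        fh.write("END\n")
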