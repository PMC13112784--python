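"""Backbone-dependent rotamer library and the rotamer-energy descriptor.

The rotamer energy penalizes rare side-chain conformations::

    E = -R T ln(p / p_max)

with the gas constant R = 0.001987 kcal/(mol K), T = 300 K by default,
``p`` the library probability of the observed rotamer at the residue's
backbone (phi, psi) bin and ``p_max`` the largest rotamer probability in
that same bin.  The energy is zero for the most common rotamer and grows
as the observed rotamer becomes rarer.  For a residue pair the two
probabilities are multiplied (independence assumption), which makes the
pair energy exactly the sum of the single-residue energies.

The parser accepts the standard whitespace-separated backbone-dependent
library layout: ``resname phi psi count r1 r2 r3 r4 probability chi1..chi4
[sd1..sd4]``, with ``#`` comment lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .geometry import dihedral_deg
from .structure import Residue, ResidueKey, StructureError, TypedMolecularSystem

__all__ = [
    "GAS_CONSTANT_KCAL",
    "RotamerEnergyConfig",
    "RotamerRecord",
    "RotamerLibrary",
    "parse_rotamer_library",
    "rotamer_energy",
    "pair_rotamer_energy",
    "CHI_ATOMS",
    "measure_chi_angles",
    "backbone_phi_psi",
]

#: gas constant in kcal/(mol K)
GAS_CONSTANT_KCAL = 0.001987


@dataclass(frozen=True)
class RotamerEnergyConfig:
    R: float = GAS_CONSTANT_KCAL
    T: float = 300.0
    p_floor: float = 1e-6  # clamp for zero probabilities

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class RotamerRecord:
    residue: str
    phi: float
    psi: float
    rotamer: Tuple[int, ...]
    probability: float
    chi_means: Tuple[float, ...] = ()


class RotamerParseError(ValueError):
    pass


class RotamerLibrary:
    """Records indexed by (residue, phi bin, psi bin)."""

    def __init__(self, records: Sequence[RotamerRecord], bin_width: float = 10.0):
        self.bin_width = bin_width
        self._bins: Dict[Tuple[str, float, float], List[RotamerRecord]] = {}
        for rec in records:
            self._bins.setdefault((rec.residue, rec.phi, rec.psi), []).append(rec)

    def __len__(self) -> int:
        return sum(len(v) for v in self._bins.values())

    @property
    def residues(self):
        return sorted({k[0] for k in self._bins})

    def _nearest_grid(self, value: float) -> float:
        # round half away from zero onto the library grid, wrap to [-180, 180)
        w = self.bin_width
        snapped = math.floor(abs(value) / w + 0.5) * w * (1 if value >= 0 else -1)
        if snapped >= 180.0:
            snapped -= 360.0
        if snapped < -180.0:
            snapped += 360.0
        return snapped

    def bin_records(self, residue: str, phi: float, psi: float) -> List[RotamerRecord]:
        key = (residue.upper(), self._nearest_grid(phi), self._nearest_grid(psi))
        try:
            return self._bins[key]
        except KeyError as exc:
            raise KeyError(
                f"no rotamer records for {residue} at phi/psi bin {key[1]:.0f}/{key[2]:.0f}"
            ) from exc

    def probability(self, residue: str, phi: float, psi: float,
                    rotamer: Optional[Tuple[int, ...]] = None,
                    chis: Optional[Sequence[float]] = None) -> float:
        """Probability of a rotamer, located by id or by nearest chi means."""
        recs = self.bin_records(residue, phi, psi)
        if rotamer is not None:
            for rec in recs:
                if rec.rotamer == tuple(rotamer):
                    return rec.probability
            raise KeyError(f"rotamer {rotamer} not found for {residue}")
        if chis is None:
            raise ValueError("give either a rotamer id or measured chi angles")
        return min(recs, key=lambda r: _chi_distance(chis, r.chi_means)).probability

    def max_probability(self, residue: str, phi: float, psi: float) -> float:
        return max(r.probability for r in self.bin_records(residue, phi, psi))


def _wrap_deg(x: float) -> float:
    return (x + 180.0) % 360.0 - 180.0


def _chi_distance(chis: Sequence[float], means: Sequence[float]) -> float:
    n = min(len(chis), len(means))
    if n == 0:
        return float("inf")
    return sum(_wrap_deg(c - m) ** 2 for c, m in zip(chis[:n], means[:n]))


def parse_rotamer_library(path, bin_width: float = 10.0) -> RotamerLibrary:
    records: List[RotamerRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 9:
                raise RotamerParseError(
                    f"{path}:{lineno}: expected at least 9 fields, got {len(tok)}"
                )
            try:
                records.append(RotamerRecord(
                    residue=tok[0].upper(),
                    phi=float(tok[1]),
                    psi=float(tok[2]),
                    rotamer=tuple(int(v) for v in tok[4:8]),
                    probability=float(tok[8]),
                    chi_means=tuple(float(v) for v in tok[9:13]),
                ))
            except ValueError as exc:
                raise RotamerParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
    return RotamerLibrary(records, bin_width=bin_width)


def rotamer_energy(p: float, p_max: float,
                   config: RotamerEnergyConfig = RotamerEnergyConfig()) -> float:
    """-RT ln(p / p_max), in kcal/mol; zero iff p equals p_max."""
    if p_max <= 0 or p_max > 1:
        raise ValueError("maximum probability must be in (0, 1]")
    if p > p_max:
        raise ValueError(f"probability {p} exceeds maximum probability {p_max}")
    if p <= 0:
        warnings.warn("zero rotamer probability clamped", stacklevel=2)
        p = config.p_floor
    return -config.R * config.T * math.log(p / p_max)


def pair_rotamer_energy(p1: float, p1_max: float, p2: float, p2_max: float,
                        config: RotamerEnergyConfig = RotamerEnergyConfig()) -> float:
    """Energy of a residue pair under independent rotamer probabilities.

    Probabilities multiply, so the result equals the sum of the two
    single-residue energies exactly.
    """
    return rotamer_energy(p1 * p2, p1_max * p2_max, config)


# ---------------------------------------------------------------------
# measuring backbone and side-chain torsions from a structure

#: side-chain torsion definitions (chi1..chi4) per residue
CHI_ATOMS: Dict[str, List[Tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def measure_chi_angles(residue: Residue) -> List[float]:
    if residue.name not in CHI_ATOMS:
        raise StructureError(f"{residue.name} has no side-chain rotamers")
    chis = []
    for quad in CHI_ATOMS[residue.name]:
        coords = [residue.atom(n).coords for n in quad]
        chis.append(dihedral_deg(*coords))
    return chis


def backbone_phi_psi(system: TypedMolecularSystem, key: ResidueKey) -> Tuple[float, float]:
    """phi/psi of a residue from its chain neighbors (error at termini)."""
    res = system.residue(key)
    chain = [r for r in system.residues.values()
             if r.chain_id == res.chain_id and r.has_atom("CA")]
    idx = next(i for i, r in enumerate(chain) if r.key == key)
    if idx == 0 or idx == len(chain) - 1:
        raise StructureError("phi/psi undefined for terminal residues")
    prev_c = chain[idx - 1].atom("C").coords
    next_n = chain[idx + 1].atom("N").coords
    n, ca, c = (res.atom(x).coords for x in ("N", "CA", "C"))
    return dihedral_deg(prev_c, n, ca, c), dihedral_deg(n, ca, c, next_n)


def residue_rotamer_energy(
    system: TypedMolecularSystem,
    key: ResidueKey,
    library: RotamerLibrary,
    config: RotamerEnergyConfig = RotamerEnergyConfig(),
) -> float:
    """Rotamer energy of one residue: measure phi/psi + chis, look up, Eq."""
    res = system.residue(key)
    phi, psi = backbone_phi_psi(system, key)
    chis = measure_chi_angles(res)
    p = library.probability(res.name, phi, psi, chis=chis)
    p_max = library.max_probability(res.name, phi, psi)
    return rotamer_energy(p, p_max, config)
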