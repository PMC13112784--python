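"""Synthetic probe systems: minimal typed geometries for every rule.

Each probe is a two-(or three-)residue system engineered so that exactly
one interaction of the requested label is present (``satisfy=True``) or
absent (``satisfy=False``), with margins of at least 0.05 A / 2 deg to
every threshold so that tests never sit on a rule boundary.  Bond lengths
are idealized (C-H 1.09 A, N-H 1.01, O-H 0.96, S-H 1.34, C=O 1.23) and
charges come from the same template set as the typing dictionary; rule
thresholds, not chemical realism, are what these systems exercise.

The toy complex mimics a mutated-residue site: a glutamine-like target
surrounded by antibody and antigen fragments and two waters, one of which
bridges the target to the antigen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .structure import Atom, Residue, TypedMolecularSystem, assign_partner_classes

__all__ = ["ProbeSpec", "SystemBuilder", "make_probe", "make_toy_complex",
           "rigid_motion", "apply_rigid_motion", "PROBE_LABELS",
           "EXPECTED_TOY_HITS", "EXPECTED_TOY_BRIDGES", "EXPECTED_TOY_GROUPED"]


# idealized bond lengths (A)
_DH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}
_Q = {"C.3": 0.03, "C.2": 0.22, "C.ar": -0.06, "O.2": -0.27, "O.3": -0.38,
      "O.co2": -0.28, "N.am": -0.35, "N.2": -0.28, "N.4": -0.30, "S.3": -0.11,
      "H": 0.10}


class SystemBuilder:
    """Incremental construction of small typed systems for fixtures."""

    def __init__(self, name: str = "probe"):
        self.system = TypedMolecularSystem(name=name)
        self._serial = 0

    def residue(self, chain: str, resseq: int, name: str) -> Residue:
        res = Residue(chain_id=chain, resseq=resseq, icode="", name=name)
        self.system.add_residue(res)
        return res

    def atom(self, res: Residue, name: str, sybyl: str, xyz, charge: Optional[float] = None):
        self._serial += 1
        q = _Q.get(sybyl, 0.0) if charge is None else charge
        a = Atom(serial=self._serial, pdb_name=name, element=sybyl.split(".")[0].upper(),
                 coords=np.asarray(xyz, float), sybyl_type=sybyl, partial_charge=q)
        return self.system.add_atom(res, a)

    def bond(self, a, b, btype="1"):
        self.system.add_bond(a, b, btype)

    def ring(self, res: Residue, center, z: float, radius: float = 1.39,
             prefix: str = "CG", vertical: bool = False) -> List:
        """Six-membered aromatic carbon ring in the z-plane (or x-plane)."""
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = []
        for k, nm in enumerate(names):
            th = np.pi / 3.0 * k
            if vertical:
                xyz = (center[0], center[1] + radius * np.cos(th), center[2] + radius * np.sin(th))
            else:
                xyz = (center[0] + radius * np.cos(th), center[1] + radius * np.sin(th), z)
            atoms.append(self.atom(res, nm, "C.ar", xyz))
        for i in range(6):
            self.bond(atoms[i], atoms[(i + 1) % 6], "ar")
        return atoms

    def finish(self, targets=("A:1",), chains=None) -> TypedMolecularSystem:
        chains = chains or {"A": "Ab", "B": "Ab", "C": "Ag"}
        assign_partner_classes(self.system, {"targets": list(targets), "chains": chains})
        return self.system


@dataclass(frozen=True)
class ProbeSpec:
    label: str
    satisfy: bool = True
    jitter: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------
# X-H...Y probes: donor fragment on the target, acceptor on the partner

_XH_Y = {
    # label: (donor element, acceptor kind, d(H:A) satisfied)
    "HB_OH_O": ("O", "carbonyl_O", 1.90),
    "HB_NH_O": ("N", "carbonyl_O", 1.90),
    "HB_OH_N": ("O", "imine_N", 1.90),
    "HB_NH_N": ("N", "imine_N", 1.90),
    "Ele_OH_O": ("O", "carbonyl_O", 3.90 - 0.96),
    "Ele_NH_O": ("N", "carbonyl_O", 3.90 - 1.01),
    "Ele_OH_N": ("O", "imine_N", 3.90 - 0.96),
    "Ele_NH_N": ("N", "imine_N", 3.90 - 1.01),
    "CH_O": ("C", "carbonyl_O", 2.50),
    "CH_N": ("C", "imine_N", 2.50),
    "CH_S": ("C", "thiol_S", 2.60),
    "OH_S": ("O", "thiol_S", 2.60),
    "NH_S": ("N", "thiol_S", 2.60),
    "SH_O": ("S", "carbonyl_O", 2.40),
    "SH_N": ("S", "imine_N", 2.40),
    "SH_S": ("S", "thiol_S", 2.60),
}

_DONOR_SYBYL = {"C": "C.3", "N": "N.am", "O": "O.3", "S": "S.3"}
_DN_BOND = {"C": 1.52, "N": 1.47, "O": 1.43, "S": 1.81}
_AN_DIR = np.array([0.3, 0.954, 0.0])  # unit-ish direction for acceptor neighbors


def _build_xh_y(b: SystemBuilder, label: str, satisfy: bool):
    donor_el, acc_kind, d_ha = _XH_Y[label]
    dh = _DH[donor_el]
    m = b.residue("A", 1, "PRB")
    d_name = {"C": "CB", "N": "NB", "O": "OB", "S": "SB"}[donor_el]
    d_atom = b.atom(m, d_name, _DONOR_SYBYL[donor_el], (0.0, 0.0, 0.0))
    dn = b.atom(m, "CG", "C.3", np.array([-0.51, 1.31, 0.0]) / 1.406 * _DN_BOND[donor_el])
    h = b.atom(m, "HB1", "H", (dh, 0.0, 0.0))
    b.bond(d_atom, dn)
    b.bond(d_atom, h)
    if satisfy:
        a_pos = np.array([dh + d_ha, 0.0, 0.0])
    else:
        # angle(D:H:A) = 80 deg, well below the 94.58 deg minimum
        th = np.radians(100.0)
        a_pos = np.array([dh, 0.0, 0.0]) + d_ha * np.array([np.cos(th), np.sin(th), 0.0])
    p = b.residue("B", 1, "PRB")
    if acc_kind == "carbonyl_O":
        a = b.atom(p, "O1", "O.2", a_pos)
        an = b.atom(p, "C1", "C.2", a_pos + 1.23 * _AN_DIR)
        an2 = b.atom(p, "C2", "C.3", a_pos + 1.23 * _AN_DIR + 1.52 * _AN_DIR)
        b.bond(a, an, "2")
        b.bond(an, an2)
    elif acc_kind == "imine_N":
        a = b.atom(p, "N1", "N.2", a_pos)
        an = b.atom(p, "C1", "C.2", a_pos + 1.28 * _AN_DIR)
        an2 = b.atom(p, "C2", "C.3", a_pos + 1.28 * _AN_DIR + 1.52 * _AN_DIR)
        b.bond(a, an, "2")
        b.bond(an, an2)
    else:  # thiol_S
        a = b.atom(p, "S1", "S.3", a_pos)
        an = b.atom(p, "C1", "C.3", a_pos + 1.81 * _AN_DIR)
        ha = b.atom(p, "HS1", "H", a_pos + 1.34 * np.array([0.9, -0.436, 0.0]))
        b.bond(a, an)
        b.bond(a, ha)


# ---------------------------------------------------------------------
# X-H...pi probes: donor on the ring axis

_XH_PI = {"CH_PI": ("C", 3.80), "NH_PI": ("N", 3.70), "OH_PI": ("O", 3.60),
          "SH_PI": ("S", 3.90)}


def _build_xh_pi(b: SystemBuilder, label: str, satisfy: bool):
    donor_el, z_d = _XH_PI[label]
    dh = _DH[donor_el]
    # small offset makes one ring atom uniquely nearest; the large shift
    # pushes Nr outside the ring circle (violation)
    x0 = 0.3 if satisfy else 3.0
    m = b.residue("A", 1, "PRB")
    d_atom = b.atom(m, {"C": "CB", "N": "NB", "O": "OB", "S": "SB"}[donor_el],
                    _DONOR_SYBYL[donor_el], (x0, 0.0, z_d))
    dn = b.atom(m, "CG", "C.3", (x0 + 0.8, 0.8, z_d + 0.9))
    h = b.atom(m, "HB1", "H", (x0, 0.0, z_d - dh))
    b.bond(d_atom, dn)
    b.bond(d_atom, h)
    p = b.residue("B", 1, "PRB")
    b.ring(p, (0.0, 0.0, 0.0), z=0.0)


def _build_s_pi(b: SystemBuilder, satisfy: bool):
    x0 = 0.3 if satisfy else 3.0
    m = b.residue("A", 1, "PRB")
    s = b.atom(m, "SD", "S.3", (x0, 0.0, 3.9))
    cg = b.atom(m, "CG", "C.3", (x0 - 1.2, 0.9, 4.8))
    ce = b.atom(m, "CE", "C.3", (x0 + 1.2, -0.9, 4.8))
    b.bond(s, cg)
    b.bond(s, ce)
    p = b.residue("B", 1, "PRB")
    b.ring(p, (0.0, 0.0, 0.0), z=0.0)


def _build_pi_pi(b: SystemBuilder, satisfy: bool):
    m = b.residue("A", 1, "PRB")
    b.ring(m, (0.0, 0.0, 0.0), z=0.0)
    p = b.residue("B", 1, "PRB")
    if satisfy:
        # parallel-displaced stack: centroid separation 3.80 A, offset 1.0 A
        b.ring(p, (1.0, 0.0, 3.67), z=3.67)
    else:
        # perpendicular rings: interplanar angle 90 deg
        b.ring(p, (0.0, 0.0, 4.5), z=4.5, vertical=True)


# ---------------------------------------------------------------------
# dipole probes

def _build_omulpol(b: SystemBuilder, satisfy: bool):
    m = b.residue("A", 1, "PRB")
    cg = b.atom(m, "CG", "C.2", (0.0, 0.0, -1.23), charge=0.25)
    od1 = b.atom(m, "OD1", "O.2", (0.0, 0.0, 0.0), charge=-0.27)
    cb = b.atom(m, "CB", "C.3", (1.23, 0.0, -1.94), charge=0.03)
    b.bond(cg, od1, "2")
    b.bond(cb, cg)
    p = b.residue("B", 1, "PRB")
    shift = 0.0 if satisfy else 3.0  # lateral shift breaks perpendicularity
    c2 = b.atom(p, "C", "C.2", (shift, 0.0, 3.0), charge=0.25)
    o2 = b.atom(p, "O", "O.2", (shift + 1.23, 0.0, 3.0), charge=-0.27)
    ca2 = b.atom(p, "CA", "C.3", (shift - 1.23, 0.71, 3.0), charge=0.08)
    b.bond(c2, o2, "2")
    b.bond(ca2, c2)


def _build_dipo(b: SystemBuilder, satisfy: bool):
    m = b.residue("A", 1, "PRB")
    cg = b.atom(m, "CG", "C.2", (0.0, 0.0, 0.0), charge=0.25)
    od1 = b.atom(m, "OD1", "O.2", (1.23, 0.0, 0.0), charge=-0.27)
    cb = b.atom(m, "CB", "C.3", (-1.23, 0.71, 0.0), charge=0.03)
    b.bond(cg, od1, "2")
    b.bond(cb, cg)
    p = b.residue("B", 1, "PRB")
    cbp = b.atom(p, "CB", "C.3", (1.23, 0.0, 4.1), charge=0.03)
    if satisfy:
        # near-antiparallel (170 deg); reverse pairing exceeds the gate
        u = np.array([np.cos(np.radians(170.0)), 0.0, np.sin(np.radians(170.0))])
    else:
        u = np.array([0.0, 0.0, 1.0])  # perpendicular dipoles: alignment fails
    og = b.atom(p, "OG", "O.3", np.array([1.23, 0.0, 4.1]) + 1.43 * u, charge=-0.38)
    b.bond(cbp, og)


# ---------------------------------------------------------------------
# chalcogen probes: thioether sulfur toward an sp2/charged acceptor

def _build_chalcogen(b: SystemBuilder, label: str, satisfy: bool):
    m = b.residue("A", 1, "PRB")
    s = b.atom(m, "SD", "S.3", (0.0, 0.0, 0.0))
    cg = b.atom(m, "CG", "C.3", (-1.4, 1.15, 0.0))
    ce = b.atom(m, "CE", "C.3", (1.4, 1.15, 0.0))
    b.bond(s, cg)
    b.bond(s, ce)
    p = b.residue("B", 1, "PRB")
    if label == "S_O":
        d = 3.3 if satisfy else 4.6
        a = b.atom(p, "O1", "O.2", (0.0, -d, 0.0))
        an = b.atom(p, "C1", "C.2", (0.0, -d - 1.23, 0.0))
        b.bond(a, an, "2")
    elif label == "S_N":
        d = 3.4 if satisfy else 4.7
        a = b.atom(p, "N1", "N.2", (0.0, -d, 0.0))
        an = b.atom(p, "C1", "C.2", (0.0, -d - 1.28, 0.0))
        b.bond(a, an, "2")
    else:  # S_S
        d = 3.8 if satisfy else 5.0
        a = b.atom(p, "SD", "S.3", (0.0, -d, 0.0))
        cg2 = b.atom(p, "CG", "C.3", (-1.4, -d - 1.15, 0.0))
        ce2 = b.atom(p, "CE", "C.3", (1.4, -d - 1.15, 0.0))
        b.bond(a, cg2)
        b.bond(a, ce2)


# ---------------------------------------------------------------------
# metal / ion probes: carboxylate target, bare ion on the antigen chain

_METALS = {"Fe_A": ("FE", "Fe"), "Zn_A": ("ZN", "Zn"), "Ca_A": ("CA", "Ca"),
           "Mg_A": ("MG", "Mg"), "Ni_A": ("NI", "Ni"),
           "Na_A": ("NA", "Na"), "K_A": ("K", "K"), "Cl_A": ("CL", "Cl")}
_IONS = {"Na_A", "K_A", "Cl_A"}


def _build_metal(b: SystemBuilder, label: str, satisfy: bool):
    m = b.residue("A", 1, "PRB")
    cg = b.atom(m, "CG", "C.2", (0.0, 1.23, 0.0), charge=0.22)
    od1 = b.atom(m, "OD1", "O.co2", (0.0, 0.0, 0.0))
    od2 = b.atom(m, "OD2", "O.co2", (1.07, 1.85, 0.0))
    cb = b.atom(m, "CB", "C.3", (-1.07, 1.85, 0.0))
    b.bond(cg, od1, "ar")
    b.bond(cg, od2, "ar")
    b.bond(cb, cg)
    resname, sybyl = _METALS[label]
    if label in _IONS:
        d = 2.4 if satisfy else 4.0
    else:
        d = 2.1 if satisfy else 3.6
    ion_res = b.residue("C", 301, resname)
    b.atom(ion_res, resname, sybyl, (0.0, -d, 0.0), charge=1.0)


def _build_vdw(b: SystemBuilder, satisfy: bool):
    m = b.residue("A", 1, "PRB")
    cb = b.atom(m, "CB", "C.3", (0.0, 0.0, 0.0))
    p = b.residue("B", 1, "PRB")
    d = 4.0 if satisfy else 4.5  # C-C gate is 1.7 + 1.7 + 1.0 = 4.4 A
    c1 = b.atom(p, "C1", "C.3", (d, 0.0, 0.0))
    c2 = b.atom(p, "C2", "C.3", (d + 1.52, 0.0, 0.0))
    b.bond(c1, c2)


PROBE_LABELS: Tuple[str, ...] = tuple(
    list(_XH_Y) + list(_XH_PI) + ["S_PI", "PI_PI", "OMulPol", "Dipo",
                                  "S_O", "S_N", "S_S", "vdW"] + list(_METALS)
)


def make_probe(spec: ProbeSpec) -> TypedMolecularSystem:
    """Build the minimal probe system for one registry label."""
    label = spec.label
    b = SystemBuilder(name=f"probe_{label}_{'sat' if spec.satisfy else 'vio'}")
    if label in _XH_Y:
        _build_xh_y(b, label, spec.satisfy)
    elif label in _XH_PI:
        _build_xh_pi(b, label, spec.satisfy)
    elif label == "S_PI":
        _build_s_pi(b, spec.satisfy)
    elif label == "PI_PI":
        _build_pi_pi(b, spec.satisfy)
    elif label == "OMulPol":
        _build_omulpol(b, spec.satisfy)
    elif label == "Dipo":
        _build_dipo(b, spec.satisfy)
    elif label in ("S_O", "S_N", "S_S"):
        _build_chalcogen(b, label, spec.satisfy)
    elif label in _METALS:
        _build_metal(b, label, spec.satisfy)
    elif label == "vdW":
        _build_vdw(b, spec.satisfy)
    else:
        raise ValueError(f"unknown probe label {label!r}")
    system = b.finish()
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        for atom in system.atoms:
            atom.coords = atom.coords + rng.normal(0.0, spec.jitter, 3)
    return system


# ---------------------------------------------------------------------
# rigid motions (used by invariance tests and the toy complex)

def rigid_motion(seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """A deterministic random rotation matrix and translation vector."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10.0, 10.0, 3)
    return q, t


def apply_rigid_motion(system: TypedMolecularSystem, rotation: np.ndarray,
                       translation: np.ndarray) -> TypedMolecularSystem:
    for atom in system.atoms:
        atom.coords = rotation @ atom.coords + translation
    system._ring_cache = None
    return system


# ---------------------------------------------------------------------
# toy antibody-antigen-water complex around one target residue

#: expected detection result for the toy complex (any seed), computed once
#: with the exhaustive all-pairs oracle and frozen here
EXPECTED_TOY_HITS: Dict[str, int] = {
    "M#CH_N#Ag": 1, "M#CH_O#Ag": 1, "M#CH_PI#Ab": 1, "M#Ele_NH_O#Ab": 1,
    "M#HB_NH_O#S": 2, "M#HB_OH_O#Ab": 1, "M#vdW#Ab": 16, "M#vdW#Ag": 2,
    "M#vdW#S": 4,
}
EXPECTED_TOY_BRIDGES: Dict[str, int] = {
    "M#HB_NH_O#S#HB_OH_O#Ag": 1, "M#HB_NH_O#S#vdW#Ab": 1,
    "M#HB_NH_O#S#vdW#Ag": 2, "M#vdW#S#HB_OH_O#Ag": 3,
    "M#vdW#S#vdW#Ab": 3, "M#vdW#S#vdW#Ag": 6,
}
EXPECTED_TOY_GROUPED: Dict[str, int] = {
    "M#HB_OH_O#": 1, "M#Ele_NH_O#": 1, "M#CH_PI#": 1, "M#CH_O#": 1,
    "M#CH_N#": 1, "M#vdW#": 18, "M##S": 6, "M##S##": 16,
}


def make_toy_complex(seed: int = 0):
    """A glutamine-like target residue with engineered surroundings.

    Engineered contacts: a serine hydroxyl hydrogen-bonding the target
    carbonyl (HB_OH_O, Ab), an ammonium at 3.9 A (Ele_NH_O, Ab), an
    antigen C-H donating to the carbonyl (CH_O, Ag), a target C-H over an
    antibody phenyl ring (CH_PI, Ab), an apolar carbon in vdW contact,
    one water bridging the target amide N-H to an antigen carbonyl
    (M#HB_NH_O#S#HB_OH_O#Ag) and one water touching the target only.
    A seed-dependent rigid motion is applied to the whole complex; all
    detected interactions are invariant under it.
    """
    b = SystemBuilder(name=f"toy_complex_{seed}")
    m = b.residue("A", 1, "GLN")
    # backbone (excluded from the analyzed atom set)
    n = b.atom(m, "N", "N.am", (-2.2, 3.4, -1.4))
    ca = b.atom(m, "CA", "C.3", (-2.0, 3.3, -0.5), charge=0.08)
    c = b.atom(m, "C", "C.2", (-2.9, 4.0, 0.3))
    o = b.atom(m, "O", "O.2", (-3.9, 4.5, -0.2))
    b.bond(n, ca)
    b.bond(ca, c)
    b.bond(c, o, "2")
    # side chain
    cb = b.atom(m, "CB", "C.3", (-1.47, 2.28, 0.0))
    cg = b.atom(m, "CG", "C.3", (-0.77, 1.08, 0.0))
    cd = b.atom(m, "CD", "C.2", (0.0, 0.0, 0.0))
    oe1 = b.atom(m, "OE1", "O.2", (1.23, 0.0, 0.0))
    ne2 = b.atom(m, "NE2", "N.am", (-0.67, -1.15, 0.0))
    b.bond(ca, cb)
    b.bond(cb, cg)
    b.bond(cg, cd)
    b.bond(cd, oe1, "2")
    b.bond(cd, ne2, "am")
    hb1 = b.atom(m, "HB1", "H", (-1.47, 2.28, 1.09))       # points at the Phe ring
    hg1 = b.atom(m, "HG1", "H", (-0.77, 0.78, -1.03))
    he21 = b.atom(m, "HE21", "H", (-0.67, -1.15, -1.01))   # points at water W1
    he22 = b.atom(m, "HE22", "H", (-1.53, -1.55, 0.347))  # points at water W2
    b.bond(cb, hb1)
    b.bond(cg, hg1)
    b.bond(ne2, he21)
    b.bond(ne2, he22)

    # Ab serine: OG-HG donates to OE1 along +x (HB_OH_O)
    ser = b.residue("B", 10, "SER")
    og = b.atom(ser, "OG", "O.3", (4.09, 0.0, 0.0))
    hg = b.atom(ser, "HG", "H", (3.13, 0.0, 0.0))
    scb = b.atom(ser, "CB", "C.3", (4.57, 1.35, 0.0))
    b.bond(og, hg)
    b.bond(scb, og)

    # Ab lysine-like ammonium: N-H toward OE1 at 3.9 A (Ele_NH_O)
    lys = b.residue("B", 11, "LYS")
    nz = b.atom(lys, "NZ", "N.4", (1.23, 3.9, 0.0))
    hz1 = b.atom(lys, "HZ1", "H", (1.23, 2.89, 0.0))
    hz2 = b.atom(lys, "HZ2", "H", (0.52, 4.42, 0.35))
    hz3 = b.atom(lys, "HZ3", "H", (1.94, 4.42, -0.35))
    ce = b.atom(lys, "CE", "C.3", (1.23, 5.1, 1.2))
    b.bond(nz, hz1)
    b.bond(nz, hz2)
    b.bond(nz, hz3)
    b.bond(ce, nz)

    # Ag tryptophan-like C-H donating to OE1 (CH_O, antigen partner)
    agc = b.residue("C", 20, "TRP")
    wcb = b.atom(agc, "CB", "C.3", (1.23, -3.69, 0.0))
    wh = b.atom(agc, "HB1", "H", (1.23, -2.60, 0.0))
    wcg = b.atom(agc, "CG", "C.3", (0.72, -5.00, 0.0))
    b.bond(wcb, wh)
    b.bond(wcb, wcg)

    # Ab phenylalanine ring 3.8 A above the target CB hydrogen (CH_PI)
    phe = b.residue("B", 12, "PHE")
    b.ring(phe, (-1.47, 2.28, 0.0), z=3.85)

    # Ab leucine-like apolar carbon in vdW contact with the carbonyl O
    leu = b.residue("B", 13, "LEU")
    lcd = b.atom(leu, "CD1", "C.3", (2.4, -1.0, -3.7))
    lcg = b.atom(leu, "CG2", "C.3", (3.7, -1.75, -3.96))
    b.bond(lcd, lcg)

    # water W1: accepts from NE2-H, donates to the antigen carbonyl below
    w1 = b.residue("W", 100, "HOH")
    ow1 = b.atom(w1, "O", "O.3", (-0.67, -1.15, -2.91), charge=-0.41)
    hw11 = b.atom(w1, "H1", "H", (-0.67, -1.15, -3.87), charge=0.205)
    hw12 = b.atom(w1, "H2", "H", (0.20, -1.15, -2.61), charge=0.205)
    b.bond(ow1, hw11)
    b.bond(ow1, hw12)

    # antigen backbone carbonyl under W1 (bridge partner)
    agg = b.residue("C", 21, "GLY")
    go = b.atom(agg, "O", "O.2", (-0.67, -1.15, -5.77))
    gc = b.atom(agg, "C", "C.2", (-0.301, 0.023, -5.77))
    gca = b.atom(agg, "CA", "C.3", (0.155, 1.473, -5.77), charge=0.08)
    b.bond(gc, go, "2")
    b.bond(gca, gc)

    # water W2: accepts the second amide hydrogen; touches the target only,
    # so it contributes an M-S hit but no bridge
    w2 = b.residue("W", 101, "HOH")
    ow2 = b.atom(w2, "O", "O.3", (-3.24, -2.33, 1.03), charge=-0.41)
    hw21 = b.atom(w2, "H1", "H", (-4.06, -2.71, 1.36), charge=0.205)
    hw22 = b.atom(w2, "H2", "H", (-3.05, -3.26, 0.77), charge=0.205)
    b.bond(ow2, hw21)
    b.bond(ow2, hw22)

    system = b.finish(targets=("A:1",), chains={"A": "Ab", "B": "Ab", "C": "Ag", "W": "Ab"})
    rot, trans = rigid_motion(seed)
    apply_rigid_motion(system, rot, trans)
    return system
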