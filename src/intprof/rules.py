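"""Declarative registry of the 36 interaction definitions and evaluators.

Every interaction is an operational definition: participant constraints
(element / SYBYL-type / bonding requirements on the donor D, hydrogen H,
acceptor A, ring, or dipole atoms Dpn+/Dpn-) plus a conjunction of
geometric and charge predicates.  The registry holds 28 direct labels,
5 metal labels and 3 ion labels.

The geometric template of the CH...O weak hydrogen bond::

    d(D:A) <= RvdW(D) + RvdW(A) + buffer
    d(D:A) <= d(Dn:A)   for every heavy neighbor Dn of D
    d(D:A) <= d(D:An)   for every heavy neighbor An of A
    d(H:A) <= d(D:A)
    d(H:A) <= 3.22 A
    94.58 deg <= angle(D:H:A) <= 180 deg

is shared by every X-H...Y rule (per-rule H:A cap and angle minimum are
overridable through the criteria config); X-H...pi rules share the
CH...pi template; conventional hydrogen bonds and electrostatic contacts
additionally split on the heavy-atom distance at 3.2 A (boundary goes to
the hydrogen bond).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .geometry import (
    GeometryProbe,
    RingSystem,
    angle_deg,
    distance,
    foot_of_perpendicular,
    best_fit_plane,
    GeometryError,
)
from .structure import Atom, TypedMolecularSystem

__all__ = [
    "VdwRadiusTable",
    "RuleParameters",
    "InteractionRule",
    "RuleRegistry",
    "build_registry",
    "DEFAULT_PRIORITY",
    "load_priority",
    "load_criteria",
    "load_radii",
    "evaluate_xh_y",
    "evaluate_ch_o",
    "classify_polar_contact",
    "evaluate_xh_pi",
    "evaluate_ch_pi",
    "evaluate_s_pi",
    "evaluate_pi_pi",
    "evaluate_omulpol",
    "evaluate_dipo",
    "evaluate_chalcogen",
    "evaluate_metal",
    "evaluate_vdw_contact",
    "water_can_participate",
]


# ---------------------------------------------------------------------
# van der Waals radii (Bondi set; metals/ions from standard compilations)

_BONDI = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31,
    "FE": 2.05, "NI": 1.63, "ZN": 1.39,
}


class VdwRadiusTable(dict):
    """Element -> vdW radius (A).  Missing elements raise ``KeyError``."""

    @classmethod
    def default(cls) -> "VdwRadiusTable":
        return cls(_BONDI)

    def radius(self, atom: Atom) -> float:
        return self[atom.element.upper()]


def load_radii(path) -> VdwRadiusTable:
    """vdW radius file: one ``ELEMENT radius`` pair per line, # comments."""
    table = VdwRadiusTable.default()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            try:
                el, r = line.split()
                table[el.upper()] = float(r)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad radius line {line!r}") from exc
    return table


# ---------------------------------------------------------------------
# parameters

@dataclass
class RuleParameters:
    """Global defaults plus per-label overrides (the criteria config)."""

    vdw_buffer: float = 1.0
    hb_ele_cutoff: float = 3.2
    xh_y_ha_max: float = 3.22
    xh_y_angle_min: float = 94.58
    xh_pi_ha_inner: float = 3.195
    xh_pi_ha_outer: float = 3.325
    xh_pi_angle_min: float = 124.455
    ring_radius_factor: float = 1.4
    dipole_charge_gap: float = 0.2
    omulpol_buffer: float = 0.7
    omulpol_perp_window: Tuple[float, float] = (75.0, 105.0)
    omulpol_nr_window: Tuple[float, float] = (0.0, 35.0)
    omulpol_anti_window: Tuple[float, float] = (150.0, 180.0)
    dipo_align_window: Tuple[float, float] = (135.0, 180.0)
    pi_pi_cn_max: float = 5.5
    pi_pi_angle_max: float = 30.0
    metal_coord_max: float = 3.0
    ion_coord_max: float = 3.4
    overrides: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def get(self, label: str, name: str):
        per_rule = self.overrides.get(label, {})
        if name in per_rule:
            return per_rule[name]
        return getattr(self, name)

    def buffer(self, label: str) -> float:
        per_rule = self.overrides.get(label, {})
        if "vdw_buffer" in per_rule:
            return per_rule["vdw_buffer"]
        if label == "OMulPol":
            return self.omulpol_buffer
        return self.vdw_buffer


def load_criteria(path) -> RuleParameters:
    """Interaction criteria file (YAML): global keys + per-label overrides.

    Example::

        vdw_buffer: 1.0
        overrides:
          CH_O: {vdw_buffer: 1.2}
          CH_PI: {xh_pi_ha_inner: 3.0}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = RuleParameters()
    for key, value in raw.items():
        if key == "overrides":
            params.overrides = {str(k): dict(v) for k, v in value.items()}
        elif hasattr(params, key):
            setattr(params, key, tuple(value) if isinstance(value, list) else value)
        else:
            raise ValueError(f"unknown criteria key {key!r}")
    return params


# ---------------------------------------------------------------------
# the registry

@dataclass(frozen=True)
class InteractionRule:
    label: str
    category: str  # hbond, electrostatic, weak_hbond, pi, sulfur, dipole, vdw, metal, ion
    kind: str      # xh_y, xh_pi, s_pi, pi_pi, chalcogen, omulpol, dipo, vdw, metal, ion
    donor_element: Optional[str] = None
    acceptor_element: Optional[str] = None
    metal_element: Optional[str] = None


_DIRECT_SPECS = [
    ("HB_OH_O", "hbond", "xh_y", "O", "O"),
    ("HB_NH_O", "hbond", "xh_y", "N", "O"),
    ("HB_OH_N", "hbond", "xh_y", "O", "N"),
    ("HB_NH_N", "hbond", "xh_y", "N", "N"),
    ("Ele_OH_O", "electrostatic", "xh_y", "O", "O"),
    ("Ele_NH_O", "electrostatic", "xh_y", "N", "O"),
    ("Ele_OH_N", "electrostatic", "xh_y", "O", "N"),
    ("Ele_NH_N", "electrostatic", "xh_y", "N", "N"),
    ("PI_PI", "pi", "pi_pi", None, None),
    ("CH_PI", "pi", "xh_pi", "C", None),
    ("NH_PI", "pi", "xh_pi", "N", None),
    ("S_PI", "pi", "s_pi", "S", None),
    ("CH_O", "weak_hbond", "xh_y", "C", "O"),
    ("CH_N", "weak_hbond", "xh_y", "C", "N"),
    ("CH_S", "weak_hbond", "xh_y", "C", "S"),
    ("OH_S", "weak_hbond", "xh_y", "O", "S"),
    ("NH_S", "weak_hbond", "xh_y", "N", "S"),
    ("SH_O", "weak_hbond", "xh_y", "S", "O"),
    ("SH_N", "weak_hbond", "xh_y", "S", "N"),
    ("SH_S", "weak_hbond", "xh_y", "S", "S"),
    ("OH_PI", "pi", "xh_pi", "O", None),
    ("SH_PI", "pi", "xh_pi", "S", None),
    ("S_O", "sulfur", "chalcogen", "S", "O"),
    ("S_N", "sulfur", "chalcogen", "S", "N"),
    ("S_S", "sulfur", "chalcogen", "S", "S"),
    ("OMulPol", "dipole", "omulpol", None, None),
    ("Dipo", "dipole", "dipo", None, None),
    ("vdW", "vdw", "vdw", None, None),
]
_METAL_SPECS = [("Fe_A", "FE"), ("Zn_A", "ZN"), ("Ca_A", "CA"), ("Mg_A", "MG"), ("Ni_A", "NI")]
_ION_SPECS = [("Na_A", "NA"), ("K_A", "K"), ("Cl_A", "CL")]


class RuleRegistry(dict):
    """Ordered label -> :class:`InteractionRule` map (exactly 36 labels)."""

    @property
    def direct_labels(self) -> List[str]:
        return [r.label for r in self.values() if r.category not in ("metal", "ion")]

    @property
    def metal_labels(self) -> List[str]:
        return [r.label for r in self.values() if r.category == "metal"]

    @property
    def ion_labels(self) -> List[str]:
        return [r.label for r in self.values() if r.category == "ion"]


def build_registry() -> RuleRegistry:
    reg = RuleRegistry()
    for label, cat, kind, de, ae in _DIRECT_SPECS:
        reg[label] = InteractionRule(label, cat, kind, donor_element=de, acceptor_element=ae)
    for label, el in _METAL_SPECS:
        reg[label] = InteractionRule(label, "metal", "metal", metal_element=el)
    for label, el in _ION_SPECS:
        reg[label] = InteractionRule(label, "ion", "ion", metal_element=el)
    assert len(reg) == 36
    return reg


#: highest priority first: when several rules accept the same atom pair,
#: the first label in this list wins (overridable via the priority file)
DEFAULT_PRIORITY: List[str] = (
    [m for m, _ in _METAL_SPECS]
    + [i for i, _ in _ION_SPECS]
    + ["HB_OH_O", "HB_NH_O", "HB_OH_N", "HB_NH_N",
       "Ele_OH_O", "Ele_NH_O", "Ele_OH_N", "Ele_NH_N",
       "OMulPol", "Dipo", "S_O", "S_N", "S_S",
       "NH_PI", "OH_PI", "SH_PI", "CH_PI", "PI_PI", "S_PI",
       "CH_O", "CH_N", "CH_S", "OH_S", "NH_S", "SH_O", "SH_N", "SH_S",
       "vdW"]
)


def load_priority(path) -> List[str]:
    """Priority file: one label per line, highest priority first."""
    labels = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if line:
                labels.append(line)
    registry = build_registry()
    unknown = [l for l in labels if l not in registry]
    if unknown:
        raise ValueError(f"priority file lists unknown labels: {unknown}")
    missing = [l for l in registry if l not in labels]
    if missing:
        raise ValueError(f"priority file must cover all labels; missing: {missing}")
    return labels


# ---------------------------------------------------------------------
# participant eligibility helpers

def donor_ok(rule: InteractionRule, system: TypedMolecularSystem, D: Atom) -> bool:
    if D.element != rule.donor_element:
        return False
    return len(system.bonded_hydrogens(D)) > 0


def acceptor_ok(rule: InteractionRule, system: TypedMolecularSystem, A: Atom) -> bool:
    if A.element != rule.acceptor_element:
        return False
    if A.element == "N" and A.sybyl_type == "N.4":
        return False  # quaternary/protonated N has no lone pair
    return True


_CHALCOGEN_ACCEPTOR_TYPES = {"O": {"O.2", "O.co2"}, "N": {"N.2", "N.ar"}}


def chalcogen_sulfur_ok(system: TypedMolecularSystem, S: Atom) -> bool:
    """Divalent sulfur with two heavy neighbors (thioether / disulfide)."""
    return S.element == "S" and len(system.heavy_neighbors(S)) == 2


def chalcogen_acceptor_ok(rule: InteractionRule, system: TypedMolecularSystem, A: Atom) -> bool:
    el = rule.acceptor_element
    if A.element != el:
        return False
    if el == "S":
        return chalcogen_sulfur_ok(system, A)
    return A.sybyl_type in _CHALCOGEN_ACCEPTOR_TYPES[el]


# ---------------------------------------------------------------------
# predicate evaluators

def _gate(radii: VdwRadiusTable, a: Atom, b: Atom, buffer: float) -> float:
    return radii.radius(a) + radii.radius(b) + buffer


def evaluate_xh_y(
    rule: InteractionRule,
    system: TypedMolecularSystem,
    D: Atom,
    H: Atom,
    A: Atom,
    params: RuleParameters,
    radii: VdwRadiusTable,
) -> Tuple[bool, GeometryProbe]:
    """CH...O template for every X-H...Y rule (incl. HB_* / Ele_* split)."""
    if D.residue_key == A.residue_key:
        return False, GeometryProbe()
    d_da = distance(D.coords, A.coords)
    d_ha = distance(H.coords, A.coords)
    probe = GeometryProbe({"d_DA": d_da, "d_HA": d_ha})
    if d_da > _gate(radii, D, A, params.buffer(rule.label)):
        return False, probe
    # directionality via neighbors (vacuously true when absent)
    for dn in system.heavy_neighbors(D):
        if d_da > distance(dn.coords, A.coords):
            return False, probe
    for an in system.heavy_neighbors(A):
        if d_da > distance(D.coords, an.coords):
            return False, probe
    if d_ha > d_da:
        return False, probe
    if d_ha > params.get(rule.label, "xh_y_ha_max"):
        return False, probe
    ang = angle_deg(D.coords, H.coords, A.coords)
    probe["ang_DHA"] = ang
    if ang < params.get(rule.label, "xh_y_angle_min"):
        return False, probe
    cutoff = params.get(rule.label, "hb_ele_cutoff")
    if rule.category == "hbond" and d_da > cutoff:
        return False, probe
    if rule.category == "electrostatic" and d_da <= cutoff:
        return False, probe
    return True, probe


def evaluate_ch_o(D, H, A, system, params, radii):
    """Spec-facing alias: CH...O evaluation of a single (D, H, A) binding."""
    rule = build_registry()["CH_O"]
    if D.element != "C" or A.element != "O":
        raise ValueError("CH_O requires a carbon donor and oxygen acceptor")
    return evaluate_xh_y(rule, system, D, H, A, params, radii)


def classify_polar_contact(
    system: TypedMolecularSystem,
    D: Atom,
    H: Atom,
    A: Atom,
    params: RuleParameters,
    radii: VdwRadiusTable,
) -> Optional[str]:
    """Label a polar X-H...Y contact ``HB_<DH>_<A>`` or ``Ele_<DH>_<A>``.

    The heavy-atom distance decides the family: <= 3.2 A is a hydrogen
    bond, beyond 3.2 A but within the vdW gate is electrostatic, beyond
    the gate is nothing.
    """
    if D.element not in ("N", "O"):
        raise ValueError(f"polar donor must be N or O, got {D.element}")
    registry = build_registry()
    for prefix in ("HB", "Ele"):
        label = f"{prefix}_{D.element}H_{A.element}"
        rule = registry.get(label)
        if rule is None:
            continue
        ok, _ = evaluate_xh_y(rule, system, D, H, A, params, radii)
        if ok:
            return label
    return None


def evaluate_xh_pi(
    rule: InteractionRule,
    system: TypedMolecularSystem,
    D: Atom,
    H: Atom,
    ring: RingSystem,
    params: RuleParameters,
    radii: VdwRadiusTable,
) -> Tuple[bool, GeometryProbe, Optional[Atom]]:
    """CH...pi template; reports the nearest qualifying ring atom A.

    At most one hit per (D, ring) pair: candidates are scanned in order
    of increasing d(H:A) (ties broken by serial) and the first qualifying
    ring atom is reported.
    """
    if not ring.member_serials:
        raise GeometryError("ring has no member atoms bound to the system")
    label = rule.label
    x = params.get(label, "ring_radius_factor")
    inner = params.get(label, "xh_pi_ha_inner")
    outer = params.get(label, "xh_pi_ha_outer")
    ang_min = params.get(label, "xh_pi_angle_min")
    buffer = params.buffer(label)
    nr = foot_of_perpendicular(H.coords, ring.plane)
    members = sorted(
        (system.atom_by_serial(s) for s in ring.member_serials),
        key=lambda a: (distance(H.coords, a.coords), a.serial),
    )
    dn_atoms = system.heavy_neighbors(D)
    for A in members:
        if A.residue_key == D.residue_key:
            continue
        d_da = distance(D.coords, A.coords)
        d_ha = distance(H.coords, A.coords)
        if d_da > _gate(radii, D, A, buffer):
            continue
        if any(d_da > distance(dn.coords, A.coords) for dn in dn_atoms):
            continue
        if d_ha > d_da:
            continue
        d_nr_cn = distance(nr, ring.cn)
        d_cn_a = distance(ring.cn, A.coords)
        if d_nr_cn > x * d_cn_a:
            continue
        ang = angle_deg(D.coords, H.coords, A.coords)
        if not (d_ha <= inner or (inner < d_ha <= outer and ang >= ang_min)):
            continue
        probe = GeometryProbe(
            {"d_DA": d_da, "d_HA": d_ha, "d_Nr_cn": d_nr_cn, "ang_DHA": ang}
        )
        return True, probe, A
    return False, GeometryProbe(), None


def evaluate_ch_pi(D, H, ring, system, params, radii):
    """Spec-facing alias for the CH...pi rule."""
    return evaluate_xh_pi(build_registry()["CH_PI"], system, D, H, ring, params, radii)


def evaluate_s_pi(
    rule: InteractionRule,
    system: TypedMolecularSystem,
    S: Atom,
    ring: RingSystem,
    params: RuleParameters,
    radii: VdwRadiusTable,
) -> Tuple[bool, GeometryProbe, Optional[Atom]]:
    """Sulfur-aromatic contact: vdW gate + perpendicular-foot-in-circle."""
    x = params.get(rule.label, "ring_radius_factor")
    buffer = params.buffer(rule.label)
    nr = foot_of_perpendicular(S.coords, ring.plane)
    members = sorted(
        (system.atom_by_serial(s) for s in ring.member_serials),
        key=lambda a: (distance(S.coords, a.coords), a.serial),
    )
    sn_atoms = system.heavy_neighbors(S)
    for A in members:
        if A.residue_key == S.residue_key:
            continue
        d_sa = distance(S.coords, A.coords)
        if d_sa > _gate(radii, S, A, buffer):
            continue
        if any(d_sa > distance(sn.coords, A.coords) for sn in sn_atoms):
            continue
        d_nr_cn = distance(nr, ring.cn)
        if d_nr_cn > x * distance(ring.cn, A.coords):
            continue
        return True, GeometryProbe({"d_SA": d_sa, "d_Nr_cn": d_nr_cn}), A
    return False, GeometryProbe(), None


def evaluate_pi_pi(
    ring1: RingSystem,
    ring2: RingSystem,
    params: RuleParameters,
) -> Tuple[bool, GeometryProbe]:
    """Face-to-face stacking: centroid gate, interplanar angle, offset."""
    d_cn = distance(ring1.cn, ring2.cn)
    probe = GeometryProbe({"d_cn_cn": d_cn})
    if d_cn > params.get("PI_PI", "pi_pi_cn_max"):
        return False, probe
    cosang = abs(float(np.dot(ring1.normal, ring2.normal)))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    probe["ang_planes"] = ang
    if ang > params.get("PI_PI", "pi_pi_angle_max"):
        return False, probe
    x = params.get("PI_PI", "ring_radius_factor")
    off1 = distance(foot_of_perpendicular(ring2.cn, ring1.plane), ring1.cn)
    off2 = distance(foot_of_perpendicular(ring1.cn, ring2.plane), ring2.cn)
    probe["offset"] = min(off1, off2)
    if off1 > x * ring1.radius and off2 > x * ring2.radius:
        return False, probe
    return True, probe


def sp2_plane_of(system: TypedMolecularSystem, center: Atom):
    """Plane of an sp2 group: the center atom and its covalent neighbors."""
    pts = [center.coords] + [n.coords for n in system.neighbors(center)]
    if len(pts) < 3:
        return None
    try:
        return best_fit_plane(np.array(pts))
    except GeometryError:
        return None


def evaluate_omulpol(
    system: TypedMolecularSystem,
    dp1_plus: Atom,
    dp1_minus: Atom,
    dp2_plus: Atom,
    dp2_minus: Atom,
    params: RuleParameters,
    radii: VdwRadiusTable,
) -> Tuple[bool, GeometryProbe]:
    """Orthogonal multipolar contact (canonical perpendicular C=O...C=O).

    Nr is the foot of the perpendicular from Dp1- onto the sp2 plane of
    dipole 2's group (Dp2+ and its covalent neighbors).
    """
    for a in (dp1_plus, dp1_minus, dp2_plus, dp2_minus):
        if a.partial_charge is None:
            raise ValueError(f"atom {a.serial} lacks a partial charge")
    gap = params.get("OMulPol", "dipole_charge_gap")
    probe = GeometryProbe()
    if abs(dp1_plus.partial_charge - dp1_minus.partial_charge) < gap:
        return False, probe
    if abs(dp2_plus.partial_charge - dp2_minus.partial_charge) < gap:
        return False, probe
    d = distance(dp1_minus.coords, dp2_plus.coords)
    probe["d_Dp1m_Dp2p"] = d
    if d > _gate(radii, dp1_minus, dp2_plus, params.buffer("OMulPol")):
        return False, probe
    if d > distance(dp1_plus.coords, dp2_plus.coords):
        return False, probe
    lo, hi = params.get("OMulPol", "omulpol_perp_window")
    ang1 = angle_deg(dp2_minus.coords, dp2_plus.coords, dp1_minus.coords)
    probe["ang_Dp2m_Dp2p_Dp1m"] = ang1
    if not (lo <= ang1 <= hi):
        return False, probe
    plane2 = sp2_plane_of(system, dp2_plus)
    if plane2 is None:
        return False, probe
    nr = foot_of_perpendicular(dp1_minus.coords, plane2)
    if distance(nr, dp1_minus.coords) < 1e-9:
        # Dp1- lies exactly in the plane: the perpendicular degenerates
        return False, probe
    lo, hi = params.get("OMulPol", "omulpol_nr_window")
    if distance(nr, dp2_plus.coords) < 1e-9:
        ang2 = 0.0  # Nr coincides with Dp2+: perfectly perpendicular approach
    else:
        ang2 = angle_deg(nr, dp1_minus.coords, dp2_plus.coords)
    probe["ang_Nr_Dp1m_Dp2p"] = ang2
    if not (lo <= ang2 <= hi):
        return False, probe
    lo, hi = params.get("OMulPol", "omulpol_anti_window")
    ang3 = angle_deg(nr, dp1_minus.coords, dp1_plus.coords)
    probe["ang_Nr_Dp1m_Dp1p"] = ang3
    if not (lo <= ang3 <= hi):
        return False, probe
    return True, probe


def evaluate_dipo(
    system: TypedMolecularSystem,
    dp1_plus: Atom,
    dp1_minus: Atom,
    dp2_plus: Atom,
    dp2_minus: Atom,
    params: RuleParameters,
    radii: VdwRadiusTable,
) -> Tuple[bool, GeometryProbe]:
    """Antiparallel bond-dipole contact (reconstructed definition).

    Both dipoles must clear the charge gap; the negative pole of dipole 1
    approaches the positive pole of dipole 2 within the vdW gate and the
    two bond-dipole vectors are antiparallel within the alignment window.
    """
    gap = params.get("Dipo", "dipole_charge_gap")
    probe = GeometryProbe()
    if abs(dp1_plus.partial_charge - dp1_minus.partial_charge) < gap:
        return False, probe
    if abs(dp2_plus.partial_charge - dp2_minus.partial_charge) < gap:
        return False, probe
    d = distance(dp1_minus.coords, dp2_plus.coords)
    probe["d_Dp1m_Dp2p"] = d
    if d > _gate(radii, dp1_minus, dp2_plus, params.buffer("Dipo")):
        return False, probe
    v1 = dp1_minus.coords - dp1_plus.coords
    v2 = dp2_minus.coords - dp2_plus.coords
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    probe["ang_align"] = ang
    lo, hi = params.get("Dipo", "dipo_align_window")
    if not (lo <= ang <= hi):
        return False, probe
    return True, probe


def evaluate_chalcogen(
    rule: InteractionRule,
    system: TypedMolecularSystem,
    S: Atom,
    A: Atom,
    params: RuleParameters,
    radii: VdwRadiusTable,
) -> Tuple[bool, GeometryProbe]:
    """S...O / S...N / S...S heavy-atom contact with acceptor typing."""
    if not chalcogen_sulfur_ok(system, S):
        return False, GeometryProbe()
    if not chalcogen_acceptor_ok(rule, system, A):
        return False, GeometryProbe()
    if S.residue_key == A.residue_key:
        return False, GeometryProbe()
    d = distance(S.coords, A.coords)
    probe = GeometryProbe({"d_SA": d})
    if d > _gate(radii, S, A, params.buffer(rule.label)):
        return False, probe
    for sn in system.heavy_neighbors(S):
        if d > distance(sn.coords, A.coords):
            return False, probe
    return True, probe


def evaluate_metal(
    rule: InteractionRule,
    metal: Atom,
    A: Atom,
    params: RuleParameters,
) -> Tuple[bool, GeometryProbe]:
    """Coordination gate: metal/ion within cutoff of an N/O/S atom."""
    if metal.element != rule.metal_element:
        return False, GeometryProbe()
    if A.element not in ("N", "O", "S"):
        return False, GeometryProbe()
    cutoff = params.get(
        rule.label, "metal_coord_max" if rule.category == "metal" else "ion_coord_max"
    )
    d = distance(metal.coords, A.coords)
    return d <= cutoff, GeometryProbe({"d_MA": d})


def evaluate_vdw_contact(
    a1: Atom,
    a2: Atom,
    params: RuleParameters,
    radii: VdwRadiusTable,
    already_assigned=(),
) -> Tuple[bool, GeometryProbe]:
    """Heavy-atom contact within the buffered vdW gate, not otherwise labeled."""
    if not (a1.is_heavy and a2.is_heavy) or a1.residue_key == a2.residue_key:
        return False, GeometryProbe()
    pair = frozenset((a1.serial, a2.serial))
    if pair in already_assigned:
        return False, GeometryProbe()
    d = distance(a1.coords, a2.coords)
    probe = GeometryProbe({"d": d})
    return d <= _gate(radii, a1, a2, params.buffer("vdW")), probe


# ---------------------------------------------------------------------
# water-side satisfiability (drives the M#X#S descriptor arithmetic)

def water_can_participate(rule: InteractionRule) -> bool:
    """Can one side of ``rule`` be a water molecule?

    A water offers exactly: an O.3 oxygen bearing two hydrogens (O-H
    donor and O acceptor) and that single heavy atom for vdW contacts.
    It has no C, N or S, no aromatic ring, and no heavy-heavy bond
    dipole, which rules out every other participant role.
    """
    if rule.kind == "vdw":
        return True
    if rule.kind == "xh_y":
        if rule.donor_element == "O":
            return True
        if rule.acceptor_element == "O":
            # water O is O.3; acceptor typing for X-H...O admits any oxygen
            return True
        return False
    if rule.kind == "xh_pi":
        return rule.donor_element == "O"
    if rule.kind == "chalcogen":
        # acceptor restricted to sp2/charged O (O.2/O.co2); water O is O.3
        return False
    return False
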