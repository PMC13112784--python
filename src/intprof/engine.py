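"""Interaction detection around designated residues.

For every side-chain heavy atom (plus bonded hydrogens) of each target
(class ``M``) residue, every registry rule is evaluated against the
surrounding environment — the rest of the antibody, the antigen, waters,
and the other target residue in double-mutation mode.  When several
rules accept the same atom pair, the interaction priority order decides
the single label kept, so a pair that qualifies as CH...O is never also
counted as a van der Waals contact.

Waters that touch a target residue are then profiled against their own
environment, and every (target-water leg, water-environment leg) pair
through a single water molecule becomes a :class:`WaterBridge`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import GeometryProbe, RingSystem, distance
from .rules import (
    DEFAULT_PRIORITY,
    InteractionRule,
    RuleParameters,
    RuleRegistry,
    VdwRadiusTable,
    build_registry,
    acceptor_ok,
    chalcogen_acceptor_ok,
    chalcogen_sulfur_ok,
    evaluate_chalcogen,
    evaluate_dipo,
    evaluate_metal,
    evaluate_omulpol,
    evaluate_pi_pi,
    evaluate_s_pi,
    evaluate_vdw_contact,
    evaluate_xh_pi,
    evaluate_xh_y,
)
from .structure import (
    Atom,
    Residue,
    ResidueKey,
    TypedMolecularSystem,
    format_residue_key,
)

__all__ = ["InteractionHit", "WaterBridge", "detect_interactions", "bridge_water",
           "write_hits", "write_pml"]


@dataclass
class InteractionHit:
    label: str
    role_atoms: Dict[str, Atom]
    target_residue: ResidueKey
    partner_residue: ResidueKey
    partner_class: str
    measured: GeometryProbe = field(default_factory=GeometryProbe)
    pair_key: frozenset = frozenset()

    def sort_key(self):
        return (
            self.target_residue,
            self.partner_residue,
            self.label,
            tuple(sorted(a.serial for a in self.role_atoms.values())),
        )


@dataclass
class WaterBridge:
    water_residue: ResidueKey
    leg1: InteractionHit  # target (M) <-> water
    leg2: InteractionHit  # water <-> environment (or the other M residue)

    @property
    def partner_residue(self) -> ResidueKey:
        return self.leg2.partner_residue

    @property
    def partner_class(self) -> str:
        return self.leg2.partner_class


# ---------------------------------------------------------------------
# candidate enumeration

def _analyzed_atoms(res: Residue, system: TypedMolecularSystem, include_backbone: bool):
    base = list(res.atoms) if include_backbone else res.sidechain_atoms()
    heavies = [a for a in base if a.is_heavy]
    atoms = list(heavies)
    for h in base:
        if h.is_hydrogen and h not in atoms:
            atoms.append(h)
    # hydrogens of analyzed heavies (side-chain H already in base)
    return heavies, atoms


def _dipoles_of(atoms: Sequence[Atom], system: TypedMolecularSystem, gap: float):
    """Bonded heavy-atom pairs with a charge gap >= ``gap`` (plus, minus)."""
    out = []
    seen = set()
    for a in atoms:
        if not a.is_heavy or a.partial_charge is None:
            continue
        for b in system.heavy_neighbors(a):
            if b.partial_charge is None:
                continue
            key = frozenset((a.serial, b.serial))
            if key in seen:
                continue
            seen.add(key)
            if abs(a.partial_charge - b.partial_charge) < gap:
                continue
            plus, minus = (a, b) if a.partial_charge > b.partial_charge else (b, a)
            out.append((plus, minus))
    return out


def _rings_by_residue(system: TypedMolecularSystem) -> Dict[ResidueKey, List[RingSystem]]:
    by_res: Dict[ResidueKey, List[RingSystem]] = {}
    for ring in system.aromatic_rings():
        keys = {system.atom_by_serial(s).residue_key for s in ring.member_serials}
        if len(keys) == 1:
            by_res.setdefault(keys.pop(), []).append(ring)
    return by_res


def _env_residues(
    system: TypedMolecularSystem,
    heavies: Sequence[Atom],
    exclude: ResidueKey,
    cull_radius: Optional[float],
) -> List[Residue]:
    out = []
    coords = np.array([a.coords for a in heavies]) if heavies else np.zeros((0, 3))
    for res in system.residues.values():
        if res.key == exclude:
            continue
        if cull_radius is None or not len(coords):
            out.append(res)
            continue
        res_heavy = np.array([a.coords for a in res.atoms if a.is_heavy])
        if not len(res_heavy):
            continue
        d2 = ((coords[:, None, :] - res_heavy[None, :, :]) ** 2).sum(-1)
        if d2.min() <= cull_radius ** 2:
            out.append(res)
    return out


def _candidates(
    system: TypedMolecularSystem,
    target: Residue,
    registry: RuleRegistry,
    params: RuleParameters,
    radii: VdwRadiusTable,
    *,
    include_backbone: bool,
    cull_radius: Optional[float],
    rings_by_res: Dict[ResidueKey, List[RingSystem]],
    skip_metal_ion: bool = False,
) -> List[InteractionHit]:
    heavies, analyzed = _analyzed_atoms(target, system, include_backbone)
    env = _env_residues(system, heavies, target.key, cull_radius)
    env_atoms = [a for r in env for a in r.atoms]
    cands: List[InteractionHit] = []

    def emit(rule, roles, partner_res, probe, pair):
        cands.append(InteractionHit(
            label=rule.label,
            role_atoms=roles,
            target_residue=target.key,
            partner_residue=partner_res.key,
            partner_class=system.partner_class(partner_res.key),
            measured=probe,
            pair_key=frozenset(a.serial for a in pair),
        ))

    t_heavy = heavies
    e_heavy = [a for a in env_atoms if a.is_heavy]

    for rule in registry.values():
        if rule.kind == "xh_y":
            for D_pool, A_pool, flipped in ((t_heavy, e_heavy, False), (e_heavy, t_heavy, True)):
                for D in D_pool:
                    if D.element != rule.donor_element:
                        continue
                    hs = system.bonded_hydrogens(D)
                    if not hs:
                        continue
                    for A in A_pool:
                        if not acceptor_ok(rule, system, A):
                            continue
                        best = None
                        for H in hs:
                            ok, probe = evaluate_xh_y(rule, system, D, H, A, params, radii)
                            if ok and (best is None or probe["d_HA"] < best[1]["d_HA"]):
                                best = (H, probe)
                        if best is not None:
                            H, probe = best
                            partner = system.residue(D.residue_key if flipped else A.residue_key)
                            emit(rule, {"D": D, "H": H, "A": A}, partner, probe, (D, A))
        elif rule.kind == "xh_pi":
            for D_pool, ring_pool, flipped in (
                (t_heavy, [(r, rings) for r in env for rings in [rings_by_res.get(r.key, [])]], False),
                (e_heavy, [(target, rings_by_res.get(target.key, []))], True),
            ):
                for res, rings in ring_pool:
                    for ring in rings:
                        for D in D_pool:
                            if D.element != rule.donor_element:
                                continue
                            hs = system.bonded_hydrogens(D)
                            best = None
                            for H in hs:
                                ok, probe, A = evaluate_xh_pi(
                                    rule, system, D, H, ring, params, radii)
                                if ok and (best is None or probe["d_HA"] < best[1]["d_HA"]):
                                    best = (H, probe, A)
                            if best is not None:
                                H, probe, A = best
                                partner = system.residue(
                                    D.residue_key if flipped else A.residue_key)
                                emit(rule, {"D": D, "H": H, "A": A}, partner, probe, (D, A))
        elif rule.kind == "s_pi":
            for S_pool, ring_pool, flipped in (
                (t_heavy, [(r, rings_by_res.get(r.key, [])) for r in env], False),
                (e_heavy, [(target, rings_by_res.get(target.key, []))], True),
            ):
                for res, rings in ring_pool:
                    for ring in rings:
                        for S in S_pool:
                            if S.element != "S":
                                continue
                            ok, probe, A = evaluate_s_pi(rule, system, S, ring, params, radii)
                            if ok:
                                partner = system.residue(
                                    S.residue_key if flipped else A.residue_key)
                                emit(rule, {"S": S, "A": A}, partner, probe, (S, A))
        elif rule.kind == "pi_pi":
            t_rings = rings_by_res.get(target.key, [])
            for res in env:
                for ring2 in rings_by_res.get(res.key, []):
                    for ring1 in t_rings:
                        ok, probe = evaluate_pi_pi(ring1, ring2, params)
                        if ok:
                            a1 = system.atom_by_serial(min(ring1.member_serials))
                            a2 = system.atom_by_serial(min(ring2.member_serials))
                            emit(rule, {"ring1": a1, "ring2": a2}, res, probe, (a1, a2))
        elif rule.kind in ("omulpol", "dipo"):
            gap = params.get(rule.label, "dipole_charge_gap")
            t_dip = _dipoles_of(analyzed, system, gap)
            t_dip = [d for d in t_dip
                     if d[0].residue_key == target.key and d[1].residue_key == target.key]
            e_dip = _dipoles_of(e_heavy, system, gap)
            fn = evaluate_omulpol if rule.kind == "omulpol" else evaluate_dipo
            for dip1_pool, dip2_pool, flipped in ((t_dip, e_dip, False), (e_dip, t_dip, True)):
                for p1, m1 in dip1_pool:
                    for p2, m2 in dip2_pool:
                        if p1.residue_key == p2.residue_key:
                            continue
                        ok, probe = fn(system, p1, m1, p2, m2, params, radii)
                        if ok:
                            partner = system.residue(
                                m1.residue_key if flipped else p2.residue_key)
                            emit(rule, {"Dp1+": p1, "Dp1-": m1, "Dp2+": p2, "Dp2-": m2},
                                 partner, probe, (m1, p2))
        elif rule.kind == "chalcogen":
            for S_pool, A_pool, flipped in ((t_heavy, e_heavy, False), (e_heavy, t_heavy, True)):
                for S in S_pool:
                    if not chalcogen_sulfur_ok(system, S):
                        continue
                    for A in A_pool:
                        ok, probe = evaluate_chalcogen(rule, system, S, A, params, radii)
                        if ok:
                            partner = system.residue(S.residue_key if flipped else A.residue_key)
                            emit(rule, {"S": S, "A": A}, partner, probe, (S, A))
        elif rule.kind in ("metal", "ion"):
            if skip_metal_ion:
                continue
            for metal in e_heavy:
                if metal.element != rule.metal_element:
                    continue
                for A in t_heavy:
                    ok, probe = evaluate_metal(rule, metal, A, params)
                    if ok:
                        partner = system.residue(metal.residue_key)
                        emit(rule, {"metal": metal, "A": A}, partner, probe, (metal, A))
        elif rule.kind == "vdw":
            for a1 in t_heavy:
                for a2 in e_heavy:
                    ok, probe = evaluate_vdw_contact(a1, a2, params, radii)
                    if ok:
                        partner = system.residue(a2.residue_key)
                        emit(rule, {"a1": a1, "a2": a2}, partner, probe, (a1, a2))
    return cands


def _resolve_priority(cands: List[InteractionHit], priority: List[str]) -> List[InteractionHit]:
    rank = {label: i for i, label in enumerate(priority)}
    best: Dict[Tuple, InteractionHit] = {}
    for hit in cands:
        key = (hit.target_residue, hit.pair_key)
        cur = best.get(key)
        if cur is None or rank[hit.label] < rank[cur.label]:
            best[key] = hit
    return sorted(best.values(), key=InteractionHit.sort_key)


# ---------------------------------------------------------------------
# public API

def detect_interactions(
    system: TypedMolecularSystem,
    registry: Optional[RuleRegistry] = None,
    params: Optional[RuleParameters] = None,
    radii: Optional[VdwRadiusTable] = None,
    priority: Optional[List[str]] = None,
    *,
    include_backbone: bool = False,
    cull_radius: Optional[float] = 8.0,
) -> Tuple[List[InteractionHit], List[WaterBridge]]:
    """Detect all labeled interactions around the target residues.

    Returns the sorted hit list (targets are always class-M residues;
    waters appear as ``S`` partners) and the water bridges through single
    water molecules.
    """
    registry = registry or build_registry()
    params = params or RuleParameters()
    radii = radii or VdwRadiusTable.default()
    priority = priority or DEFAULT_PRIORITY
    targets = system.target_residues()
    if not targets:
        raise ValueError("no target (class M) residues assigned; run assign_partner_classes")
    rings_by_res = _rings_by_residue(system)

    hits: List[InteractionHit] = []
    for target in targets:
        cands = _candidates(
            system, target, registry, params, radii,
            include_backbone=include_backbone, cull_radius=cull_radius,
            rings_by_res=rings_by_res,
        )
        # the M-M pair is reported once, from the lower residue key
        cands = [c for c in cands
                 if not (c.partner_class == "M" and c.partner_residue < c.target_residue)]
        hits.extend(_resolve_priority(cands, priority))

    bridges = _find_bridges(
        system, hits, registry, params, radii, priority,
        cull_radius=cull_radius, rings_by_res=rings_by_res,
    )
    hits.sort(key=InteractionHit.sort_key)
    return hits, bridges


def _find_bridges(system, hits, registry, params, radii, priority, *,
                  cull_radius, rings_by_res) -> List[WaterBridge]:
    legs1: Dict[ResidueKey, List[InteractionHit]] = {}
    for h in hits:
        if h.partner_class == "S":
            legs1.setdefault(h.partner_residue, []).append(h)
    bridges: List[WaterBridge] = []
    for wkey in sorted(legs1):
        water = system.residue(wkey)
        cands = _candidates(
            system, water, registry, params, radii,
            include_backbone=True, cull_radius=cull_radius,
            rings_by_res=rings_by_res, skip_metal_ion=True,
        )
        cands = [c for c in cands
                 if c.partner_class in ("Ab", "Ag") and not system.residue(c.partner_residue).is_water]
        legs2 = _resolve_priority(cands, priority)
        for leg1 in legs1[wkey]:
            for leg2 in legs2:
                bridges.append(WaterBridge(water_residue=wkey, leg1=leg1, leg2=leg2))
            # bridge to the other target residue through the same water
            for other in legs1[wkey]:
                if other.target_residue > leg1.target_residue:
                    leg2 = InteractionHit(
                        label=other.label, role_atoms=other.role_atoms,
                        target_residue=wkey, partner_residue=other.target_residue,
                        partner_class="M", measured=other.measured,
                        pair_key=other.pair_key,
                    )
                    bridges.append(WaterBridge(water_residue=wkey, leg1=leg1, leg2=leg2))
    bridges.sort(key=lambda b: (b.leg1.sort_key(), b.leg2.sort_key()))
    return bridges


def bridge_water(system, hits, **kwargs) -> List[WaterBridge]:
    """Enumerate single-water bridges from a resolved hit list."""
    registry = kwargs.pop("registry", None) or build_registry()
    params = kwargs.pop("params", None) or RuleParameters()
    radii = kwargs.pop("radii", None) or VdwRadiusTable.default()
    priority = kwargs.pop("priority", None) or DEFAULT_PRIORITY
    return _find_bridges(
        system, hits, registry, params, radii, priority,
        cull_radius=kwargs.pop("cull_radius", 8.0),
        rings_by_res=_rings_by_residue(system),
    )


# ---------------------------------------------------------------------
# output writers

def write_hits(hits: List[InteractionHit], bridges: List[WaterBridge], path):
    """Tab-separated hit/bridge table; byte-identical across reruns."""
    from .descriptors import descriptor_name

    with open(path, "w") as fh:
        fh.write("descriptor\tlabel\ttarget\tpartner\tpartner_class\tatoms\tmeasured\n")
        for h in sorted(hits, key=InteractionHit.sort_key):
            atoms = ",".join(
                f"{role}={a.pdb_name}({a.serial})" for role, a in sorted(h.role_atoms.items())
            )
            fh.write(
                f"{descriptor_name(h)}\t{h.label}\t{format_residue_key(h.target_residue)}\t"
                f"{format_residue_key(h.partner_residue)}\t{h.partner_class}\t{atoms}\t"
                f"{h.measured.fmt()}\n"
            )
        for b in bridges:
            atoms = ";".join(
                ",".join(f"{r}={a.pdb_name}({a.serial})" for r, a in sorted(leg.role_atoms.items()))
                for leg in (b.leg1, b.leg2)
            )
            fh.write(
                f"{descriptor_name(b)}\t{b.leg1.label}+{b.leg2.label}\t"
                f"{format_residue_key(b.leg1.target_residue)}\t"
                f"{format_residue_key(b.partner_residue)}\t{b.partner_class}\t{atoms}\t"
                f"{b.leg1.measured.fmt()};{b.leg2.measured.fmt()}\n"
            )


_PML_COLORS = {
    "hbond": "blue",
    "electrostatic": "cyan",
    "pi": "orange",
    "CH_O": "pink",
    "OMulPol": "yellow",
}


def _pml_color(label: str, registry: RuleRegistry) -> Optional[str]:
    if label in _PML_COLORS:
        return _PML_COLORS[label]
    category = registry[label].category
    if category == "vdw":
        return None  # van der Waals contacts are not drawn
    return _PML_COLORS.get(category, "gray70")


def write_pml(hits: List[InteractionHit], bridges: List[WaterBridge], path,
              registry: Optional[RuleRegistry] = None, include_vdw: bool = False):
    """PyMOL script: one dashed distance object per hit, colored by type.

    Hydrogen bonds are blue, electrostatic contacts cyan, pi-family
    interactions orange, CH...O pink and orthogonal multipolar contacts
    yellow; van der Waals contacts are omitted unless requested.
    """
    registry = registry or build_registry()
    lines = []
    counter: Dict[str, int] = {}

    def add(label, a, b):
        color = _pml_color(label, registry)
        if color is None and not include_vdw:
            return
        counter[label] = counter.get(label, 0) + 1
        name = f"intprof_{label}_{counter[label]}"
        lines.append(f"distance {name}, (id {a.serial}), (id {b.serial})")
        lines.append(f"color {color or 'gray70'}, {name}")

    for h in sorted(hits, key=InteractionHit.sort_key):
        a, b = _display_atoms(h)
        add(h.label, a, b)
    for br in bridges:
        for leg in (br.leg1, br.leg2):
            a, b = _display_atoms(leg)
            add(leg.label, a, b)
    with open(path, "w") as fh:
        fh.write("# generated by intprof\n")
        for line in lines:
            fh.write(line + "\n")
        if lines:
            fh.write("hide labels, intprof_*\n")


def _display_atoms(hit: InteractionHit) -> Tuple[Atom, Atom]:
    r = hit.role_atoms
    for pair in (("D", "A"), ("S", "A"), ("metal", "A"), ("Dp1-", "Dp2+"),
                 ("ring1", "ring2"), ("a1", "a2")):
        if pair[0] in r and pair[1] in r:
            return r[pair[0]], r[pair[1]]
    atoms = sorted(r.values(), key=lambda a: a.serial)
    return atoms[0], atoms[-1]
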