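import itertools

import numpy as np
import pytest

from intprof import (
    DEFAULT_PRIORITY,
    RuleParameters,
    VdwRadiusTable,
    build_registry,
    detect_interactions,
    write_hits,
    write_pml,
)
from intprof.fixtures import (
    EXPECTED_TOY_BRIDGES,
    EXPECTED_TOY_HITS,
    PROBE_LABELS,
    ProbeSpec,
    SystemBuilder,
    make_probe,
    make_toy_complex,
)
from intprof.descriptors import descriptor_name

import oracle_utils


def hit_multiset(hits):
    return sorted((h.label, tuple(sorted(h.pair_key))) for h in hits)


class TestDetection:
    def test_engineered_ch_o_yields_single_ab_hit(self):
        system = make_probe(ProbeSpec("CH_O"))
        hits, bridges = detect_interactions(system)
        ch_o = [h for h in hits if h.label == "CH_O"]
        assert len(ch_o) == 1
        assert ch_o[0].partner_class == "Ab"
        assert descriptor_name(ch_o[0]) == "M#CH_O#Ab"
        assert bridges == []

    def test_priority_suppresses_vdw_on_labeled_pair(self):
        system = make_probe(ProbeSpec("CH_O"))
        hits, _ = detect_interactions(system)
        ch_o = next(h for h in hits if h.label == "CH_O")
        vdw_pairs = {h.pair_key for h in hits if h.label == "vdW"}
        assert ch_o.pair_key not in vdw_pairs

    def test_two_targets_in_contact_yield_one_mm_hit(self):
        b = SystemBuilder()
        m1 = b.residue("A", 1, "PRB")
        b.atom(m1, "CB", "C.3", (0, 0, 0))
        m2 = b.residue("A", 2, "PRB")
        b.atom(m2, "CB", "C.3", (4.0, 0, 0))
        system = b.finish(targets=("A:1", "A:2"))
        hits, _ = detect_interactions(system)
        assert [(h.label, h.partner_class) for h in hits] == [("vdW", "M")]
        assert hits[0].target_residue == ("A", 1, "")

    def test_no_intra_residue_hits(self, toy_complex):
        hits, _ = detect_interactions(toy_complex)
        assert all(h.target_residue != h.partner_residue for h in hits)

    def test_spatial_culling_is_lossless(self, toy_complex):
        default = detect_interactions(toy_complex, cull_radius=8.0)
        unculled = detect_interactions(toy_complex, cull_radius=None)
        assert hit_multiset(default[0]) == hit_multiset(unculled[0])
        assert len(default[1]) == len(unculled[1])

    def test_at_most_one_label_per_pair(self, toy_complex):
        hits, _ = detect_interactions(toy_complex)
        pairs = [(h.target_residue, tuple(sorted(h.pair_key))) for h in hits]
        assert len(pairs) == len(set(pairs))

    def test_determinism(self, toy_complex):
        h1, b1 = detect_interactions(toy_complex)
        h2, b2 = detect_interactions(toy_complex)
        assert hit_multiset(h1) == hit_multiset(h2)
        assert [hx.sort_key() for hx in h1] == [hx.sort_key() for hx in h2]


class TestEngineEqualsOracle:
    """Every accepted hit re-measured independently from raw coordinates."""

    @pytest.mark.parametrize("label", PROBE_LABELS)
    def test_probe_hits_satisfy_printed_inequalities(self, label, radii):
        system = make_probe(ProbeSpec(label))
        hits, _ = detect_interactions(system)
        assert hits, f"probe for {label} produced no hits at all"
        for hit in hits:
            oracle_utils.recheck_hit(system, hit, radii)

    def test_toy_complex_hits_satisfy_printed_inequalities(self, toy_complex, radii):
        hits, bridges = detect_interactions(toy_complex)
        for hit in hits:
            oracle_utils.recheck_hit(toy_complex, hit, radii)
        for br in bridges:
            oracle_utils.recheck_hit(toy_complex, br.leg1, radii)
            oracle_utils.recheck_hit(toy_complex, br.leg2, radii)

    def test_rigid_motion_invariance_of_decisions(self):
        for label in ("CH_O", "CH_PI", "OMulPol", "HB_OH_O", "S_O", "vdW"):
            base = detect_interactions(make_probe(ProbeSpec(label)))[0]
            moved_system = make_probe(ProbeSpec(label))
            from intprof.fixtures import apply_rigid_motion, rigid_motion

            rot, trans = rigid_motion(seed=42)
            apply_rigid_motion(moved_system, rot, trans)
            moved = detect_interactions(moved_system)[0]
            assert hit_multiset(base) == hit_multiset(moved)


class TestWaterBridges:
    def test_toy_bridge_descriptor_path(self, toy_complex):
        _, bridges = detect_interactions(toy_complex)
        names = [descriptor_name(b) for b in bridges]
        assert "M#HB_NH_O#S#HB_OH_O#Ag" in names

    def test_water_touching_only_target_yields_no_bridge(self, toy_complex):
        hits, bridges = detect_interactions(toy_complex)
        w2 = ("W", 101, "")
        # W2 has target legs ...
        assert any(h.partner_residue == w2 for h in hits)
        # ... but participates in no bridge
        assert all(b.water_residue != w2 for b in bridges)

    def test_bridge_between_two_targets_is_mm(self):
        b = SystemBuilder()
        m1 = b.residue("A", 1, "PRB")
        d = b.atom(m1, "NB", "N.am", (0, 0, 0))
        dn = b.atom(m1, "CG", "C.3", (-0.51, 1.31, 0))
        h = b.atom(m1, "HB1", "H", (1.01, 0, 0))
        b.bond(d, dn)
        b.bond(d, h)
        w = b.residue("W", 50, "HOH")
        ow = b.atom(w, "O", "O.3", (2.91, 0, 0), charge=-0.41)
        hw1 = b.atom(w, "H1", "H", (3.87, 0, 0), charge=0.205)
        hw2 = b.atom(w, "H2", "H", (2.61, -0.9, 0.2), charge=0.205)
        b.bond(ow, hw1)
        b.bond(ow, hw2)
        m2 = b.residue("A", 2, "PRB")
        a = b.atom(m2, "OD1", "O.2", (5.77, 0, 0))
        an = b.atom(m2, "CG", "C.2", np.array([5.77, 0, 0]) + 1.23 * np.array([0.3, 0.954, 0]))
        b.bond(a, an, "2")
        system = b.finish(targets=("A:1", "A:2"), chains={"A": "Ab", "W": "Ab"})
        hits, bridges = detect_interactions(system)
        mm = [br for br in bridges if br.partner_class == "M"]
        assert len(mm) >= 1
        assert descriptor_name(mm[0]).endswith("#M")


class TestWriters:
    def test_empty_hits_write_header_only(self, tmp_path):
        path = tmp_path / "hits.tsv"
        write_hits([], [], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("descriptor\t")

    def test_hits_tsv_contents_and_byte_determinism(self, tmp_path, toy_complex):
        hits, bridges = detect_interactions(toy_complex)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_hits(hits, bridges, p1)
        hits2, bridges2 = detect_interactions(toy_complex)
        write_hits(hits2, bridges2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        body = p1.read_text()
        assert "M#CH_O#Ag\t" in body
        assert "M#HB_NH_O#S#HB_OH_O#Ag\t" in body

    def test_pml_palette(self, tmp_path):
        for label, color in (("HB_OH_O", "blue"), ("Ele_NH_O", "cyan"),
                             ("CH_PI", "orange"), ("CH_O", "pink"),
                             ("OMulPol", "yellow")):
            system = make_probe(ProbeSpec(label))
            hits, bridges = detect_interactions(system)
            hits = [h for h in hits if h.label == label]
            path = tmp_path / f"{label}.pml"
            write_pml(hits, bridges, path)
            text = path.read_text()
            assert "distance intprof_" in text
            assert f"color {color}," in text

    def test_vdw_only_hits_produce_no_dash_objects(self, tmp_path):
        system = make_probe(ProbeSpec("vdW"))
        hits, bridges = detect_interactions(system)
        assert {h.label for h in hits} == {"vdW"}
        path = tmp_path / "vdw.pml"
        write_pml(hits, bridges, path)
        assert "distance" not in path.read_text()


class TestBruteForceOracle:
    """Exhaustive all-pairs, all-rules re-evaluation with priority resolution,
    written independently of the engine's candidate enumeration."""

    def brute_force(self, system, params=None, radii=None):
        from intprof.rules import (
            acceptor_ok,
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

        registry = build_registry()
        params = params or RuleParameters()
        radii = radii or VdwRadiusTable.default()
        rank = {l: i for i, l in enumerate(DEFAULT_PRIORITY)}
        targets = [r for r in system.residues.values()
                   if system.partner_class(r.key) == "M"]
        rings = list(enumerate(system.aromatic_rings()))
        ring_res = {i: system.atom_by_serial(min(r.member_serials)).residue_key
                    for i, r in rings}
        found = {}

        def consider(target_key, label, pair, partner_key):
            key = (target_key, frozenset(a.serial for a in pair))
            cur = found.get(key)
            if cur is None or rank[label] < rank[cur[0]]:
                found[key] = (label, partner_key)

        for target in targets:
            sc = set(a.serial for a in target.sidechain_atoms())
            others = [a for a in system.atoms if a.residue_key != target.key]
            for rule in registry.values():
                if rule.kind == "xh_y":
                    for D in system.atoms:
                        if D.element != rule.donor_element:
                            continue
                        for H in system.bonded_hydrogens(D):
                            for A in system.atoms:
                                if not acceptor_ok(rule, system, A):
                                    continue
                                if D.residue_key == A.residue_key:
                                    continue
                                involved = {D.serial, A.serial} | {H.serial}
                                if not (involved & sc):
                                    continue
                                if target.key not in (D.residue_key, A.residue_key):
                                    continue
                                ok, _ = evaluate_xh_y(rule, system, D, H, A, params, radii)
                                if ok:
                                    partner = (A.residue_key if D.residue_key == target.key
                                               else D.residue_key)
                                    consider(target.key, rule.label, (D, A), partner)
                elif rule.kind == "xh_pi":
                    for D in system.atoms:
                        if D.element != rule.donor_element:
                            continue
                        for H in system.bonded_hydrogens(D):
                            for ri, ring in rings:
                                rk = ring_res[ri]
                                if rk == D.residue_key:
                                    continue
                                if target.key not in (rk, D.residue_key):
                                    continue
                                if D.residue_key == target.key and D.serial not in sc:
                                    continue
                                ok, _, A = evaluate_xh_pi(rule, system, D, H, ring,
                                                          params, radii)
                                if ok:
                                    partner = rk if D.residue_key == target.key else D.residue_key
                                    consider(target.key, rule.label, (D, A), partner)
                elif rule.kind == "s_pi":
                    for S in system.atoms:
                        if S.element != "S":
                            continue
                        for ri, ring in rings:
                            rk = ring_res[ri]
                            if rk == S.residue_key:
                                continue
                            if target.key not in (rk, S.residue_key):
                                continue
                            if S.residue_key == target.key and S.serial not in sc:
                                continue
                            ok, _, A = evaluate_s_pi(rule, system, S, ring, params, radii)
                            if ok:
                                partner = rk if S.residue_key == target.key else S.residue_key
                                consider(target.key, rule.label, (S, A), partner)
                elif rule.kind == "pi_pi":
                    for (i1, r1), (i2, r2) in itertools.permutations(rings, 2):
                        if ring_res[i1] != target.key or ring_res[i2] == target.key:
                            continue
                        ok, _ = evaluate_pi_pi(r1, r2, params)
                        if ok:
                            a1 = system.atom_by_serial(min(r1.member_serials))
                            a2 = system.atom_by_serial(min(r2.member_serials))
                            consider(target.key, "PI_PI", (a1, a2), ring_res[i2])
                elif rule.kind in ("omulpol", "dipo"):
                    gap = params.get(rule.label, "dipole_charge_gap")
                    dipoles = []
                    for pair, _t in system.bonds.items():
                        x, y = (system.atom_by_serial(s) for s in pair)
                        if not (x.is_heavy and y.is_heavy):
                            continue
                        if abs(x.partial_charge - y.partial_charge) < gap:
                            continue
                        plus, minus = (x, y) if x.partial_charge > y.partial_charge else (y, x)
                        dipoles.append((plus, minus))
                    fn = evaluate_omulpol if rule.kind == "omulpol" else evaluate_dipo
                    for (p1, m1), (p2, m2) in itertools.permutations(dipoles, 2):
                        if p1.residue_key == p2.residue_key:
                            continue
                        if target.key not in (p1.residue_key, p2.residue_key):
                            continue
                        if p1.residue_key == target.key and not (
                                {p1.serial, m1.serial} & sc):
                            continue
                        if p2.residue_key == target.key and not (
                                {p2.serial, m2.serial} & sc):
                            continue
                        ok, _ = fn(system, p1, m1, p2, m2, params, radii)
                        if ok:
                            partner = (p2.residue_key if p1.residue_key == target.key
                                       else p1.residue_key)
                            consider(target.key, rule.label, (m1, p2), partner)
                elif rule.kind == "chalcogen":
                    for S in system.atoms:
                        for A in system.atoms:
                            if S.residue_key == A.residue_key:
                                continue
                            if target.key not in (S.residue_key, A.residue_key):
                                continue
                            local = S if S.residue_key == target.key else A
                            if local.serial not in sc:
                                continue
                            ok, _ = evaluate_chalcogen(rule, system, S, A, params, radii)
                            if ok:
                                partner = (A.residue_key if S.residue_key == target.key
                                           else S.residue_key)
                                consider(target.key, rule.label, (S, A), partner)
                elif rule.kind in ("metal", "ion"):
                    for metal in others:
                        for A in target.sidechain_atoms():
                            if not A.is_heavy:
                                continue
                            ok, _ = evaluate_metal(rule, metal, A, params)
                            if ok:
                                consider(target.key, rule.label, (metal, A),
                                         metal.residue_key)
                elif rule.kind == "vdw":
                    for a1 in target.sidechain_atoms():
                        if not a1.is_heavy:
                            continue
                        for a2 in others:
                            if not a2.is_heavy:
                                continue
                            ok, _ = evaluate_vdw_contact(a1, a2, params, radii)
                            if ok:
                                consider(target.key, "vdW", (a1, a2), a2.residue_key)

        # M-M dedup: keep the hit on the lower target key
        out = []
        for (tk, pair), (label, pk) in found.items():
            if system.partner_class(pk) == "M" and pk < tk:
                continue
            out.append((label, tuple(sorted(pair))))
        return sorted(out)

    @pytest.mark.parametrize("label", PROBE_LABELS)
    def test_probe_systems(self, label):
        system = make_probe(ProbeSpec(label))
        hits, _ = detect_interactions(system, cull_radius=None)
        assert hit_multiset(hits) == self.brute_force(system)

    def test_toy_complex(self, toy_complex):
        hits, _ = detect_interactions(toy_complex)
        assert hit_multiset(hits) == self.brute_force(toy_complex)
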