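import numpy as np
import pytest

from intprof import RuleParameters, build_registry, detect_interactions
from intprof.fixtures import PROBE_LABELS, ProbeSpec, SystemBuilder, make_probe
from intprof.geometry import ring_center_normal
from intprof.rules import (
    DEFAULT_PRIORITY,
    classify_polar_contact,
    evaluate_ch_o,
    evaluate_ch_pi,
    evaluate_metal,
    evaluate_omulpol,
    evaluate_pi_pi,
    evaluate_vdw_contact,
    evaluate_xh_y,
    load_criteria,
    load_priority,
    load_radii,
)

EXPECTED_LABELS = [
    "HB_OH_O", "HB_NH_O", "HB_OH_N", "HB_NH_N",
    "Ele_OH_O", "Ele_NH_O", "Ele_OH_N", "Ele_NH_N",
    "PI_PI", "CH_PI", "NH_PI", "S_PI",
    "CH_O", "CH_N", "CH_S", "OH_S", "NH_S", "SH_O", "SH_N", "SH_S",
    "OH_PI", "SH_PI", "S_O", "S_N", "S_S", "OMulPol", "Dipo", "vdW",
    "Fe_A", "Zn_A", "Ca_A", "Mg_A", "Ni_A", "Na_A", "K_A", "Cl_A",
]


class TestRegistry:
    def test_cardinality_and_label_set(self, registry):
        assert len(registry) == 36
        assert sorted(registry) == sorted(EXPECTED_LABELS)
        assert len(registry.direct_labels) == 28
        assert len(registry.metal_labels) == 5
        assert len(registry.ion_labels) == 3

    def test_priority_covers_registry(self, registry):
        assert sorted(DEFAULT_PRIORITY) == sorted(registry)

    def test_priority_file_round_trip(self, tmp_path, registry):
        path = tmp_path / "priority.txt"
        path.write_text("\n".join(DEFAULT_PRIORITY) + "\n")
        assert load_priority(path) == DEFAULT_PRIORITY
        path.write_text("\n".join(DEFAULT_PRIORITY[:-1]) + "\n")
        with pytest.raises(ValueError, match="missing"):
            load_priority(path)


def _ch_o_system(a_pos, an_pos=(4.0, 1.2, 0.0)):
    b = SystemBuilder()
    m = b.residue("A", 1, "PRB")
    d = b.atom(m, "CB", "C.3", (0, 0, 0))
    dn = b.atom(m, "CG", "C.3", (-0.51, 1.31, 0))
    h = b.atom(m, "HB1", "H", (1.09, 0, 0))
    b.bond(d, dn)
    b.bond(d, h)
    p = b.residue("B", 1, "PRB")
    a = b.atom(p, "O1", "O.2", a_pos)
    an = b.atom(p, "C1", "C.2", an_pos)
    b.bond(a, an, "2")
    return b.finish(), d, h, a


class TestChOExample:
    """The printed CH...O worked geometry and its rejected variants."""

    def test_reference_geometry_accepts(self, params, radii):
        system, d, h, a = _ch_o_system((3.40, 0.0, 0.0))
        ok, probe = evaluate_ch_o(d, h, a, system, params, radii)
        assert ok
        # RvdW(C)=1.70, RvdW(O)=1.52 -> gate 4.22 A
        assert probe["d_DA"] == pytest.approx(3.40)
        assert probe["d_HA"] == pytest.approx(2.31)
        assert probe["ang_DHA"] == pytest.approx(180.0)

    def test_90_degree_angle_rejects(self, params, radii):
        # A placed so the D:H:A angle is 90 deg (directly below H,
        # away from the donor neighbor so only the angle fails)
        system, d, h, a = _ch_o_system((1.09, -2.4, 0.0), an_pos=(1.6, -3.5, 0.0))
        ok, probe = evaluate_ch_o(d, h, a, system, params, radii)
        assert not ok
        assert probe["ang_DHA"] == pytest.approx(90.0, abs=1e-6)

    def test_ha_beyond_322_rejects(self, params, radii):
        system, d, h, a = _ch_o_system((1.09 + 3.30, 0.0, 0.0), an_pos=(5.0, 1.2, 0.0))
        ok, probe = evaluate_ch_o(d, h, a, system, params, radii)
        assert not ok
        assert probe["d_HA"] == pytest.approx(3.30)

    def test_acceptor_neighbor_condition(self, params, radii):
        # An closer to D than A is -> d(D:A) <= d(D:An) violated
        system, d, h, a = _ch_o_system((3.40, 0.0, 0.0), an_pos=(2.2, 0.5, 0.0))
        ok, _ = evaluate_ch_o(d, h, a, system, params, radii)
        assert not ok


def _ring_system(builder):
    p = builder.residue("B", 1, "PRB")
    atoms = builder.ring(p, (0.0, 0.0, 0.0), z=0.0)
    return atoms


class TestChPiExample:
    def _donor(self, b, d_xyz, h_xyz):
        m = b.residue("A", 1, "PRB")
        d = b.atom(m, "CB", "C.3", d_xyz)
        dn = b.atom(m, "CG", "C.3", (d_xyz[0] + 0.8, d_xyz[1] + 0.8, d_xyz[2] + 0.9))
        h = b.atom(m, "HB1", "H", h_xyz)
        b.bond(d, dn)
        b.bond(d, h)
        return d, h

    def test_axial_donor_accepts_with_nr_at_centroid(self, params, radii):
        b = SystemBuilder()
        d, h = self._donor(b, (0, 0, 3.80), (0, 0, 2.71))
        _ring_system(b)
        system = b.finish()
        ring = system.aromatic_rings()[0]
        ok, probe, a = evaluate_ch_pi(d, h, ring, system, params, radii)
        assert ok
        assert probe["d_HA"] == pytest.approx(np.hypot(1.39, 2.71), abs=1e-6)
        assert probe["d_Nr_cn"] == pytest.approx(0.0, abs=1e-9)

    def test_lateral_offset_beyond_circle_rejects(self, params, radii):
        b = SystemBuilder()
        d, h = self._donor(b, (2.5, 0, 3.40), (2.5, 0, 2.31))
        _ring_system(b)
        system = b.finish()
        ring = system.aromatic_rings()[0]
        # Nr is 2.5 A from cn > 1.4 * 1.39 = 1.946 A
        ok, _, _ = evaluate_ch_pi(d, h, ring, system, params, radii)
        assert not ok

    def test_outer_shell_or_branch(self, params, radii):
        # d(A:H) = 3.25 in (3.195, 3.325]; angle(D:H:A) ~ 154 >= 124.455
        h_z = float(np.sqrt(3.25**2 - 1.39**2))
        b = SystemBuilder()
        d, h = self._donor(b, (0, 0, h_z + 1.09), (0, 0, h_z))
        _ring_system(b)
        system = b.finish()
        ring = system.aromatic_rings()[0]
        ok, probe, _ = evaluate_ch_pi(d, h, ring, system, params, radii)
        assert ok
        assert 3.195 < probe["d_HA"] <= 3.325
        assert probe["ang_DHA"] >= 124.455


class TestOMulPolExample:
    def _dipoles(self, b, *, q_c1=0.25, q_o1=-0.27, o2_pos=(1.23, 0.0, 3.0)):
        m = b.residue("A", 1, "PRB")
        c1 = b.atom(m, "CG", "C.2", (0, 0, -1.23), charge=q_c1)
        o1 = b.atom(m, "OD1", "O.2", (0, 0, 0), charge=q_o1)
        b.bond(c1, o1, "2")
        p = b.residue("B", 1, "PRB")
        c2 = b.atom(p, "C", "C.2", (0, 0, 3.0), charge=0.25)
        o2 = b.atom(p, "O", "O.2", o2_pos, charge=-0.27)
        ca = b.atom(p, "CA", "C.3", (-1.23, 0.71, 3.0), charge=0.08)
        b.bond(c2, o2, "2")
        b.bond(ca, c2)
        return c1, o1, c2, o2

    def test_perpendicular_carbonyls_accept(self, params, radii):
        b = SystemBuilder()
        c1, o1, c2, o2 = self._dipoles(b)
        system = b.finish()
        ok, probe = evaluate_omulpol(system, c1, o1, c2, o2, params, radii)
        assert ok
        assert probe["ang_Dp2m_Dp2p_Dp1m"] == pytest.approx(90.0, abs=1e-6)
        assert probe["ang_Nr_Dp1m_Dp1p"] == pytest.approx(180.0, abs=1e-6)

    def test_charge_gap_below_02_rejects(self, params, radii):
        b = SystemBuilder()
        c1, o1, c2, o2 = self._dipoles(b, q_c1=0.10, q_o1=-0.05)
        system = b.finish()
        ok, _ = evaluate_omulpol(system, c1, o1, c2, o2, params, radii)
        assert not ok

    def test_non_perpendicular_approach_rejects(self, params, radii):
        # O2 tilted so angle(Dp2-:Dp2+:Dp1-) = 60 deg
        o2_pos = (1.23 * np.sin(np.radians(60)), 0.0, 3.0 - 1.23 * np.cos(np.radians(60)))
        b = SystemBuilder()
        c1, o1, c2, o2 = self._dipoles(b, o2_pos=o2_pos)
        system = b.finish()
        ok, probe = evaluate_omulpol(system, c1, o1, c2, o2, params, radii)
        assert not ok
        assert probe["ang_Dp2m_Dp2p_Dp1m"] == pytest.approx(60.0, abs=1e-6)


class TestPolarContactClassification:
    def _polar(self, d_da):
        b = SystemBuilder()
        m = b.residue("A", 1, "PRB")
        d = b.atom(m, "NB", "N.am", (0, 0, 0))
        dn = b.atom(m, "CG", "C.3", (-0.51, 1.31, 0))
        h = b.atom(m, "HB1", "H", (1.01, 0, 0))
        b.bond(d, dn)
        b.bond(d, h)
        p = b.residue("B", 1, "PRB")
        a = b.atom(p, "O1", "O.2", (d_da, 0, 0))
        an = b.atom(p, "C1", "C.2", np.array([d_da, 0, 0]) + 1.23 * np.array([0.3, 0.954, 0]))
        b.bond(a, an, "2")
        return b.finish(), d, h, a

    def test_39_angstrom_is_electrostatic(self, params, radii):
        system, d, h, a = self._polar(3.9)
        assert classify_polar_contact(system, d, h, a, params, radii) == "Ele_NH_O"

    def test_285_angstrom_is_hydrogen_bond(self, params, radii):
        system, d, h, a = self._polar(2.85)
        assert classify_polar_contact(system, d, h, a, params, radii) == "HB_NH_O"

    def test_beyond_gate_is_nothing(self, params, radii):
        # gate = 1.55 + 1.52 + 1.0 = 4.07 A < 4.5 A
        system, d, h, a = self._polar(4.5)
        assert classify_polar_contact(system, d, h, a, params, radii) is None

    def test_boundary_32_goes_to_hydrogen_bond(self, params, radii):
        system, d, h, a = self._polar(3.2)
        assert classify_polar_contact(system, d, h, a, params, radii) == "HB_NH_O"

    def test_hb_and_ele_are_mutually_exclusive(self, params, radii, registry):
        for d_da in np.linspace(2.6, 4.0, 15):
            system, d, h, a = self._polar(float(d_da))
            accepted = [
                label for label in ("HB_NH_O", "Ele_NH_O")
                if evaluate_xh_y(registry[label], system, d, h, a, params, radii)[0]
            ]
            assert len(accepted) <= 1

    def test_carbon_donor_raises(self, params, radii):
        system, d, h, a = self._polar(2.9)
        d.element = "C"
        d.sybyl_type = "C.3"
        with pytest.raises(ValueError, match="donor"):
            classify_polar_contact(system, d, h, a, params, radii)


class TestVdw:
    def _pair(self, dist):
        b = SystemBuilder()
        m = b.residue("A", 1, "PRB")
        a1 = b.atom(m, "CB", "C.3", (0, 0, 0))
        p = b.residue("B", 1, "PRB")
        a2 = b.atom(p, "C1", "C.3", (dist, 0, 0))
        b.finish()
        return a1, a2

    def test_40_accepts_45_rejects(self, params, radii):
        a1, a2 = self._pair(4.0)
        assert evaluate_vdw_contact(a1, a2, params, radii)[0]
        a1, a2 = self._pair(4.5)
        assert not evaluate_vdw_contact(a1, a2, params, radii)[0]

    def test_already_assigned_pair_is_not_vdw(self, params, radii):
        a1, a2 = self._pair(4.0)
        taken = {frozenset((a1.serial, a2.serial))}
        assert not evaluate_vdw_contact(a1, a2, params, radii, already_assigned=taken)[0]


class TestGenericTemplates:
    def test_sh_o_template(self, params, radii, registry):
        b = SystemBuilder()
        m = b.residue("A", 1, "PRB")
        s = b.atom(m, "SB", "S.3", (0, 0, 0))
        cg = b.atom(m, "CG", "C.3", (-0.65, 1.68, 0))
        h = b.atom(m, "HB1", "H", (1.34, 0, 0))
        b.bond(s, cg)
        b.bond(s, h)
        p = b.residue("B", 1, "PRB")
        # d(H:O)=2.6, angle 150 deg
        th = np.radians(30.0)
        a_pos = np.array([1.34, 0, 0]) + 2.6 * np.array([np.cos(th), np.sin(th), 0])
        a = b.atom(p, "O1", "O.2", a_pos)
        an = b.atom(p, "C1", "C.2", a_pos + 1.23 * np.array([0.3, 0.954, 0]))
        b.bond(a, an, "2")
        system = b.finish()
        ok, probe = evaluate_xh_y(registry["SH_O"], system, s, h, a, params, radii)
        assert ok
        assert probe["ang_DHA"] == pytest.approx(150.0, abs=1e-6)

    def test_pi_pi_parallel_displaced(self, params):
        b = SystemBuilder()
        p1 = b.residue("A", 1, "PRB")
        b.ring(p1, (0, 0, 0), z=0.0)
        p2 = b.residue("B", 1, "PRB")
        b.ring(p2, (1.0, 0, 3.67), z=3.67)
        system = b.finish()
        r1, r2 = system.aromatic_rings()
        ok, probe = evaluate_pi_pi(r1, r2, params)
        assert ok
        assert probe["d_cn_cn"] == pytest.approx(np.hypot(1.0, 3.67), abs=1e-6)
        assert probe["ang_planes"] == pytest.approx(0.0, abs=1e-6)

    def test_sodium_coordination(self, params, registry):
        b = SystemBuilder()
        m = b.residue("A", 1, "PRB")
        o = b.atom(m, "OD1", "O.co2", (0, 0, 0))
        ion = b.residue("C", 300, "NA")
        na = b.atom(ion, "NA", "Na", (2.4, 0, 0), charge=1.0)
        b.finish()
        ok, probe = evaluate_metal(registry["Na_A"], na, o, params)
        assert ok
        assert probe["d_MA"] == pytest.approx(2.4)


class TestParameterFiles:
    def test_criteria_overrides(self, tmp_path):
        path = tmp_path / "criteria.yaml"
        path.write_text("vdw_buffer: 0.8\noverrides:\n  CH_O: {vdw_buffer: 1.2}\n")
        params = load_criteria(path)
        assert params.vdw_buffer == 0.8
        assert params.buffer("CH_O") == 1.2
        assert params.buffer("CH_PI") == 0.8
        assert params.buffer("OMulPol") == 0.7

    def test_unknown_criteria_key_raises(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("not_a_parameter: 1\n")
        with pytest.raises(ValueError, match="not_a_parameter"):
            load_criteria(path)

    def test_radius_file_overrides_default(self, tmp_path):
        path = tmp_path / "radii.txt"
        path.write_text("# custom\nC 1.80\n")
        table = load_radii(path)
        assert table["C"] == 1.80
        assert table["O"] == 1.52  # untouched defaults remain


DISTANCE_GATED = ["CH_O", "CH_S", "SH_O", "S_O", "vdW", "CH_PI"]


@pytest.mark.parametrize("label", DISTANCE_GATED)
def test_buffer_monotonicity(label):
    """Growing the vdW buffer never removes a distance-gated hit."""
    counts = []
    for buffer in (0.5, 1.0, 1.5):
        params = RuleParameters(vdw_buffer=buffer)
        system = make_probe(ProbeSpec(label))
        hits, _ = detect_interactions(system, params=params)
        counts.append(sum(1 for h in hits if h.label == label))
    assert counts == sorted(counts)
    assert counts[1] == 1  # the probe satisfies the rule at the default buffer
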