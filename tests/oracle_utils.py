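"""Independent re-measurement oracle used by engine and acceptance tests.

Every accepted hit is re-checked from raw coordinates with plain numpy,
re-deriving each rule's printed inequalities without going through the
package's evaluator code paths.
"""

import numpy as np

HB_ELE_CUTOFF = 3.2
XH_Y_HA_MAX = 3.22
XH_Y_ANGLE_MIN = 94.58
XH_PI_INNER = 3.195
XH_PI_OUTER = 3.325
XH_PI_ANGLE_MIN = 124.455
RING_FACTOR = 1.4
CHARGE_GAP = 0.2


def d(a, b):
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def ang(a, b, c):
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1, 1))))


def plane_of(points):
    pts = np.asarray(points, float)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    return c, vt[2] / np.linalg.norm(vt[2])


def foot(p, plane_point, normal):
    p = np.asarray(p, float)
    return p - np.dot(p - plane_point, normal) * normal


def gate(radii, a1, a2, buffer):
    return radii.radius(a1) + radii.radius(a2) + buffer


def ring_of(system, atom):
    for ring in system.aromatic_rings():
        if atom.serial in ring.member_serials:
            return ring
    raise AssertionError(f"atom {atom.serial} is not in any aromatic ring")


def recheck_hit(system, hit, radii, buffer=1.0, omulpol_buffer=0.7):
    """Assert every printed inequality of the hit's rule from coordinates."""
    r = hit.role_atoms
    label = hit.label
    if label.startswith(("HB_", "Ele_")) or label in (
        "CH_O", "CH_N", "CH_S", "OH_S", "NH_S", "SH_O", "SH_N", "SH_S"
    ):
        D, H, A = r["D"], r["H"], r["A"]
        dda = d(D.coords, A.coords)
        dha = d(H.coords, A.coords)
        assert dda <= gate(radii, D, A, buffer)
        for dn in system.heavy_neighbors(D):
            assert dda <= d(dn.coords, A.coords)
        for an in system.heavy_neighbors(A):
            assert dda <= d(D.coords, an.coords)
        assert dha <= dda
        assert dha <= XH_Y_HA_MAX
        assert XH_Y_ANGLE_MIN <= ang(D.coords, H.coords, A.coords) <= 180.0
        if label.startswith("HB_"):
            assert dda <= HB_ELE_CUTOFF
        if label.startswith("Ele_"):
            assert dda > HB_ELE_CUTOFF
    elif label in ("CH_PI", "NH_PI", "OH_PI", "SH_PI"):
        D, H, A = r["D"], r["H"], r["A"]
        ring = ring_of(system, A)
        cn = np.mean(ring.coords, axis=0)
        _, normal = plane_of(ring.coords)
        nr = foot(H.coords, cn, normal)
        dda = d(D.coords, A.coords)
        dha = d(H.coords, A.coords)
        assert dda <= gate(radii, D, A, buffer)
        for dn in system.heavy_neighbors(D):
            assert dda <= d(dn.coords, A.coords)
        assert dha <= dda
        assert d(nr, cn) <= RING_FACTOR * d(cn, A.coords)
        a_ = ang(D.coords, H.coords, A.coords)
        assert dha <= XH_PI_INNER or (
            XH_PI_INNER < dha <= XH_PI_OUTER and a_ >= XH_PI_ANGLE_MIN
        )
    elif label == "S_PI":
        S, A = r["S"], r["A"]
        ring = ring_of(system, A)
        cn = np.mean(ring.coords, axis=0)
        _, normal = plane_of(ring.coords)
        nr = foot(S.coords, cn, normal)
        assert d(S.coords, A.coords) <= gate(radii, S, A, buffer)
        assert d(nr, cn) <= RING_FACTOR * d(cn, A.coords)
    elif label == "PI_PI":
        ring1 = ring_of(system, r["ring1"])
        ring2 = ring_of(system, r["ring2"])
        c1, n1 = np.mean(ring1.coords, axis=0), plane_of(ring1.coords)[1]
        c2, n2 = np.mean(ring2.coords, axis=0), plane_of(ring2.coords)[1]
        assert d(c1, c2) <= 5.5
        angle = np.degrees(np.arccos(np.clip(abs(np.dot(n1, n2)), -1, 1)))
        assert angle <= 30.0
        rad1 = np.mean([d(c1, p) for p in ring1.coords])
        rad2 = np.mean([d(c2, p) for p in ring2.coords])
        assert (d(foot(c2, c1, n1), c1) <= RING_FACTOR * rad1
                or d(foot(c1, c2, n2), c2) <= RING_FACTOR * rad2)
    elif label == "OMulPol":
        p1, m1, p2, m2 = r["Dp1+"], r["Dp1-"], r["Dp2+"], r["Dp2-"]
        assert abs(p1.partial_charge - m1.partial_charge) >= CHARGE_GAP
        assert abs(p2.partial_charge - m2.partial_charge) >= CHARGE_GAP
        dv = d(m1.coords, p2.coords)
        assert dv <= gate(radii, m1, p2, omulpol_buffer)
        assert dv <= d(p1.coords, p2.coords)
        assert 75.0 <= ang(m2.coords, p2.coords, m1.coords) <= 105.0
        pts = [p2.coords] + [n.coords for n in system.neighbors(p2)]
        c, normal = plane_of(pts)
        nr = foot(m1.coords, c, normal)
        if d(nr, p2.coords) > 1e-9:
            assert 0.0 <= ang(nr, m1.coords, p2.coords) <= 35.0
        assert 150.0 <= ang(nr, m1.coords, p1.coords) <= 180.0
    elif label == "Dipo":
        p1, m1, p2, m2 = r["Dp1+"], r["Dp1-"], r["Dp2+"], r["Dp2-"]
        assert abs(p1.partial_charge - m1.partial_charge) >= CHARGE_GAP
        assert abs(p2.partial_charge - m2.partial_charge) >= CHARGE_GAP
        assert d(m1.coords, p2.coords) <= gate(radii, m1, p2, buffer)
        v1 = m1.coords - p1.coords
        v2 = m2.coords - p2.coords
        align = np.degrees(np.arccos(np.clip(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
        assert 135.0 <= align <= 180.0
    elif label in ("S_O", "S_N", "S_S"):
        S, A = r["S"], r["A"]
        assert len(system.heavy_neighbors(S)) == 2
        assert d(S.coords, A.coords) <= gate(radii, S, A, buffer)
    elif label.endswith("_A"):
        metal, A = r["metal"], r["A"]
        cutoff = 3.4 if label in ("Na_A", "K_A", "Cl_A") else 3.0
        assert d(metal.coords, A.coords) <= cutoff
        assert A.element in ("N", "O", "S")
    elif label == "vdW":
        a1, a2 = r["a1"], r["a2"]
        assert d(a1.coords, a2.coords) <= gate(radii, a1, a2, buffer)
    else:
        raise AssertionError(f"unknown label {label}")
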