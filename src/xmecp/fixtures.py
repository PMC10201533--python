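"""Deterministic test molecules built from standard internal coordinates.

Every geometry here is generated from fixed, literature-standard bond lengths
and angles so that all inputs used in tests and examples are reproducible
bit-for-bit without any external files.
"""

from __future__ import annotations

import numpy as np

from .structures import Geometry

__all__ = ["build_fixture", "zmatrix_to_cartesian", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("h2", "ethylene", "azobenzene", "quadratic-test-points")


def zmatrix_to_cartesian(entries) -> np.ndarray:
    """Convert a Z-matrix to Cartesian coordinates (same length unit as input).

    ``entries`` is a list of tuples; entry *i* refers only to atoms < *i*:

    - ``()`` for the first atom (placed at the origin),
    - ``(j, r)`` bond to atom *j*,
    - ``(j, r, k, theta)`` bond + angle i-j-k in degrees,
    - ``(j, r, k, theta, l, phi)`` bond + angle + dihedral i-j-k-l in degrees.

    Placement uses the standard natural-extension (NeRF) construction.
    """
    coords = np.zeros((len(entries), 3))
    for i, entry in enumerate(entries):
        if i == 0:
            if entry:
                raise ValueError("first Z-matrix entry takes no references")
            continue
        if i == 1:
            (j, r) = entry
            coords[1] = coords[j] + np.array([r, 0.0, 0.0])
            continue
        if i == 2 and len(entry) == 4:
            j, r, k, theta = entry
            th = np.radians(theta)
            axis = coords[k] - coords[j]
            axis /= np.linalg.norm(axis)
            # any perpendicular direction is fine for the third atom
            perp = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(axis, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            coords[2] = coords[j] + r * (np.cos(th) * axis + np.sin(th) * perp)
            continue
        j, r, k, theta, l, phi = entry
        th, ph = np.radians(theta), np.radians(phi)
        b_kj = coords[j] - coords[k]
        b_lk = coords[k] - coords[l]
        e1 = b_kj / np.linalg.norm(b_kj)
        n = np.cross(b_lk, b_kj)
        nn = np.linalg.norm(n)
        if nn < 1e-10:
            raise ValueError(f"Z-matrix entry {i}: reference atoms are collinear")
        e3 = n / nn
        e2 = np.cross(e3, e1)
        d = r * (
            -np.cos(th) * e1
            + np.sin(th) * (np.cos(ph) * e2 + np.sin(ph) * e3)
        )
        coords[i] = coords[j] + d
    return coords


def _h2(params: dict) -> Geometry:
    r = params.get("r", 0.74)
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
    return Geometry.from_angstrom(["H", "H"], coords, comment=f"H2 r={r} A")


def _ethylene(params: dict) -> Geometry:
    """Ethylene with an adjustable H-C-C-H twist (0 = planar)."""
    r_cc = params.get("cc", 1.33)
    r_ch = params.get("ch", 1.09)
    a_hcc = params.get("hcc", 121.5)
    twist = params.get("hcch", 0.0)
    entries = [
        (),                                   # C0
        (0, r_cc),                            # C1
        (0, r_ch, 1, a_hcc),                  # H2 on C0
        (0, r_ch, 1, a_hcc, 2, 180.0),        # H3 on C0
        (1, r_ch, 0, a_hcc, 2, twist),        # H4 on C1
        (1, r_ch, 0, a_hcc, 4, 180.0),        # H5 on C1
    ]
    coords = zmatrix_to_cartesian(entries)
    return Geometry.from_angstrom(
        ["C", "C", "H", "H", "H", "H"], coords, comment=f"ethylene HCCH={twist} deg"
    )


def _azobenzene(params: dict) -> Geometry:
    """Azobenzene (C12H10N2) with an adjustable C-N=N-C dihedral.

    Standard internal coordinates: N=N 1.25 A, C-N 1.43 A, aromatic C-C
    1.39 A, C-H 1.09 A, C-N=N angle 115 deg, ideal 120 deg ring angles.
    Atom order: N0 N1 | ring A C2..C7, H8..H12 | ring B C13..C18, H19..H23;
    the scanned dihedral is 2-0-1-13 (C-N=N-C).
    """
    cnnc = params.get("cnnc", 180.0)
    r_nn = params.get("nn", 1.25)
    r_cn = params.get("cn", 1.43)
    r_cc = params.get("cc", 1.39)
    r_ch = params.get("ch", 1.09)
    a_cnn = params.get("cnn", 115.0)
    # Near the cis side planar rings would collide (ortho H...H far below
    # van der Waals contact); real cis-azobenzene rotates both phenyls
    # conrotatorily out of the CNNC plane.  The default relief interpolates
    # smoothly from ~55 deg at cis to 0 at trans and can be overridden.
    twist = params.get("ring_twist")
    if twist is None:
        twist = 55.0 * ((1.0 + np.cos(np.radians(cnnc))) / 2.0) ** 2

    entries: list[tuple] = [
        (),                                    # 0: N
        (0, r_nn),                             # 1: N
        (0, r_cn, 1, a_cnn),                   # 2: C ipso ring A
        (1, r_cn, 0, a_cnn, 2, cnnc),          # 13 eventually; placed now as 3
    ]
    # Build with a temporary order, then permute to the documented order.
    # ring A off atom 2 (ipso), reference chain 2-0-1
    ring_a = [
        (2, r_cc, 0, 120.0, 1, 0.0 + twist),   # 4: C ortho
        (2, r_cc, 0, 120.0, 1, 180.0 + twist),  # 5: C ortho'
        (4, r_cc, 2, 120.0, 0, 180.0),         # 6: C meta
        (5, r_cc, 2, 120.0, 0, 180.0),         # 7: C meta'
        (6, r_cc, 4, 120.0, 2, 0.0),           # 8: C para
        (4, r_ch, 2, 120.0, 6, 180.0),         # 9: H ortho
        (5, r_ch, 2, 120.0, 7, 180.0),         # 10: H ortho'
        (6, r_ch, 4, 120.0, 8, 180.0),         # 11: H meta
        (7, r_ch, 5, 120.0, 8, 180.0),         # 12: H meta'
        (8, r_ch, 6, 120.0, 4, 180.0),         # 13: H para
    ]
    # ring B off atom 3 (ipso), reference chain 3-1-0
    ring_b = [
        (3, r_cc, 1, 120.0, 0, 0.0 + twist),
        (3, r_cc, 1, 120.0, 0, 180.0 + twist),
        (14, r_cc, 3, 120.0, 1, 180.0),
        (15, r_cc, 3, 120.0, 1, 180.0),
        (16, r_cc, 14, 120.0, 3, 0.0),
        (14, r_ch, 3, 120.0, 16, 180.0),
        (15, r_ch, 3, 120.0, 17, 180.0),
        (16, r_ch, 14, 120.0, 18, 180.0),
        (17, r_ch, 15, 120.0, 18, 180.0),
        (18, r_ch, 16, 120.0, 14, 180.0),
    ]
    entries = entries + ring_a + ring_b
    coords = zmatrix_to_cartesian(entries)
    # temporary order: N0 N1 C2 C3(ipso B) | ring A C4..C8 H9..H13 | ring B ...
    build_order = [0, 1, 2, 4, 6, 8, 7, 5, 9, 11, 13, 12, 10,
                   3, 14, 16, 18, 17, 15, 19, 21, 23, 22, 20]
    coords = coords[build_order]
    elements = (
        ["N", "N"]
        + ["C"] * 6 + ["H"] * 5
        + ["C"] * 6 + ["H"] * 5
    )
    return Geometry.from_angstrom(
        elements, coords, comment=f"azobenzene CNNC={cnnc} deg"
    )


#: Atom indices of the scanned C-N=N-C dihedral in the azobenzene fixture.
AZOBENZENE_CNNC = (2, 0, 1, 13)


def _quadratic_test_points(params: dict) -> Geometry:
    """Small deterministic H4 tetrahedron used as a generic distorted input."""
    a = params.get("edge", 0.9)
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
    ) * (a / np.sqrt(8.0))
    return Geometry.from_angstrom(["H"] * 4, verts, comment="H4 test points")


_BUILDERS = {
    "h2": _h2,
    "ethylene": _ethylene,
    "azobenzene": _azobenzene,
    "quadratic-test-points": _quadratic_test_points,
}


def build_fixture(name: str, **parameters) -> Geometry:
    """Build a named fixture molecule.

    Parameters override the standard internal coordinates, e.g.
    ``build_fixture("azobenzene", cnnc=90.0)`` or ``build_fixture("h2", r=0.9)``.
    """
    key = name.lower()
    if key not in _BUILDERS:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return _BUILDERS[key](parameters)
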