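"""Geometry I/O, internal coordinates and Kabsch RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xmecp import (
    Geometry,
    build_fixture,
    dihedral,
    distance,
    kabsch_rmsd,
    read_xyz,
    write_xyz,
)
from xmecp.structures import (
    GeometryError,
    XYZParseError,
    dihedral_from_points,
    read_xyz_frames,
    write_xyz_frames,
)
from conftest import rigid_transform


class TestXYZRoundTrip:
    def test_read_simple_h2(self, tmp_path):
        p = tmp_path / "h2.xyz"
        p.write_text("2\nhydrogen\nH 0 0 0\nH 0 0 0.74\n")
        g = read_xyz(p)
        assert g.n_atoms == 2
        assert g.elements == ("H", "H")
        assert distance(g, 0, 1) == pytest.approx(0.74, abs=1e-12)
        assert g.comment == "hydrogen"

    def test_element_symbols_normalized(self, tmp_path):
        p = tmp_path / "x.xyz"
        p.write_text("1\n\nh 0 0 0\n")
        assert read_xyz(p).elements == ("H",)

    def test_count_mismatch_raises(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\ncomment\nH 0 0 0\nH 0 0 1\n")
        with pytest.raises(XYZParseError, match="3 atoms"):
            read_xyz(p)

    def test_malformed_count_line_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("xx\ncomment\nH 0 0 0\n")
        with pytest.raises(XYZParseError, match="line 1"):
            read_xyz(p)

    def test_unknown_element_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nXe 0 0 0\n")
        with pytest.raises(GeometryError, match="unsupported element"):
            read_xyz(p)

    def test_write_starts_with_count(self, tmp_path, h2):
        p = tmp_path / "h2.xyz"
        write_xyz(h2, p)
        assert p.read_text().splitlines()[0] == "2"

    def test_empty_geometry_rejected(self):
        with pytest.raises(GeometryError):
            Geometry((), np.zeros((0, 3)))

    def test_azobenzene_round_trip(self, tmp_path, azobenzene):
        p = tmp_path / "azo.xyz"
        write_xyz(azobenzene, p)
        g2 = read_xyz(p)
        assert g2.elements == azobenzene.elements
        np.testing.assert_allclose(
            g2.coords_angstrom, azobenzene.coords_angstrom, atol=1e-6
        )

    @settings(deadline=None, max_examples=25)
    @given(st.lists(
        st.tuples(
            st.sampled_from(["H", "C", "N", "O", "S"]),
            st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50),
        ),
        min_size=1, max_size=8,
    ))
    def test_round_trip_property(self, tmp_path_factory, atoms):
        els = [a[0] for a in atoms]
        xyz = np.array([a[1:] for a in atoms]) + np.arange(len(atoms))[:, None] * 200.0
        g = Geometry.from_angstrom(els, xyz)
        p = tmp_path_factory.mktemp("rt") / "g.xyz"
        write_xyz(g, p)
        g2 = read_xyz(p)
        np.testing.assert_allclose(g2.coords_angstrom, g.coords_angstrom, atol=1e-6)

    def test_multiframe_round_trip(self, tmp_path, h2):
        frames = [h2, build_fixture("h2", r=0.9)]
        p = tmp_path / "traj.xyz"
        write_xyz_frames(frames, p)
        back = read_xyz_frames(p)
        assert len(back) == 2
        assert distance(back[1], 0, 1) == pytest.approx(0.9, abs=1e-6)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        g = Geometry.from_angstrom(
            ["C"] * 4,
            [[-1, 1, 0], [-1, 0, 0], [1, 0, 0], [1, 1, 0]],
        )
        assert dihedral(g, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        g = Geometry.from_angstrom(
            ["C"] * 4,
            [[-1, 1, 0], [-1, 0, 0], [1, 0, 0], [1, -1, 0]],
        )
        assert abs(dihedral(g, 0, 1, 2, 3)) == pytest.approx(180.0, abs=1e-12)

    def test_staggered_sign_convention(self):
        """+-60 deg butane-like arrangements, checked against an independent
        Newman-projection construction (project the outer bonds onto the
        plane perpendicular to the central bond; clockwise viewed along the
        central bond is positive).  Matches the RDKit sign convention."""
        def place(phi_deg):
            phi = np.radians(phi_deg)
            p0 = np.array([1.0, 0.0, 1.0])
            p1 = np.array([0.0, 0.0, 1.0])
            p2 = np.array([0.0, 0.0, 0.0])
            p3 = np.array([np.cos(phi), np.sin(phi), -1.0])
            return p0, p1, p2, p3

        def newman_oracle(p0, p1, p2, p3):
            axis = (p2 - p1) / np.linalg.norm(p2 - p1)
            u = (p0 - p1) - ((p0 - p1) @ axis) * axis
            v = (p3 - p2) - ((p3 - p2) @ axis) * axis
            return np.degrees(np.arctan2(np.cross(u, v) @ axis, u @ v))

        for phi in (60.0, -60.0, 125.0, -3.0):
            pts = place(phi)
            expected = newman_oracle(*pts)
            # the parametrization rotates counterclockwise seen along the axis
            assert expected == pytest.approx(-phi, abs=1e-9)
            assert dihedral_from_points(*pts) == pytest.approx(expected, abs=1e-9)

    def test_collinear_raises(self):
        g = Geometry.from_angstrom(
            ["C"] * 4, [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]
        )
        with pytest.raises(ValueError, match="collinear"):
            dihedral(g, 0, 1, 2, 3)

    def test_distinct_indices_required(self, azobenzene):
        with pytest.raises(ValueError):
            dihedral(azobenzene, 0, 0, 1, 2)

    @pytest.mark.parametrize("theta", [-179.0, -90.0, -30.0, 10.0, 90.0, 179.0, 180.0])
    def test_fixture_dihedral_echo(self, theta):
        g = build_fixture("azobenzene", cnnc=theta)
        assert dihedral(g, 2, 0, 1, 13) == pytest.approx(theta, abs=1e-6)


class TestFixtures:
    def test_h2_distance(self):
        g = build_fixture("h2", r=0.74)
        assert distance(g, 0, 1) == pytest.approx(0.74, abs=1e-12)

    def test_azobenzene_composition(self, azobenzene):
        from collections import Counter
        c = Counter(azobenzene.elements)
        assert c == {"C": 12, "H": 10, "N": 2}

    def test_ethylene_twist(self):
        g = build_fixture("ethylene", hcch=42.0)
        assert dihedral(g, 2, 0, 1, 4) == pytest.approx(42.0, abs=1e-9)

    def test_unknown_fixture(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            build_fixture("benzene")

    def test_fixture_determinism(self):
        a = build_fixture("azobenzene", cnnc=90.0)
        b = build_fixture("azobenzene", cnnc=90.0)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestKabschRMSD:
    def test_identical_is_zero(self, azobenzene):
        assert kabsch_rmsd(azobenzene, azobenzene) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_motion_invariance(self, azobenzene, seed):
        moved = azobenzene.with_coords(rigid_transform(azobenzene.coords, seed))
        assert kabsch_rmsd(azobenzene, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self, azobenzene):
        other = build_fixture("azobenzene", cnnc=170.0)
        assert kabsch_rmsd(azobenzene, other) == pytest.approx(
            kabsch_rmsd(other, azobenzene), abs=1e-12
        )

    def test_mismatched_elements_raise(self, h2, ethylene):
        with pytest.raises(GeometryError):
            kabsch_rmsd(h2, ethylene)

    def test_against_rotation_grid_oracle(self):
        """3-atom toy with one displaced atom: brute-force search over a fine
        Euler-angle grid (with local refinement) must agree to 1e-4 A."""
        a = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.2, 0]])
        b = a.copy()
        b[2] += np.array([0.2, -0.15, 0.15])  # |d| ~ 0.29 A
        ga = Geometry.from_angstrom(["C", "N", "O"], a)
        gb = Geometry.from_angstrom(["C", "N", "O"], b)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def rmsd_rot(angles):
            ca, cb_, cc = np.cos(angles)
            sa, sb_, sc = np.sin(angles)
            rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            ry = np.array([[cb_, 0, sb_], [0, 1, 0], [-sb_, 0, cb_]])
            rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
            r = rz1 @ ry @ rz2
            d = ac @ r.T - bc
            return np.sqrt(np.mean(np.sum(d * d, axis=1)))

        from scipy.optimize import minimize
        grid = np.linspace(0, 2 * np.pi, 14, endpoint=False)
        best = np.inf
        for x in grid:
            for y in np.linspace(0, np.pi, 8):
                for z in grid:
                    best = min(best, rmsd_rot((x, y, z)))
        for x in grid[::2]:
            for y in np.linspace(0, np.pi, 4):
                res = minimize(rmsd_rot, [x, y, 0.0], method="Nelder-Mead",
                               options=dict(xatol=1e-10, fatol=1e-12))
                best = min(best, res.fun)
        assert kabsch_rmsd(ga, gb) == pytest.approx(best, abs=1e-4)

    def test_heavy_only_option(self, azobenzene):
        jittered = azobenzene.coords.copy()
        # displace only hydrogens
        for i, el in enumerate(azobenzene.elements):
            if el == "H":
                jittered[i] += 0.3
        gb = azobenzene.with_coords(jittered)
        assert kabsch_rmsd(azobenzene, gb, heavy_only=True) == pytest.approx(0.0, abs=1e-9)
        assert kabsch_rmsd(azobenzene, gb) > 0.05
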