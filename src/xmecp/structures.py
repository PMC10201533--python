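"""Molecular geometries: XYZ input/output, internal coordinates, Kabsch RMSD.

Coordinates are stored internally in bohr; XYZ files use Angstrom, following
the usual quantum-chemistry convention.  Geometries are immutable value
objects: every mutating-style operation returns a new :class:`Geometry`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "Geometry",
    "GeometryError",
    "XYZParseError",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "write_xyz_frames",
    "dihedral",
    "bond_angle",
    "distance",
    "kabsch_rmsd",
]

#: Elements with extended-Hueckel parameters shipped in the data file.
SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "S")


class GeometryError(ValueError):
    """Invalid geometry (unknown element, zero atoms, clashing atoms, ...)."""


class XYZParseError(ValueError):
    """Malformed XYZ file."""


@dataclass(frozen=True)
class Geometry:
    """An ordered set of atoms with Cartesian coordinates in bohr.

    Parameters
    ----------
    elements
        Capitalised element symbols, one per atom.
    coords
        ``(n_atoms, 3)`` array, bohr.
    charge
        Net molecular charge (electrons removed if positive).
    comment
        Free-text comment, carried through XYZ round trips.
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    charge: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise GeometryError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] == 0:
            raise GeometryError("geometry must contain at least one atom")
        object.__setattr__(self, "elements", tuple(e.capitalize() for e in self.elements))
        object.__setattr__(self, "coords", coords)
        for el in self.elements:
            if el not in SUPPORTED_ELEMENTS:
                raise GeometryError(
                    f"unsupported element {el!r}; supported: {', '.join(SUPPORTED_ELEMENTS)}"
                )
        if coords.shape[0] > 1:
            # reject exactly coincident atoms early; energy code applies a
            # stricter clash threshold of its own
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if np.min(d) <= 0.0:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise GeometryError(f"atoms {i} and {j} coincide")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def coords_angstrom(self) -> np.ndarray:
        return self.coords * BOHR_TO_ANGSTROM

    @classmethod
    def from_angstrom(
        cls,
        elements: Sequence[str],
        coords_angstrom: np.ndarray,
        charge: int = 0,
        comment: str = "",
    ) -> "Geometry":
        coords = np.asarray(coords_angstrom, dtype=float) * ANGSTROM_TO_BOHR
        return cls(tuple(elements), coords, charge=charge, comment=comment)

    def with_coords(self, coords_bohr: np.ndarray) -> "Geometry":
        """New geometry with replaced coordinates (bohr)."""
        return replace(self, coords=np.asarray(coords_bohr, float).reshape(self.n_atoms, 3))


# ---------------------------------------------------------------------------
# XYZ I/O (xmol dialect)
# ---------------------------------------------------------------------------

def _parse_frame(lines: list[str], start: int, path: str) -> tuple[Geometry, int]:
    count_line = lines[start].strip()
    try:
        n = int(count_line)
    except ValueError:
        raise XYZParseError(
            f"{path}: line {start + 1}: expected atom count, got {count_line!r}"
        ) from None
    if n <= 0:
        raise XYZParseError(f"{path}: line {start + 1}: atom count must be positive")
    if start + 2 + n > len(lines):
        raise XYZParseError(
            f"{path}: header declares {n} atoms but only "
            f"{len(lines) - start - 2} atom lines follow"
        )
    comment = lines[start + 1].rstrip("\n")
    elements: list[str] = []
    xyz = np.empty((n, 3))
    for i in range(n):
        parts = lines[start + 2 + i].split()
        if len(parts) < 4:
            raise XYZParseError(
                f"{path}: line {start + 3 + i}: expected 'El x y z', got "
                f"{lines[start + 2 + i].rstrip()!r}"
            )
        elements.append(parts[0])
        try:
            xyz[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        except ValueError:
            raise XYZParseError(
                f"{path}: line {start + 3 + i}: non-numeric coordinate"
            ) from None
    try:
        geom = Geometry.from_angstrom(elements, xyz, comment=comment)
    except GeometryError as exc:
        raise GeometryError(f"{path}: {exc}") from exc
    return geom, start + 2 + n


def read_xyz(path: str | Path) -> Geometry:
    """Read the first frame of an XYZ file (coordinates in Angstrom)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    geom, _ = _parse_frame(lines, 0, str(path))
    return geom


def read_xyz_frames(path: str | Path) -> list[Geometry]:
    """Read all frames of a (possibly multi-frame) XYZ trajectory."""
    lines = Path(path).read_text().splitlines()
    frames: list[Geometry] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        geom, pos = _parse_frame(lines, pos, str(path))
        frames.append(geom)
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return frames


def _format_frame(geometry: Geometry) -> str:
    buf = io.StringIO()
    buf.write(f"{geometry.n_atoms}\n")
    buf.write(f"{geometry.comment}\n")
    for el, (x, y, z) in zip(geometry.elements, geometry.coords_angstrom):
        buf.write(f"{el:<2s} {x:15.6f} {y:15.6f} {z:15.6f}\n")
    return buf.getvalue()


def write_xyz(geometry: Geometry, path: str | Path) -> None:
    """Write a single-frame XYZ file (Angstrom, 6 decimals)."""
    Path(path).write_text(_format_frame(geometry))


def write_xyz_frames(geometries: Iterable[Geometry], path: str | Path) -> None:
    """Write a multi-frame XYZ trajectory."""
    Path(path).write_text("".join(_format_frame(g) for g in geometries))


# ---------------------------------------------------------------------------
# Internal coordinates
# ---------------------------------------------------------------------------

def distance(geometry: Geometry, i: int, j: int) -> float:
    """Interatomic distance in Angstrom."""
    return float(
        np.linalg.norm(geometry.coords[i] - geometry.coords[j]) * BOHR_TO_ANGSTROM
    )


def bond_angle(geometry: Geometry, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees."""
    u = geometry.coords[i] - geometry.coords[j]
    v = geometry.coords[k] - geometry.coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(geometry: Geometry, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in degrees, in (-180, 180].

    IUPAC sign convention: looking down the j->k axis, a clockwise rotation of
    the distal bond relative to the proximal bond is positive.
    """
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral requires four distinct atom indices")
    p = geometry.coords
    return dihedral_from_points(p[i], p[j], p[k], p[l])


def dihedral_from_points(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees) of four Cartesian points."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * nb2 or np.linalg.norm(n2) < 1e-10 * nb2:
        raise ValueError("dihedral undefined: three consecutive atoms are collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(
    geom_a: Geometry,
    geom_b: Geometry,
    heavy_only: bool = False,
) -> float:
    """Minimal Cartesian RMSD (Angstrom) over proper rotations + translations.

    Atoms are matched by position in the atom list; no permutation search is
    performed, so both geometries must list the same elements in the same
    order.  ``heavy_only=True`` drops hydrogens from the superposition and the
    deviation measure.
    """
    if geom_a.elements != geom_b.elements:
        raise GeometryError("kabsch_rmsd requires identical element sequences")
    mask = np.ones(geom_a.n_atoms, bool)
    if heavy_only:
        mask = np.array([el != "H" for el in geom_a.elements])
        if not mask.any():
            raise GeometryError("no heavy atoms present")
    a = geom_a.coords_angstrom[mask]
    b = geom_b.coords_angstrom[mask]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # Kabsch via SVD of the covariance, with the determinant sign correction
    # restricting the solution to proper rotations.  The RMSD is evaluated
    # from the explicit residual (not the trace identity) to avoid
    # cancellation error for large coordinates.
    u, s, vt = np.linalg.svd(b.T @ a)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    resid = a @ rot.T - b
    return float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
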