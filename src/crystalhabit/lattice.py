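"""Unit-cell arithmetic: metric tensors, interplanar spacings, plane normals
and point-group expansion of crystal face forms.

The conventions used throughout the package:

* Cartesian frame: the **a** axis lies along x, **b** in the x-y plane and
  **c** completes a right-handed set.
* A face is a Miller index triple (h, k, l).  Its outward normal is the
  direction of the reciprocal-lattice vector G(hkl) and the interplanar
  spacing is d_hkl = 1/|G(hkl)|.
* A *form* {h k l} is the orbit of a face under the crystal's point group;
  every face of the form shares d_hkl and (for growth morphology) the
  attachment energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians, sin, sqrt
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "FaceForm",
    "d_spacing",
    "plane_unit_normal",
    "symmetry_equivalents",
    "POINT_GROUPS",
]

Miller = tuple[int, int, int]


def _check_miller(face: Sequence[int]) -> Miller:
    h, k, l = (int(i) for i in face)
    if (h, k, l) != tuple(face):
        raise ValueError(f"Miller indices must be integers, got {face!r}")
    if h == k == l == 0:
        raise ValueError("Miller index (0 0 0) does not define a plane")
    return (h, k, l)


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in angstroms, angles in degrees.

    Handles the general triclinic case through the metric tensor even when
    the cell of interest is tetragonal.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ValueError("cell parameters give a non-positive volume")

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with the direct lattice vectors as *columns*
        (a along x, b in the x-y plane)."""
        al, be, ga = (radians(x) for x in (self.alpha, self.beta, self.gamma))
        cx = self.c * cos(be)
        cy = self.c * (cos(al) - cos(be) * cos(ga)) / sin(ga)
        cz_sq = self.c**2 - cx**2 - cy**2
        if cz_sq <= 0:
            raise ValueError("cell angles are geometrically inconsistent")
        return np.array(
            [
                [self.a, self.b * cos(ga), cx],
                [0.0, self.b * sin(ga), cy],
                [0.0, 0.0, sqrt(cz_sq)],
            ]
        )

    @property
    def volume(self) -> float:
        al, be, ga = (radians(x) for x in (self.alpha, self.beta, self.gamma))
        s = 1 - cos(al) ** 2 - cos(be) ** 2 - cos(ga) ** 2 + 2 * cos(al) * cos(be) * cos(ga)
        if s <= 0:
            return float("nan")
        return self.a * self.b * self.c * sqrt(s)

    @property
    def metric(self) -> np.ndarray:
        """Direct metric tensor G_ij = a_i . a_j."""
        m = self.orthogonalization_matrix
        return m.T @ m

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    def reciprocal_vector(self, face: Sequence[int]) -> np.ndarray:
        """Cartesian reciprocal-lattice vector G(hkl) (units 1/angstrom)."""
        hkl = np.asarray(_check_miller(face), dtype=float)
        # rows of inv(M) are the reciprocal basis vectors in Cartesian coords
        return hkl @ np.linalg.inv(self.orthogonalization_matrix)

    @classmethod
    def from_dict(cls, d: dict) -> "UnitCell":
        return cls(
            a=float(d["a"]), b=float(d["b"]), c=float(d["c"]),
            alpha=float(d.get("alpha", 90.0)),
            beta=float(d.get("beta", 90.0)),
            gamma=float(d.get("gamma", 90.0)),
        )


def d_spacing(cell: UnitCell, face: Sequence[int]) -> float:
    """Interplanar spacing d_hkl in angstroms.

    d_hkl = 1 / sqrt(h^T G* h) with G* the reciprocal metric tensor; for an
    orthogonal cell this reduces to 1/sqrt(h^2/a^2 + k^2/b^2 + l^2/c^2).
    Invariant under negating all three indices.
    """
    hkl = np.asarray(_check_miller(face), dtype=float)
    return float(1.0 / sqrt(hkl @ cell.reciprocal_metric @ hkl))


def plane_unit_normal(cell: UnitCell, face: Sequence[int]) -> np.ndarray:
    """Outward unit normal of the (h k l) plane: direction of G(hkl)."""
    g = cell.reciprocal_vector(face)
    return g / np.linalg.norm(g)


def _rot_matrices(generators: Iterable[np.ndarray]) -> list[np.ndarray]:
    """Close a set of integer generator matrices into the full group."""
    mats = [np.eye(3, dtype=int)]
    frontier = [np.asarray(g, dtype=int) for g in generators]
    seen = {mats[0].tobytes()}
    while frontier:
        g = frontier.pop()
        if g.tobytes() not in seen:
            seen.add(g.tobytes())
            mats.append(g)
        for m in list(mats):
            for prod in (g @ m, m @ g):
                if prod.tobytes() not in seen:
                    frontier.append(prod)
    return mats


_R2Z = np.array([[-1, 0, 0], [0, -1, 0], [0, 0, 1]])
_R4Z = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])  # (h,k,l) -> (k,-h,l) on row vectors
_R2X = np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1]])

#: Supported proper-rotation point groups, keyed by Hermann-Mauguin symbol.
POINT_GROUPS: dict[str, list[np.ndarray]] = {
    "1": _rot_matrices([]),
    "2": _rot_matrices([_R2Z]),
    "4": _rot_matrices([_R4Z]),
    "222": _rot_matrices([_R2Z, _R2X]),
    "422": _rot_matrices([_R4Z, _R2X]),
}


def symmetry_equivalents(face: Sequence[int], point_group: str = "1") -> list[Miller]:
    """Orbit of (h k l) under the proper rotations of *point_group*.

    Group ``"4"`` (the rotations of space group P4_3 about c) maps
    (h,k,l) -> {(h,k,l), (k,-h,l), (-h,-k,l), (-k,h,l)}; note it does not
    relate +l to -l, so e.g. (1 0 1) and (1 0 -1) are distinct forms.
    """
    try:
        mats = POINT_GROUPS[str(point_group)]
    except KeyError:
        raise ValueError(
            f"unsupported point group {point_group!r}; "
            f"supported: {sorted(POINT_GROUPS)}"
        ) from None
    hkl = np.asarray(_check_miller(face), dtype=int)
    orbit = {tuple(int(x) for x in hkl @ m) for m in mats}
    return sorted(orbit, reverse=True)


@dataclass(frozen=True)
class FaceForm:
    """A symmetry form {h k l} with its spacing and attachment energy.

    ``energy`` is the (possibly solvent-modified) attachment energy in
    kcal/mol/unit cell; growth faces have energy <= 0 and the facet distance
    used by the growth morphology is |energy|.
    """

    representative: Miller
    equivalents: tuple[Miller, ...]
    d_hkl: float
    energy: float
    point_group: str = "1"

    @property
    def multiplicity(self) -> int:
        return len(self.equivalents)

    @classmethod
    def from_cell(
        cls,
        cell: UnitCell,
        face: Sequence[int],
        energy: float,
        point_group: str = "1",
        expected_multiplicity: int | None = None,
    ) -> "FaceForm":
        rep = _check_miller(face)
        eqs = tuple(symmetry_equivalents(rep, point_group))
        if expected_multiplicity is not None and len(eqs) != expected_multiplicity:
            raise ValueError(
                f"form {rep}: point group {point_group!r} gives multiplicity "
                f"{len(eqs)}, expected {expected_multiplicity}"
            )
        return cls(
            representative=rep,
            equivalents=eqs,
            d_hkl=d_spacing(cell, rep),
            energy=float(energy),
            point_group=str(point_group),
        )
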