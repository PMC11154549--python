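"""Solvent-accessible surface area (Shrake-Rupley sampling) and rugosity.

The accessible surface of an atom is the sphere of radius r_atom + r_probe
traced by the probe centre.  Each atom's sphere is sampled on a
deterministic Fibonacci point lattice; a point is exposed if it lies
outside every other atom's extended sphere, and the atom contributes
(exposed fraction) * 4 pi (r + probe)^2.

The rugosity of a crystal face is S = A_acc / A_hkl: the accessible area of
the face divided by its flat cross-section, so an ideally flat face has
S = 1 and corrugated faces score higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "fibonacci_sphere",
    "sasa",
    "per_atom_sasa",
    "slab_top_sasa",
    "rugosity",
]

#: van der Waals radii (angstrom), Bondi values for the elements used here.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

DEFAULT_PROBE = 1.4  # angstrom, water-sized probe


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (no RNG)."""
    if n_points < 1:
        raise ValueError("need at least one sample point")
    i = np.arange(n_points) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_points
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def per_atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = 1000,
) -> np.ndarray:
    """Accessible area contributed by each atom (angstrom^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_atoms, 3)")
    if radii.shape != (coords.shape[0],) or np.any(radii <= 0):
        raise ValueError("radii must be positive, one per atom")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    ext = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.empty(len(coords))
    rmax = ext.max()
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax)
                 if j != i]
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :], axis=-1)
            buried = (d < ext[neigh][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return areas


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = 1000,
) -> float:
    """Total solvent-accessible surface area (angstrom^2)."""
    return float(per_atom_sasa(coords, radii, probe, n_points).sum())


def slab_top_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    box_xy: tuple[float, float],
    top_depth: float = 4.0,
    probe: float = DEFAULT_PROBE,
    n_points: int = 1000,
) -> float:
    """Accessible area of a slab's upper surface, per lateral cell.

    Atoms within *top_depth* of the slab's highest atom are credited; the
    slab is laterally replicated (3x3 periodic images) so central-cell atoms
    see the environment an infinite surface would provide, and only the
    central image's top atoms are summed.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lx, ly = box_xy
    if lx <= 0 or ly <= 0:
        raise ValueError("lateral box lengths must be positive")
    images, img_radii = [], []
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            shifted = coords + np.array([ix * lx, iy * ly, 0.0])
            images.append(shifted)
            img_radii.append(radii)
    all_coords = np.vstack(images)
    all_radii = np.concatenate(img_radii)
    areas = per_atom_sasa(all_coords, all_radii, probe, n_points)
    # central image occupies block index 4 of the 3x3 replication
    n = len(coords)
    central = slice(4 * n, 5 * n)
    z = coords[:, 2]
    top = z >= z.max() - top_depth
    return float(areas[central][top].sum())


def rugosity(a_acc: float, a_hkl: float) -> float:
    """Rugosity S = A_acc / A_hkl (dimensionless; 1 for an ideally flat face)."""
    if a_acc <= 0 or a_hkl <= 0:
        raise ValueError("areas must be positive")
    return a_acc / a_hkl
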