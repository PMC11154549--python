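"""Seeded synthetic-trajectory generators with known ground truth.

These generators stand in for molecular-dynamics output when exercising the
estimators: Brownian walkers with a known diffusion coefficient, ideal-gas
frames for RDF normalisation, layered boxes with prescribed z-density
profiles, planted hydrogen-bond scenes, and simple-cubic slabs of known
surface structure.  All randomness comes from ``numpy.random.default_rng``
(PCG64), so a fixed seed reproduces output byte-for-byte; the generating
parameters are echoed into the trajectory metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hbonds import HBondRecord
from .trajectory import Trajectory

__all__ = [
    "gen_brownian",
    "gen_ideal_gas",
    "gen_layered",
    "gen_hbond_scene",
    "gen_slab",
    "HBondScene",
]


def gen_brownian(
    n_particles: int,
    n_frames: int,
    dt_ps: float,
    d_true: float,
    box: tuple[float, float, float],
    seed: int,
    label: str = "P",
) -> Trajectory:
    """Free Brownian motion at diffusion coefficient *d_true* (A^2/ps).

    Steps are independent Gaussians with per-axis variance 2*D*dt.  Wrapped
    coordinates go into ``coords``; the continuous walk is kept in
    ``coords_unwrapped`` so displacement statistics need no unwrapping.
    """
    if min(n_particles, n_frames) < 1 or dt_ps <= 0 or d_true < 0:
        raise ValueError("counts and time step must be positive, D >= 0")
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    start = rng.uniform(0.0, box_arr, size=(n_particles, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * d_true * dt_ps),
                       size=(n_frames - 1, n_particles, 3)) if n_frames > 1 else \
        np.zeros((0, n_particles, 3))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    wrapped = np.mod(unwrapped, box_arr)
    return Trajectory(
        labels=np.full(n_particles, label),
        coords=wrapped,
        box=box_arr,
        dt_ps=dt_ps,
        periodic=(True, True, True),
        coords_unwrapped=unwrapped,
        metadata={"kind": "brownian", "n_particles": n_particles,
                  "n_frames": n_frames, "dt_ps": dt_ps, "D_true": d_true,
                  "box": list(box), "seed": seed},
    )


def gen_ideal_gas(
    n_atoms: int,
    n_frames: int,
    box: tuple[float, float, float],
    seed: int,
    label: str = "G",
) -> Trajectory:
    """Uncorrelated uniform positions each frame (g(r) = 1 everywhere)."""
    if min(n_atoms, n_frames) < 1:
        raise ValueError("need at least one atom and one frame")
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    coords = rng.uniform(0.0, box_arr, size=(n_frames, n_atoms, 3))
    return Trajectory(
        labels=np.full(n_atoms, label),
        coords=coords,
        box=box_arr,
        dt_ps=1.0,
        periodic=(True, True, True),
        metadata={"kind": "ideal-gas", "n_atoms": n_atoms,
                  "n_frames": n_frames, "box": list(box), "seed": seed},
    )


def _inverse_cdf_sample(rng, pdf, lo: float, hi: float, n: int) -> np.ndarray:
    """Draw from an (unnormalised) 1-D density via numeric inverse CDF."""
    z = np.linspace(lo, hi, 4096)
    p = np.clip(np.asarray([pdf(v) for v in z], dtype=float), 0.0, None)
    cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) / 2.0 * np.diff(z))])
    if cdf[-1] <= 0:
        raise ValueError("density is zero over the sampling range")
    cdf /= cdf[-1]
    return np.interp(rng.uniform(0, 1, n), cdf, z)


def gen_layered(
    n_by_species: dict[str, int],
    box: tuple[float, float, float],
    z_profiles: dict[str, object],
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Multi-species box with prescribed z-densities (uniform laterally).

    ``z_profiles`` maps a species label to a callable z -> relative density
    on [0, Lz]; positions are drawn per frame by inverse-CDF sampling, which
    makes the analytic profile the exact ground truth for the density
    estimator.
    """
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    labels, per_frame = [], []
    for name, n in n_by_species.items():
        if n < 1:
            raise ValueError(f"species {name!r} needs at least one atom")
        labels.extend([name] * n)
    frames = []
    for _ in range(n_frames):
        chunks = []
        for name, n in n_by_species.items():
            xy = rng.uniform(0.0, box_arr[:2], size=(n, 2))
            z = _inverse_cdf_sample(rng, z_profiles[name], 0.0, box_arr[2], n)
            chunks.append(np.column_stack([xy, z]))
        frames.append(np.vstack(chunks))
    return Trajectory(
        labels=np.array(labels),
        coords=np.stack(frames),
        box=box_arr,
        dt_ps=1.0,
        periodic=(True, True, False),
        metadata={"kind": "layered", "n_by_species": dict(n_by_species),
                  "n_frames": n_frames, "box": list(box), "seed": seed},
    )


@dataclass
class HBondScene:
    """A single frame with planted hydrogen bonds and decoys."""

    coords: np.ndarray
    labels: np.ndarray
    box: np.ndarray
    donors: list[tuple[int, int]]     # (D, H) pairs, planted and decoy
    acceptors: list[int]
    planted: list[HBondRecord]        # ground-truth qualifying bonds


def gen_hbond_scene(
    n_true: int,
    n_decoy: int,
    box: tuple[float, float, float],
    seed: int,
    length_mean: float = 2.57,
    length_sd: float = 0.12,
    angle_mean: float = 150.0,
    angle_sd: float = 10.0,
    d_max: float = 3.1,
    angle_min: float = 120.0,
) -> HBondScene:
    """Plant *n_true* qualifying (D, H, A) triples plus decoys.

    Planted bonds draw H...A lengths and D-H...A angles from clipped
    Gaussians inside the acceptance windows; each decoy violates exactly
    one criterion (alternating too-long distance / too-bent angle).  Triples
    sit on a coarse grid so they cannot interfere with one another.
    """
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    total = n_true + n_decoy
    spacing = 9.0  # > d_max + max bond extent, so triples are independent
    per_axis = int(np.ceil(total ** (1.0 / 3.0)))
    if per_axis * spacing > min(box_arr):
        raise ValueError("box too small for the requested number of triples")
    coords, labels = [], []
    donors, acceptors, planted = [], [], []
    sites = [(i, j, k) for i in range(per_axis)
             for j in range(per_axis) for k in range(per_axis)][:total]
    for t, site in enumerate(sites):
        h_pos = (np.asarray(site, dtype=float) + 0.5) * spacing
        is_true = t < n_true
        if is_true:
            length = float(np.clip(rng.normal(length_mean, length_sd),
                                   1.6, d_max - 0.05))
            angle = float(np.clip(rng.normal(angle_mean, angle_sd),
                                  angle_min + 1.0, 179.0))
        elif (t - n_true) % 2 == 0:  # distance decoy: good angle, too far
            length = float(rng.uniform(d_max + 0.2, d_max + 1.2))
            angle = float(np.clip(rng.normal(angle_mean, angle_sd),
                                  angle_min + 1.0, 179.0))
        else:                        # angle decoy: good length, too bent
            length = float(np.clip(rng.normal(length_mean, length_sd),
                                   1.6, d_max - 0.05))
            angle = float(rng.uniform(60.0, angle_min - 5.0))
        u = _random_unit(rng)
        a_pos = h_pos + length * u
        # place D at 1.0 A from H so that the D-H...A angle equals `angle`
        theta = np.radians(angle)
        perp = _random_perpendicular(rng, u)
        d_dir = np.cos(theta) * u + np.sin(theta) * perp
        d_pos = h_pos + 1.0 * d_dir
        base = len(coords)
        coords.extend([d_pos, h_pos, a_pos])
        labels.extend(["D", "H1", "A"])
        donors.append((base, base + 1))
        acceptors.append(base + 2)
        if is_true:
            planted.append(HBondRecord(frame=0, donor=base, hydrogen=base + 1,
                                       acceptor=base + 2, length=length,
                                       angle=angle))
    return HBondScene(
        coords=np.array(coords), labels=np.array(labels), box=box_arr,
        donors=donors, acceptors=acceptors, planted=planted,
    )


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_perpendicular(rng, u: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v -= (v @ u) * u
    return v / np.linalg.norm(v)


def gen_slab(
    lattice_constant: float,
    nx: int,
    ny: int,
    layers: int,
    vacuum: float,
    label: str = "C",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple-cubic slab: (coords, labels, box) with a vacuum pad above.

    nx*ny atoms per layer, ``layers`` layers deep; the box is periodic
    laterally and tall enough to hold the slab plus *vacuum*.
    """
    if min(nx, ny, layers) < 1 or lattice_constant <= 0 or vacuum < 0:
        raise ValueError("slab dimensions must be positive")
    a = lattice_constant
    grid = np.array([
        [(i + 0.5) * a, (j + 0.5) * a, (k + 0.5) * a]
        for k in range(layers) for j in range(ny) for i in range(nx)
    ])
    box = np.array([nx * a, ny * a, layers * a + vacuum])
    labels = np.full(len(grid), label)
    return grid, labels, box
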