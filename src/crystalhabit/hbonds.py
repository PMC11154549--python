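"""Geometric hydrogen-bond detection and census statistics.

A hydrogen bond is recorded for every (donor-H, acceptor) pair whose
H...A minimum-image distance is at most ``d_max`` (default 3.1 A, the
distance window below which an RDF peak is read as hydrogen bonding) and
whose D-H...A angle is at least ``angle_min`` (default 120 deg; a perfectly
linear bond is 180 deg).  A single H may be counted with several acceptors
simultaneously; each qualifying pair is one record.

The census reported per system mirrors the bookkeeping used to compare
crystal-face systems: mean bond length and angle, the fractions of short
(< 2.5 A) and near-linear (> 150 deg) bonds, the mean number of bonds per
frame (N_HB), the number of distinct donor hydrogens ever bonded in the
window (N_H1), and the derived per-donor, per-unit-area and per-unit-cell
face counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import Trajectory, minimum_image

__all__ = [
    "HBondRecord",
    "HBondSummary",
    "AngleLengthDensity",
    "detect_hbonds",
    "detect_hbonds_trajectory",
    "summarize_hbonds",
    "length_angle_densities",
    "band_probability",
]

DEFAULT_D_MAX = 3.1      # angstrom, H...A cutoff
DEFAULT_ANGLE_MIN = 120.0  # degrees, D-H...A cutoff


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int     # atom index of D
    hydrogen: int  # atom index of H
    acceptor: int  # atom index of A
    length: float  # H...A distance (angstrom)
    angle: float   # D-H...A angle (degrees); 180 = linear


def detect_hbonds(
    coords: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    box: np.ndarray,
    periodic: tuple[bool, bool, bool] = (True, True, False),
    d_max: float = DEFAULT_D_MAX,
    angle_min: float = DEFAULT_ANGLE_MIN,
    frame: int = 0,
) -> list[HBondRecord]:
    """Find hydrogen bonds in a single frame.

    ``donors`` is a list of (D, H) index pairs — each covalently bonded
    donor-hydrogen unit; ``acceptors`` a list of acceptor atom indices.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    donors = list(donors)
    acceptors = np.asarray(list(acceptors), dtype=int)
    if len(donors) == 0 or acceptors.size == 0:
        return []
    for d, h in donors:
        if d == h:
            raise ValueError(f"hydrogen {h} lists itself as its donor")
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    records: list[HBondRecord] = []
    h_idx = np.array([h for _, h in donors])
    d_idx = np.array([d for d, _ in donors])
    ha = minimum_image(coords[acceptors][None, :, :] - coords[h_idx][:, None, :],
                       box, periodic)
    dist = np.linalg.norm(ha, axis=-1)
    hd = minimum_image(coords[d_idx] - coords[h_idx], box, periodic)
    for i, (d, h) in enumerate(donors):
        hits = np.flatnonzero(dist[i] <= d_max)
        for j in hits:
            a = int(acceptors[j])
            if a == h or a == d:
                continue
            v1, v2 = hd[i], ha[i, j]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= angle_min:
                records.append(HBondRecord(frame=frame, donor=d, hydrogen=h,
                                           acceptor=a, length=float(dist[i, j]),
                                           angle=ang))
    return records


def detect_hbonds_trajectory(
    traj: Trajectory,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    d_max: float = DEFAULT_D_MAX,
    angle_min: float = DEFAULT_ANGLE_MIN,
    last_ps: float | None = None,
) -> tuple[list[HBondRecord], int]:
    """Detect bonds over the trailing window; returns (records, n_frames)."""
    frames = traj.trailing_frames(last_ps=last_ps)
    records: list[HBondRecord] = []
    for f in frames:
        records.extend(
            detect_hbonds(traj.coords[f], donors, acceptors, traj.box[f],
                          periodic=traj.periodic, d_max=d_max,
                          angle_min=angle_min, frame=int(f))
        )
    return records, len(frames)


@dataclass
class HBondSummary:
    """The eleven-statistic hydrogen-bond census of one face system.

    Undefined ratios (no bonds, or no participating donors) are NaN and
    flagged through :attr:`defined`.
    """

    mean_length: float       # mean H...A distance (angstrom)
    mean_angle: float        # mean D-H...A angle (degrees)
    s1_percent: float        # % of bonds with length < 2.5 A
    s2_percent: float        # % of bonds with angle > 150 deg
    n_hb: float              # mean bonds per frame
    n_h1: int                # distinct donor hydrogens ever bonded
    n_hb_per_h1: float       # n_hb / n_h1
    a_box: float             # box cross-section (angstrom^2)
    n_hb_unit_area: float    # n_hb / a_box
    a_hkl: float             # unit-cell face cross-section (angstrom^2)
    n_hb_hkl: float          # n_hb_unit_area * a_hkl

    @property
    def defined(self) -> bool:
        return not np.isnan(self.mean_length)

    def as_row(self) -> dict:
        return {
            "HB length": self.mean_length, "HB angle": self.mean_angle,
            "S1%": self.s1_percent, "S2%": self.s2_percent,
            "N_HB": self.n_hb, "N_H1": self.n_h1,
            "N_HB-per H1": self.n_hb_per_h1, "A_box": self.a_box,
            "N_HB-unit area": self.n_hb_unit_area, "A_hkl": self.a_hkl,
            "N_HB-hkl": self.n_hb_hkl,
        }


def summarize_hbonds(
    records: Sequence[HBondRecord],
    n_frames: int,
    a_box: float,
    a_hkl: float,
    length_threshold: float = 2.5,
    angle_threshold: float = 150.0,
) -> HBondSummary:
    """Aggregate detected bonds into the per-face census."""
    if n_frames < 1:
        raise ValueError("need at least one analysed frame")
    if a_box <= 0 or a_hkl <= 0:
        raise ValueError("areas must be positive")
    n_hb = len(records) / n_frames
    n_h1 = len({r.hydrogen for r in records})
    if records:
        lengths = np.array([r.length for r in records])
        angles = np.array([r.angle for r in records])
        mean_length = float(lengths.mean())
        mean_angle = float(angles.mean())
        s1 = 100.0 * float((lengths < length_threshold).mean())
        s2 = 100.0 * float((angles > angle_threshold).mean())
        per_h1 = n_hb / n_h1 if n_h1 > 0 else float("nan")
    else:
        mean_length = mean_angle = s1 = s2 = per_h1 = float("nan")
    unit_area = n_hb / a_box
    return HBondSummary(
        mean_length=mean_length, mean_angle=mean_angle,
        s1_percent=s1, s2_percent=s2,
        n_hb=n_hb, n_h1=n_h1, n_hb_per_h1=per_h1,
        a_box=a_box, n_hb_unit_area=unit_area,
        a_hkl=a_hkl, n_hb_hkl=unit_area * a_hkl,
    )


def census_identities(n_hb: float, n_h1: int, a_box: float, a_hkl: float) -> dict:
    """Derived census columns from the aggregate counts.

    Returns N_HB-per H1 = N_HB/N_H1, N_HB-unit area = N_HB/A_box and
    N_HB-hkl = (N_HB/A_box) * A_hkl; the per-donor ratio is NaN when no
    donor hydrogen ever bonded.
    """
    if a_box <= 0 or a_hkl <= 0:
        raise ValueError("areas must be positive")
    unit_area = n_hb / a_box
    return {
        "N_HB-per H1": n_hb / n_h1 if n_h1 > 0 else float("nan"),
        "N_HB-unit area": unit_area,
        "N_HB-hkl": unit_area * a_hkl,
    }


@dataclass
class AngleLengthDensity:
    centers: np.ndarray
    density: np.ndarray
    bin_width: float

    def integral(self) -> float:
        return float(self.density.sum() * self.bin_width)


def length_angle_densities(
    records: Sequence[HBondRecord],
    length_bin: float = 0.02,
    angle_bin: float = 2.0,
) -> tuple[AngleLengthDensity, AngleLengthDensity]:
    """Probability densities of H...A length and D-H...A angle."""
    if not records:
        raise ValueError("no hydrogen-bond records to histogram")
    out = []
    for values, width in (
        (np.array([r.length for r in records]), length_bin),
        (np.array([r.angle for r in records]), angle_bin),
    ):
        lo = np.floor(values.min() / width) * width
        n = int(np.ceil((values.max() - lo) / width)) + 1
        edges = lo + np.arange(n + 1) * width
        dens, _ = np.histogram(values, bins=edges, density=True)
        out.append(AngleLengthDensity(
            centers=0.5 * (edges[:-1] + edges[1:]), density=dens, bin_width=width,
        ))
    return out[0], out[1]


def band_probability(density: AngleLengthDensity, lo: float, hi: float) -> float:
    """Probability mass of the density on [lo, hi] (partial bins included)."""
    if hi < lo:
        raise ValueError("band limits inverted")
    left = density.centers - density.bin_width / 2.0
    right = density.centers + density.bin_width / 2.0
    overlap = np.clip(np.minimum(right, hi) - np.maximum(left, lo), 0.0, None)
    return float((density.density * overlap).sum())
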