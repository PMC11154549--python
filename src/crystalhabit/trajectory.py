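"""Trajectory container and estimators: RDF, MSD/diffusion, density profiles.

A :class:`Trajectory` holds ordered frames of labelled Cartesian coordinates
in an orthorhombic box.  Slab systems are periodic in x and y only (the z
direction carries a vacuum pad); synthetic bulk systems may be fully
periodic.  All lengths are angstroms, times picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Trajectory",
    "RDFResult",
    "MSDResult",
    "DensityProfile",
    "rdf",
    "classify_interaction",
    "msd",
    "density_profile",
]

Selection = "str | Sequence[int] | Callable[[str], bool]"


@dataclass
class Trajectory:
    """Ordered frames of labelled coordinates in an orthorhombic box.

    Parameters
    ----------
    labels : array of atom labels, fixed across frames.
    coords : (n_frames, n_atoms, 3) Cartesian coordinates in angstroms.
    box : (3,) or (n_frames, 3) orthorhombic box lengths.
    dt_ps : time between stored frames in picoseconds.
    periodic : which of x, y, z wrap periodically.
    coords_unwrapped : optional continuous (image-flag-free) coordinates,
        stored by generators whose particles cross box boundaries.
    metadata : free-form provenance (generator parameters, seed, ...).
    """

    labels: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    dt_ps: float
    periodic: tuple[bool, bool, bool] = (True, True, False)
    coords_unwrapped: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=str)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("label count does not match atom count")
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (self.n_frames, 3)).copy()
        if box.shape != (self.n_frames, 3) or np.any(box <= 0):
            raise ValueError("box must be positive lengths, one triple per frame")
        self.box = box
        if self.dt_ps <= 0:
            raise ValueError("time step must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, selection) -> np.ndarray:
        """Resolve a selection (label string, index list or predicate) to indices."""
        if callable(selection):
            idx = np.array([i for i, lab in enumerate(self.labels) if selection(lab)])
        elif isinstance(selection, str):
            idx = np.flatnonzero(self.labels == selection)
        else:
            idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return idx

    def trailing_frames(self, last_ps: float | None = None,
                        last_frames: int | None = None) -> np.ndarray:
        """Indices of the trailing analysis window (ps or frame count)."""
        if last_ps is not None and last_frames is not None:
            raise ValueError("give last_ps or last_frames, not both")
        if last_frames is None:
            if last_ps is None:
                return np.arange(self.n_frames)
            last_frames = int(round(last_ps / self.dt_ps))
        last_frames = max(1, min(last_frames, self.n_frames))
        return np.arange(self.n_frames - last_frames, self.n_frames)

    def unwrapped(self) -> np.ndarray:
        """Continuous coordinates: stored if available, else accumulated
        minimum-image displacements (requires per-step moves < half box)."""
        if self.coords_unwrapped is not None:
            return self.coords_unwrapped
        out = self.coords.copy()
        for f in range(1, self.n_frames):
            delta = self.coords[f] - self.coords[f - 1]
            for ax in range(3):
                if self.periodic[ax]:
                    L = self.box[f, ax]
                    delta[:, ax] -= L * np.round(delta[:, ax] / L)
            out[f] = out[f - 1] + delta
        return out


def minimum_image(delta: np.ndarray, box: np.ndarray,
                  periodic: tuple[bool, bool, bool]) -> np.ndarray:
    """Apply the minimum-image convention along the periodic axes."""
    delta = np.array(delta, dtype=float, copy=True)
    for ax in range(3):
        if periodic[ax]:
            L = box[ax]
            delta[..., ax] -= L * np.round(delta[..., ax] / L)
    return delta


@dataclass
class RDFResult:
    r: np.ndarray        # bin centres (angstrom)
    g: np.ndarray        # g(r), dimensionless
    bin_width: float
    counts: np.ndarray   # raw pair counts per bin (summed over frames)

    def peak_position(self, r_min: float = 0.0, r_max: float | None = None) -> float:
        mask = (self.r >= r_min) & (self.r <= (r_max or self.r[-1]))
        return float(self.r[mask][np.argmax(self.g[mask])])


def rdf(
    traj: Trajectory,
    reference,
    counted,
    r_max: float,
    bin_width: float = 0.05,
    frames: np.ndarray | None = None,
) -> RDFResult:
    """Radial distribution function g(r) between two selections.

    g(r) is the density of counted atoms in the shell at distance r from a
    reference atom, divided by the average density of counted atoms over the
    whole box (N_counted / V_box) — the whole-box normalisation keeps slab
    systems with a vacuum pad comparable across faces.  Distances use the
    minimum image along the trajectory's periodic axes.
    """
    ref_idx = traj.select(reference)
    cnt_idx = traj.select(counted)
    frames = np.arange(traj.n_frames) if frames is None else np.asarray(frames)
    half_min = min(
        traj.box[frames][:, ax].min() / 2.0
        for ax in range(3) if traj.periodic[ax]
    ) if any(traj.periodic) else np.inf
    if r_max > half_min:
        raise ValueError(
            f"r_max={r_max:g} exceeds half the smallest periodic box length "
            f"({half_min:g})"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = 0.0
    overlap = np.intersect1d(ref_idx, cnt_idx).size > 0
    for f in frames:
        box = traj.box[f]
        delta = traj.coords[f][cnt_idx][None, :, :] - traj.coords[f][ref_idx][:, None, :]
        delta = minimum_image(delta, box, traj.periodic)
        d = np.linalg.norm(delta, axis=-1)
        if overlap:
            same = ref_idx[:, None] == cnt_idx[None, :]
            d = d[~same]
        h, _ = np.histogram(d, bins=edges)
        counts += h
        rho_box = len(cnt_idx) / float(np.prod(box))
        norm += len(ref_idx) * rho_box
    g = counts / (shell_vol * norm)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centres, g=g, bin_width=bin_width, counts=counts)


#: Distance windows (angstrom) separating interaction types seen as RDF peaks.
HBOND_MAX = 3.1
VDW_MAX = 5.0


def classify_interaction(peak_position: float) -> str:
    """Interpret an RDF peak position: hydrogen bond (< 3.1 A),
    van der Waals (3.1-5 A) or no specific interaction (> 5 A)."""
    if peak_position <= 0:
        raise ValueError("peak position must be positive")
    if peak_position < HBOND_MAX:
        return "hydrogen-bond"
    if peak_position <= VDW_MAX:
        return "van-der-Waals"
    return "none"


@dataclass
class MSDResult:
    lags_ps: np.ndarray
    msd: np.ndarray              # angstrom^2
    fit_window_ps: tuple[float, float]
    slope: float                 # angstrom^2 / ps
    diffusion: float             # 1e-8 m^2/s (numerically == angstrom^2/ps)
    diffusion_stderr: float

    @property
    def diffusion_ang2_per_ps(self) -> float:
        # 1 A^2/ps = 1e-20 m^2 / 1e-12 s = 1e-8 m^2/s: same number
        return self.diffusion


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Multiple-time-origin MSD of one particle track x (n_frames, 3),
    via the FFT autocorrelation identity (O(F log F))."""
    F = x.shape[0]
    nfft = 1 << (2 * F - 1).bit_length()
    sq = (x**2).sum(axis=1)
    # S2(t) = sum_m x(m).x(m+t) for each axis, via FFT
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:F].sum(axis=1)
    # S1(t) = sum_m [ |x(m)|^2 + |x(m+t)|^2 ]
    ssum = np.concatenate(([0.0], np.cumsum(sq)))
    s1 = np.array([ssum[F] - ssum[t] + ssum[F - t] for t in range(F)])
    n_pairs = F - np.arange(F)
    return (s1 - 2.0 * acf) / n_pairs


def msd(
    traj: Trajectory,
    selection,
    use_multiple_origins: bool = True,
    fit_window: tuple[float, float] = (0.02, 0.2),
) -> MSDResult:
    """Mean-square displacement and Einstein-relation diffusion coefficient.

    MSD(tau) is averaged over the selected atoms (and over all time origins
    when *use_multiple_origins*); the diffusion coefficient is the slope of
    the least-squares line over the lag window ``fit_window`` (fractions of
    the maximum lag) divided by 6, reported in 1e-8 m^2/s (numerically
    identical to angstrom^2/ps).

    The default window (2-20% of the maximum lag) keeps the fit in the
    regime where the multiple-origin MSD still has many weakly correlated
    origin pairs; long lags carry large, strongly correlated fluctuations
    that inflate the variance of the fitted slope without reducing its
    bias.
    """
    if traj.n_frames < 2:
        raise ValueError("MSD needs at least two frames")
    idx = traj.select(selection)
    x = traj.unwrapped()[:, idx, :]
    F = traj.n_frames
    if use_multiple_origins:
        per_atom = np.stack([_msd_fft(x[:, i, :]) for i in range(x.shape[1])])
        curve = per_atom.mean(axis=0)
    else:
        disp = x - x[0]
        curve = (disp**2).sum(axis=2).mean(axis=1)
    lags = np.arange(F) * traj.dt_ps
    lo, hi = fit_window
    t_lo, t_hi = lo * lags[-1], hi * lags[-1]
    mask = (lags >= t_lo) & (lags <= t_hi) & (lags > 0)
    if mask.sum() < 2:
        raise ValueError(
            f"fit window ({t_lo:g}, {t_hi:g}) ps selects fewer than 2 lags"
        )
    fit = stats.linregress(lags[mask], curve[mask])
    return MSDResult(
        lags_ps=lags,
        msd=curve,
        fit_window_ps=(float(t_lo), float(t_hi)),
        slope=float(fit.slope),
        diffusion=float(fit.slope) / 6.0,
        diffusion_stderr=float(fit.stderr) / 6.0,
    )


@dataclass
class DensityProfile:
    centers: np.ndarray                  # bin centres along the axis (angstrom)
    profiles: dict[str, np.ndarray]      # species -> relative concentration
    bin_width: float


def density_profile(
    traj: Trajectory,
    species: dict[str, object],
    axis: str = "z",
    bin_width: float = 1.0,
    region: tuple[float, float] | None = None,
    last_ps: float | None = None,
) -> DensityProfile:
    """Relative concentration of each species along a box axis.

    Counts per bin are normalised by the species' mean density over the
    analysis region, so a species that uniformly fills the region profiles
    at 1.  Only the trailing *last_ps* of the trajectory is analysed when
    given.
    """
    try:
        ax = "xyz".index(axis)
    except ValueError:
        raise ValueError("axis must be one of 'x', 'y', 'z'") from None
    frames = traj.trailing_frames(last_ps=last_ps)
    if region is None:
        region = (0.0, float(traj.box[frames][:, ax].max()))
    lo, hi = region
    if hi <= lo:
        raise ValueError("analysis region is empty")
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    profiles: dict[str, np.ndarray] = {}
    for name, sel in species.items():
        idx = traj.select(sel)
        z = traj.coords[frames][:, idx, ax].ravel()
        z = z[(z >= lo) & (z < edges[-1])]
        if z.size == 0:
            raise ValueError(f"species {name!r} has no atoms in the region")
        h, _ = np.histogram(z, bins=edges)
        mean_per_bin = z.size / n_bins
        profiles[name] = h / mean_per_bin
    centres = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers=centres, profiles=profiles, bin_width=bin_width)
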