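"""Attachment-energy arithmetic for solvent-modified growth morphology.

In vacuum the relative growth rate of a face scales with |E_att|.  In
solution the solvent adsorbed on a face must be displaced before a growth
slice can attach, which is accounted for by correcting the attachment
energy:

    E_int = E_tot - (E_cry + E_sol)                      [kcal/mol]
    E_s   = (Z_cry / Z_hkl) * (A_hkl / A_box) * E_int    [kcal/mol/unit cell]
    E'att = E_att - E_s                                  [kcal/mol/unit cell]

E_int is the slab-solvent interaction energy of the whole simulation box;
the conversion factor rescales it to one crystal-face cross-section of one
unit cell so that it is commensurate with E_att.  Z_cry is the number of
molecules in the unit cell, Z_hkl the number in the face slice cut from it,
A_hkl the face cross-section within the unit cell and A_box the lateral
cross-section of the simulation box (A_hkl/A_box is the reciprocal of the
number of unit-cell faces tiling the box).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lattice import Miller

__all__ = [
    "EnergyBreakdown",
    "MAERecord",
    "BoxSpec",
    "BoxSpecResult",
    "interaction_energy",
    "mean_interaction_energy",
    "solvent_correction",
    "modified_attachment",
    "mae_table",
    "growth_rate_ranking",
    "validate_box_spec",
]


def _finite(*vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise ValueError(f"energy inputs must be finite, got {v!r}")


def interaction_energy(e_tot: float, e_cry: float, e_sol: float) -> float:
    """Slab-solvent interaction energy E_int = E_tot - (E_cry + E_sol)."""
    _finite(e_tot, e_cry, e_sol)
    return e_tot - (e_cry + e_sol)


def mean_interaction_energy(
    e_tot: Sequence[float],
    e_cry: Sequence[float],
    e_sol: Sequence[float],
    last_n_frames: int | None = 100,
) -> float:
    """Average E_int over the trailing *last_n_frames* of per-frame energies."""
    tot, cry, sol = (np.asarray(x, dtype=float) for x in (e_tot, e_cry, e_sol))
    if not tot.shape == cry.shape == sol.shape:
        raise ValueError("per-frame energy series must have equal length")
    if not np.all(np.isfinite([tot, cry, sol])):
        raise ValueError("energy inputs must be finite")
    e_int = tot - (cry + sol)
    if last_n_frames is not None:
        e_int = e_int[-last_n_frames:]
    return float(e_int.mean())


def solvent_correction(
    e_int: float, z_cry: int, z_hkl: int, a_hkl: float, a_box: float
) -> float:
    """Solvent correction E_s = (Z_cry/Z_hkl) * (A_hkl/A_box) * E_int."""
    _finite(e_int)
    if z_hkl < 1 or z_cry < 1:
        raise ValueError("molecule counts Z_cry, Z_hkl must be >= 1")
    if a_box <= 0 or a_hkl <= 0:
        raise ValueError("areas must be positive")
    if a_hkl > a_box:
        raise ValueError("A_hkl cannot exceed the box cross-section A_box")
    return (z_cry / z_hkl) * (a_hkl / a_box) * e_int


def modified_attachment(e_att: float, e_s: float) -> float:
    """Modified attachment energy E'att = E_att - E_s."""
    _finite(e_att, e_s)
    return e_att - e_s


@dataclass(frozen=True)
class EnergyBreakdown:
    """Component energies of one slab-solvent system (kcal/mol)."""

    e_tot: float
    e_cry: float
    e_sol: float

    @property
    def e_int(self) -> float:
        return interaction_energy(self.e_tot, self.e_cry, self.e_sol)


@dataclass(frozen=True)
class MAERecord:
    """One face's full modified-attachment-energy bookkeeping."""

    face: Miller
    e_att: float
    z_cry: int
    z_hkl: int
    a_hkl: float
    a_box: float
    e_int: float
    e_s: float
    e_att_modified: float

    @classmethod
    def compute(
        cls,
        face: Sequence[int],
        e_att: float,
        z_cry: int,
        z_hkl: int,
        a_hkl: float,
        a_box: float,
        e_int: float,
    ) -> "MAERecord":
        e_s = solvent_correction(e_int, z_cry, z_hkl, a_hkl, a_box)
        return cls(
            face=tuple(int(i) for i in face),
            e_att=float(e_att),
            z_cry=int(z_cry),
            z_hkl=int(z_hkl),
            a_hkl=float(a_hkl),
            a_box=float(a_box),
            e_int=float(e_int),
            e_s=e_s,
            e_att_modified=modified_attachment(e_att, e_s),
        )


#: Column names used for tabular MAE input/output.
MAE_COLUMNS = ["face", "E_att", "Z_cry", "Z_hkl", "A_hkl", "A_box", "E_int"]


def mae_table(table: pd.DataFrame) -> pd.DataFrame:
    """Extend a table of per-face inputs with E_s and E'att columns.

    Expects columns ``face, E_att, Z_cry, Z_hkl, A_hkl, A_box, E_int``;
    ``face`` may be a string like ``"1 0 -1"`` or an index triple.
    """
    missing = [c for c in MAE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"MAE table is missing columns: {missing}")
    out = table.copy()
    e_s, e_mod = [], []
    for _, row in table.iterrows():
        rec = MAERecord.compute(
            face=_parse_face(row["face"]),
            e_att=row["E_att"], z_cry=row["Z_cry"], z_hkl=row["Z_hkl"],
            a_hkl=row["A_hkl"], a_box=row["A_box"], e_int=row["E_int"],
        )
        e_s.append(rec.e_s)
        e_mod.append(rec.e_att_modified)
    out["E_s"] = e_s
    out["E'att"] = e_mod
    return out


def _parse_face(face) -> Miller:
    if isinstance(face, str):
        parts = face.replace("(", "").replace(")", "").replace(",", " ").split()
        return tuple(int(p) for p in parts)  # type: ignore[return-value]
    return tuple(int(i) for i in face)  # type: ignore[return-value]


def growth_rate_ranking(
    faces: Sequence[Sequence[int]], energies: Sequence[float]
) -> list[tuple[Miller, float, bool]]:
    """Faces ordered fastest-growing first (descending |energy|).

    Returns (face, energy, tied) triples; ties keep input order and are
    flagged.  The most negative attachment energy grows fastest and has the
    least morphological importance.
    """
    if len(faces) == 0:
        raise ValueError("ranking needs at least one face")
    if len(faces) != len(energies):
        raise ValueError("faces and energies must have equal length")
    items = [(_parse_face(f), float(e)) for f, e in zip(faces, energies)]
    order = sorted(range(len(items)), key=lambda i: (-abs(items[i][1]), i))
    mags = [abs(items[i][1]) for i in order]
    out = []
    for pos, i in enumerate(order):
        tied = (pos > 0 and math.isclose(mags[pos], mags[pos - 1])) or (
            pos + 1 < len(order) and math.isclose(mags[pos], mags[pos + 1])
        )
        out.append((items[i][0], items[i][1], tied))
    return out


@dataclass(frozen=True)
class BoxSpec:
    """Geometry of a slab-solvent simulation box for one crystal face."""

    face: Miller
    lateral_lengths: tuple[float, float]  # box a, b (angstrom)
    slab_thickness: float                 # crystal-layer thickness T_c
    cutoff: float                         # non-bonded truncation radius d_c
    vacuum_pad: float                     # vacuum above the solvent layer
    replicas: tuple[int, int]             # face tiling of the box cross-section
    area_ratio: float                     # declared A_hkl / A_box


@dataclass
class BoxSpecResult:
    ok: bool
    violations: list[str]


def validate_box_spec(
    spec: BoxSpec, min_vacuum: float = 100.0, rel_tol: float = 1e-6
) -> BoxSpecResult:
    """Check the slab-box sizing rules.

    Lateral lengths must be at least twice the truncation radius, the slab
    at least one truncation radius thick, the vacuum pad at least
    *min_vacuum* (so the slab does not interact with its z-image), and the
    declared A_hkl/A_box must equal the reciprocal of the replica product.
    """
    v: list[str] = []
    a, b = spec.lateral_lengths
    if min(a, b, spec.slab_thickness, spec.cutoff) <= 0:
        raise ValueError("box dimensions must be positive")
    if a < 2 * spec.cutoff:
        v.append(f"lateral length a={a:g} < 2*d_c={2 * spec.cutoff:g}")
    if b < 2 * spec.cutoff:
        v.append(f"lateral length b={b:g} < 2*d_c={2 * spec.cutoff:g}")
    if spec.slab_thickness < spec.cutoff:
        v.append(f"slab thickness T_c={spec.slab_thickness:g} < d_c={spec.cutoff:g}")
    if spec.vacuum_pad < min_vacuum:
        v.append(f"vacuum pad {spec.vacuum_pad:g} < required {min_vacuum:g}")
    nrep = spec.replicas[0] * spec.replicas[1]
    if nrep < 1:
        raise ValueError("replica counts must be >= 1")
    if not math.isclose(spec.area_ratio, 1.0 / nrep, rel_tol=rel_tol):
        v.append(
            f"A_hkl/A_box={spec.area_ratio:g} inconsistent with "
            f"{spec.replicas[0]}x{spec.replicas[1]} replicas (expected {1.0 / nrep:g})"
        )
    return BoxSpecResult(ok=not v, violations=v)
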