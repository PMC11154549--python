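"""Readers, writers and run configuration.

Trajectory formats:

* **multi-frame XYZ** — per frame: atom count line, then a comment line of
  the form ``box: Lx Ly Lz [meta: {...json...}]``, then one
  ``label x y z`` line per atom.  The box comment is required.
* **PDB** — CRYST1 for the (orthorhombic) box, one MODEL per frame; read
  and written through biotite.

Unit-cell parameters can come from a config mapping or from the cell block
of a CIF file (via gemmi).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .lattice import UnitCell
from .trajectory import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
    "cell_from_cif",
    "load_config",
    "config_hash",
]


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write the package's multi-frame XYZ dialect (box in the comment)."""
    path = Path(path)
    meta_dict = dict(traj.metadata)
    # record which axes wrap so a reader reconstructs the same geometry
    meta_dict.setdefault("periodic", list(traj.periodic))
    meta = " meta: " + json.dumps(meta_dict, sort_keys=True)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            bx = traj.box[f]
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"box: {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}{meta}\n")
            for lab, (x, y, z) in zip(traj.labels, traj.coords[f]):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, dt_ps: float = 1.0,
             periodic: tuple[bool, bool, bool] | None = None) -> Trajectory:
    """Read the multi-frame XYZ dialect written by :func:`write_xyz`.

    Periodicity defaults to what the file's metadata recorded, falling back
    to slab geometry (x and y periodic) when absent; an explicit *periodic*
    argument overrides both.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames, boxes = [], []
    labels: list[str] | None = None
    metadata: dict = {}
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"frame {frame_no}: expected atom count, got "
                             f"{lines[i]!r}") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        if "box:" not in comment:
            raise ValueError(f"frame {frame_no}: missing 'box:' in comment line")
        after = comment.split("box:", 1)[1]
        if "meta:" in after:
            box_part, meta_part = after.split("meta:", 1)
            if not metadata:
                metadata = json.loads(meta_part)
        else:
            box_part = after
        boxes.append([float(v) for v in box_part.split()[:3]])
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"frame {frame_no}: expected {n} atoms, "
                             f"file ends after {len(body)}")
        labs, xyz = [], []
        for row in body:
            parts = row.split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame_no}: malformed atom line {row!r}")
            labs.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if labels is None:
            labels = labs
        elif labs != labels:
            raise ValueError(
                f"frame {frame_no}: atom labels/ordering differ from frame 0"
            )
        frames.append(xyz)
        i += 2 + n
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    if periodic is None:
        periodic = tuple(bool(b) for b in
                         metadata.get("periodic", (True, True, False)))
    return Trajectory(labels=np.array(labels), coords=np.array(frames),
                      box=np.array(boxes), dt_ps=dt_ps, periodic=periodic,
                      metadata=metadata)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write frames as PDB MODELs with a CRYST1 box record (via biotite)."""
    import biotite.structure as struc
    from biotite.structure.io import pdb as bpdb

    n = traj.n_atoms
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.coords[f].astype(np.float32)
        arr.atom_name = traj.labels
        arr.element = np.array([_element_guess(l) for l in traj.labels])
        arr.res_name = np.full(n, "MOL")
        arr.res_id = np.ones(n, dtype=int)
        arr.chain_id = np.full(n, "A")
        bx = traj.box[f]
        arr.box = np.diag(bx).astype(np.float32)
        arrays.append(arr)
    fh = bpdb.PDBFile()
    fh.set_structure(struc.stack(arrays))
    fh.write(str(path))


def _element_guess(label: str) -> str:
    head = "".join(c for c in label if c.isalpha())[:2].capitalize()
    from .sasa import VDW_RADII

    if head in VDW_RADII:
        return head
    return head[:1]


def read_pdb(path: str | Path, dt_ps: float = 1.0,
             periodic: tuple[bool, bool, bool] = (True, True, False)) -> Trajectory:
    """Read a (multi-MODEL) PDB with CRYST1 into a Trajectory (via biotite)."""
    from biotite.structure.io import pdb as bpdb

    fh = bpdb.PDBFile.read(str(path))
    stack = fh.get_structure()
    if stack.box is None:
        raise ValueError(f"{path}: missing CRYST1 box record")
    boxes = np.asarray(stack.box, dtype=float)
    off_diag = boxes - np.stack([np.diag(np.diag(b)) for b in boxes])
    if np.abs(off_diag).max() > 1e-3:
        raise ValueError(f"{path}: box is not orthorhombic")
    return Trajectory(
        labels=np.asarray(stack.atom_name, dtype=str),
        coords=np.asarray(stack.coord, dtype=float),
        box=np.stack([np.diag(b) for b in boxes]),
        dt_ps=dt_ps,
        periodic=periodic,
    )


def read_trajectory(path: str | Path, format: str | None = None,
                    dt_ps: float = 1.0,
                    periodic: tuple[bool, bool, bool] | None = None
                    ) -> Trajectory:
    """Dispatch on format ('xyz' or 'pdb'; inferred from the suffix)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz(path, dt_ps=dt_ps, periodic=periodic)
    if fmt == "pdb":
        return read_pdb(path, dt_ps=dt_ps,
                        periodic=periodic or (True, True, False))
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        write_xyz(traj, path)
    elif fmt == "pdb":
        write_pdb(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")


def cell_from_cif(path: str | Path) -> UnitCell:
    """Unit cell from the cell block of a CIF file."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    vals = {}
    for key, name in [("_cell_length_a", "a"), ("_cell_length_b", "b"),
                      ("_cell_length_c", "c"), ("_cell_angle_alpha", "alpha"),
                      ("_cell_angle_beta", "beta"), ("_cell_angle_gamma", "gamma")]:
        raw = block.find_value(key) or block.find_value(key.replace("_cell_", "_cell."))
        if raw is None:
            raise ValueError(f"{path}: missing CIF item {key}")
        vals[name] = gemmi.cif.as_number(raw)
    return UnitCell(**vals)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(path: str | Path, extra_paths: list[Path] | None = None) -> str:
    """SHA-256 over the config bytes and every referenced input file."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    for p in sorted(extra_paths or []):
        h.update(str(p).encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()
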