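"""End-to-end run: vacuum habit, per-solvent MAE and solvated habits,
then any configured trajectory estimators.

The run configuration is a YAML mapping::

    seed: 1
    cell: {a: 15.419, b: 15.419, c: 6.572, alpha: 90, beta: 90, gamma: 90}
    point_group: "4"
    forms:
      - {hkl: [1, 0, 0], e_att: -48.81, multiplicity: 4}
      - ...
    systems:
      ch2cl2:
        mae_table: table_ch2cl2.csv     # face, E_att, Z_cry, Z_hkl, A_hkl, A_box, E_int
        trajectory: slab.xyz            # optional
        dt_ps: 0.1
        rdf: {reference: H1, counted: Cl, r_max: 8.0}
        msd: {selection: Cl}
        density: {species: {CH2Cl2: Cl, C6H14: C6}, last_ps: 200}

Every stage writes CSV/JSON (and OFF meshes for habits) into the output
directory; a ``manifest.json`` records the package version, seed and a
SHA-256 hash of the config plus all referenced inputs, so reruns on the
same inputs are bit-identical apart from the output timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .energies import mae_table
from .io import config_hash, load_config, read_trajectory
from .lattice import FaceForm, UnitCell
from .morphology import build_habit, morphology_report
from .trajectory import density_profile, msd, rdf

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _forms_from_config(cell: UnitCell, forms_cfg, point_group: str,
                       energies: dict | None = None) -> list[FaceForm]:
    forms = []
    for item in forms_cfg:
        hkl = tuple(int(i) for i in item["hkl"])
        energy = energies[hkl] if energies is not None else item["e_att"]
        forms.append(FaceForm.from_cell(
            cell, hkl, energy, point_group=point_group,
            expected_multiplicity=item.get("multiplicity"),
        ))
    return forms


def _write_habit(cell, forms, outdir: Path, tag: str) -> dict:
    habit = build_habit(cell, forms)
    report = morphology_report(habit)
    (outdir / f"habit_{tag}.json").write_text(report.to_json() + "\n")
    (outdir / f"habit_{tag}.off").write_text(habit.to_off())
    return report.to_dict()


def run_pipeline(config_path: str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute every configured stage; returns the report bundle."""
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base = config_path.parent
    outdir = Path(output_dir or cfg.get("output_dir", "habit_out"))
    if not outdir.is_absolute():
        outdir = base / outdir
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    bundle: dict = {"systems": {}}
    referenced: list[Path] = []

    try:
        cell = (UnitCell.from_dict(cfg["cell"]) if "cell" in cfg
                else None)
        point_group = str(cfg.get("point_group", "1"))
    except Exception as exc:
        raise PipelineError("cell", exc) from exc

    if cell is not None and cfg.get("forms"):
        try:
            forms = _forms_from_config(cell, cfg["forms"], point_group)
            bundle["vacuum"] = _write_habit(cell, forms, outdir, "vacuum")
        except Exception as exc:
            raise PipelineError("vacuum-habit", exc) from exc

    for name, sys_cfg in (cfg.get("systems") or {}).items():
        sys_out: dict = {}
        if "mae_table" in sys_cfg:
            table_path = base / sys_cfg["mae_table"]
            referenced.append(table_path)
            try:
                table = mae_table(pd.read_csv(table_path))
                table.to_csv(outdir / f"mae_{name}.csv", index=False)
                sys_out["mae"] = table.to_dict(orient="records")
            except Exception as exc:
                raise PipelineError(f"mae:{name}", exc) from exc
            if cell is not None and cfg.get("forms"):
                try:
                    from .energies import _parse_face

                    energies = {_parse_face(r["face"]): r["E'att"]
                                for _, r in table.iterrows()}
                    forms = _forms_from_config(cell, cfg["forms"], point_group,
                                               energies=energies)
                    sys_out["habit"] = _write_habit(cell, forms, outdir, name)
                except Exception as exc:
                    raise PipelineError(f"habit:{name}", exc) from exc
        if "trajectory" in sys_cfg and sys_cfg["trajectory"]:
            traj_path = base / sys_cfg["trajectory"]
            referenced.append(traj_path)
            try:
                periodic = (tuple(bool(b) for b in sys_cfg["periodic"])
                            if "periodic" in sys_cfg else None)
                traj = read_trajectory(traj_path,
                                       dt_ps=float(sys_cfg.get("dt_ps", 1.0)),
                                       periodic=periodic)
            except Exception as exc:
                raise PipelineError(f"trajectory:{name}", exc) from exc
            if "rdf" in sys_cfg:
                try:
                    rc = sys_cfg["rdf"]
                    res = rdf(traj, rc["reference"], rc["counted"],
                              r_max=float(rc["r_max"]),
                              bin_width=float(rc.get("bin_width", 0.05)))
                    pd.DataFrame({"r": res.r, "g": res.g}).to_csv(
                        outdir / f"rdf_{name}.csv", index=False)
                    sys_out["rdf_peak"] = res.peak_position()
                except Exception as exc:
                    raise PipelineError(f"rdf:{name}", exc) from exc
            if "msd" in sys_cfg:
                try:
                    mc = sys_cfg["msd"]
                    res = msd(traj, mc["selection"])
                    pd.DataFrame({"lag_ps": res.lags_ps, "msd": res.msd}).to_csv(
                        outdir / f"msd_{name}.csv", index=False)
                    sys_out["diffusion_1e-8_m2_s"] = res.diffusion
                except Exception as exc:
                    raise PipelineError(f"msd:{name}", exc) from exc
            if "density" in sys_cfg:
                try:
                    dc = sys_cfg["density"]
                    res = density_profile(
                        traj, dc["species"],
                        axis=dc.get("axis", "z"),
                        bin_width=float(dc.get("bin_width", 1.0)),
                        last_ps=dc.get("last_ps"),
                    )
                    df = pd.DataFrame({"z": res.centers, **res.profiles})
                    df.to_csv(outdir / f"density_{name}.csv", index=False)
                    sys_out["density_species"] = list(res.profiles)
                except Exception as exc:
                    raise PipelineError(f"density:{name}", exc) from exc
        bundle["systems"][name] = sys_out

    manifest = {
        "package": "crystalhabit",
        "version": __version__,
        "seed": seed,
        "config": str(config_path),
        "config_hash": config_hash(config_path, referenced),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle
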