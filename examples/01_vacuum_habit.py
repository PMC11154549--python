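"""Vacuum growth morphology of ISMN from attachment energies.

Builds the Wulff-type growth polyhedron for the six tabulated face forms
(facet distance proportional to |E_att|, point group 4) and prints the
per-form facet area percentages and shape descriptors.  Large percentages
mark slow-growing, morphologically important faces; the aspect ratio ~3.9
is the needle-like elongation along c that makes the compound awkward to
process.
"""

from pathlib import Path

from crystalhabit import FaceForm, UnitCell, build_habit, morphology_report
from crystalhabit.io import load_config

cfg = load_config(Path(__file__).parent / "data" / "ismn" / "vacuum_forms.yaml")
cell = UnitCell.from_dict(cfg["cell"])
forms = [
    FaceForm.from_cell(cell, f["hkl"], f["e_att"], point_group=cfg["point_group"],
                       expected_multiplicity=f["multiplicity"])
    for f in cfg["forms"]
]

report = morphology_report(build_habit(cell, forms))
print("form    d_hkl(A)  E_att      area %")
for form in forms:
    hkl = form.representative
    print(f"({hkl[0]} {hkl[1]} {hkl[2]:2d})  {form.d_hkl:7.2f}  {form.energy:8.2f}"
          f"  {report.area_fractions[hkl]:6.2f}")
print(f"aspect ratio            {report.aspect_ratio:.3f}")
print(f"relative surface/volume {report.relative_surface_to_volume:.3f}")
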