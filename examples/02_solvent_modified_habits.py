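"""Solvent-modified attachment energies and the habits they predict.

Takes the tabulated slab-solvent interaction energies for the pure CH2Cl2
and mixed CH2Cl2-C6H14 systems, applies the E_s conversion
(E_s = (Z_cry/Z_hkl)(A_hkl/A_box) E_int) and E'att = E_att - E_s, and
rebuilds the growth habit from the corrected energies.  Watch the face
list: solvent adsorption removes the fast-growing oblique faces in the
pure solvent, and the antisolvent brings (1 1 -1) back.
"""

from pathlib import Path

import pandas as pd

from crystalhabit import (
    FaceForm,
    UnitCell,
    build_habit,
    mae_table,
    morphology_report,
)

DATA = Path(__file__).parent / "data" / "ismn"
cell = UnitCell(a=15.419, b=15.419, c=6.572)

for name, csv in [("CH2Cl2", "mae_ch2cl2.csv"),
                  ("CH2Cl2-C6H14", "mae_ch2cl2_c6h14.csv")]:
    table = mae_table(pd.read_csv(DATA / csv))
    print(f"\n== {name} ==")
    print(table[["face", "E_att", "E_int", "E_s", "E'att"]]
          .round(2).to_string(index=False))
    forms = [FaceForm.from_cell(cell, tuple(int(i) for i in f.split()), e, "4")
             for f, e in zip(table["face"], table["E'att"])]
    report = morphology_report(build_habit(cell, forms))
    fr = {f"({k[0]} {k[1]} {k[2]})": round(v, 2)
          for k, v in report.area_fractions.items()}
    print("area %:", fr)
    print("morphologically important:",
          [f"({m[0]} {m[1]} {m[2]})" for m in report.present])
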