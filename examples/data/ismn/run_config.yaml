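# Full ISMN run from tabulated inputs: vacuum habit, then modified
# attachment energies and solvated habits for the CH2Cl2 and
# CH2Cl2-C6H14 solvent systems.
seed: 1
output_dir: ../../../scratch/ismn_out
cell: {a: 15.419, b: 15.419, c: 6.572, alpha: 90.0, beta: 90.0, gamma: 90.0}
point_group: "4"
forms:
  - {hkl: [1, 0, 0], e_att: -48.81, multiplicity: 4}
  - {hkl: [1, 1, 0], e_att: -61.87, multiplicity: 4}
  - {hkl: [1, 0, 1], e_att: -177.07, multiplicity: 4}
  - {hkl: [1, 0, -1], e_att: -177.07, multiplicity: 4}
  - {hkl: [1, 1, 1], e_att: -170.28, multiplicity: 4}
  - {hkl: [1, 1, -1], e_att: -170.28, multiplicity: 4}
systems:
  ch2cl2:
    mae_table: mae_ch2cl2.csv
  ch2cl2_c6h14:
    mae_table: mae_ch2cl2_c6h14.csv
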