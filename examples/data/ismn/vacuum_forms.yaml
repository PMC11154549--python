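# ISMN (isosorbide mononitrate) force-field-optimized tetragonal cell and the
# six morphologically important growth forms with vacuum attachment energies
# (kcal/mol/unit cell).  Point group "4": the proper rotations of P4_3.
cell: {a: 15.419, b: 15.419, c: 6.572, alpha: 90.0, beta: 90.0, gamma: 90.0}
point_group: "4"
forms:
  - {hkl: [1, 0, 0], e_att: -48.81, multiplicity: 4}
  - {hkl: [1, 1, 0], e_att: -61.87, multiplicity: 4}
  - {hkl: [1, 0, 1], e_att: -177.07, multiplicity: 4}
  - {hkl: [1, 0, -1], e_att: -177.07, multiplicity: 4}
  - {hkl: [1, 1, 1], e_att: -170.28, multiplicity: 4}
  - {hkl: [1, 1, -1], e_att: -170.28, multiplicity: 4}
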