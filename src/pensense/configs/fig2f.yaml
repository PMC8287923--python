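# Inverted (activating, ultrasensitive) L-trp sensing via pskT_TrpR.
name: fig2f
templates:
  - {name: aT, role: aT, concentration: 50.0}
  - {name: pT, role: pT, concentration: 4.0}
  - {name: rT, role: rT, concentration: 10.0}
  - {name: sT, role: sT, concentration: 0.008}
  - {name: pskT_TrpR, role: pskT, concentration: 10.0, operator: TrpR}
tfs:
  - name: TrpR
    dimer_concentration: 210.0
    operator_kd: 0.02
    ligand: L-trp
    ligand_kd: 20.0
    ligand_hill: 2.0
    mode: corepressor
ligands:
  L-trp: 0.0
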