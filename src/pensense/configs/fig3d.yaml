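# Two-input classifier: L-trp direct, IPTG through the killer template.
# Weight signs (-IPTG, -L-trp).
name: fig3d
templates:
  - {name: aT, role: aT, concentration: 50.0}
  - {name: pT, role: pT, concentration: 1.0}
  - {name: rT, role: rT, concentration: 10.0}
  - {name: psT_TrpR, role: psT, concentration: 0.063, operator: TrpR}
  - {name: pskT_LacI, role: pskT, concentration: 40.0, operator: LacI}
tfs:
  - name: LacI
    dimer_concentration: 110.0
    operator_kd: 0.04
    ligand: IPTG
    ligand_kd: 23.0
    ligand_hill: 1.0
    mode: inducer
    induction_fold: 1.0e4
  - name: TrpR
    dimer_concentration: 210.0
    operator_kd: 0.02
    ligand: L-trp
    ligand_kd: 20.0
    ligand_hill: 2.0
    mode: corepressor
ligands:
  IPTG: 0.0
  L-trp: 0.0
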