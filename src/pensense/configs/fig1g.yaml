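# IPTG induction of the LacI-repressed switch (psT 2.5 nM): direct sensing.
name: fig1g
templates:
  - {name: aT, role: aT, concentration: 50.0}
  - {name: pT, role: pT, concentration: 7.0}
  - {name: rT, role: rT, concentration: 10.0}
  - {name: psT_LacI, role: psT, concentration: 2.5, operator: LacI}
tfs:
  - name: LacI
    dimer_concentration: 110.0
    operator_kd: 0.04
    ligand: IPTG
    ligand_kd: 23.0
    ligand_hill: 1.0
    mode: inducer
    induction_fold: 1.0e4
ligands:
  IPTG: 0.0
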