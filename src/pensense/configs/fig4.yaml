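# In-situ metabolic sensing: tryptophan synthase B converts indole +
# L-serine to L-trp, which activates the inverted TrpR switch. The assay
# uses more reporter (50 nM) and boosted polymerase/nickase, reflected in
# a higher autocatalytic rate.
name: fig4
templates:
  - {name: aT, role: aT, concentration: 50.0}
  - {name: pT, role: pT, concentration: 5.0}
  - {name: rT, role: rT, concentration: 50.0}
  - {name: sT, role: sT, concentration: 2.5}
  - {name: pskT_TrpR, role: pskT, concentration: 10.0, operator: TrpR}
tfs:
  - name: TrpR
    dimer_concentration: 50.0
    operator_kd: 0.02
    ligand: L-trp
    ligand_kd: 20.0
    ligand_hill: 2.0
    mode: corepressor
enzymes:
  - name: EcB
    concentration: 0.01
    kcat: 60.0
    km_indole: 300.0
    km_serine: 1.0
    product: L-trp
ligands:
  L-trp: 0.0
  indole: 5000.0
  serine: 10.0
rates:
  k_amp: 0.072
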