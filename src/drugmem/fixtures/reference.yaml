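# Reference simulation conditions, one fixture per drug and membrane system.
# Spectra-band parameters, grids and noise calibration live in code
# (drugmem.synthdata); each entry only names the drug/system pair and the
# assay conditions that differ between systems.  Leakage plateaus follow the
# reported 5-20% release range; cardiolipin-containing stacks carry a broad
# diffuse vesicle background.

nap-popc:
  drug: NAP
  system: "POPC"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.12, ec50: 150.0e-6}
  saxs:
    peaks: [[1.00, 0.05, 100.0], [2.00, 0.08, 30.0]]
    baseline: 10.0

nap-popc-chol:
  drug: NAP
  system: "POPC:CHOL (80:20)"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.08, ec50: 180.0e-6}
  saxs:
    peaks: [[0.97, 0.04, 90.0], [1.04, 0.05, 60.0], [1.97, 0.08, 20.0]]
    baseline: 10.0

nap-popc-tmcl:
  drug: NAP
  system: "POPC:TMCL (85:15)"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.15, ec50: 150.0e-6}
  saxs:
    peaks: [[0.95, 0.06, 40.0]]
    diffuse: [1.2, 1.0, 25.0]
    baseline: 10.0

nap-popc-pi:
  drug: NAP
  system: "POPC:PI (85:15)"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.20, ec50: 120.0e-6}
  saxs:
    peaks: [[1.02, 0.05, 80.0], [2.04, 0.09, 25.0]]
    baseline: 10.0

dic-popc:
  drug: DIC
  system: "POPC"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.10, ec50: 150.0e-6}
  saxs:
    peaks: [[1.00, 0.05, 100.0], [2.00, 0.08, 30.0]]
    baseline: 10.0

dic-popc-chol:
  drug: DIC
  system: "POPC:CHOL (80:20)"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.10, ec50: 140.0e-6}
  saxs:
    peaks: [[0.99, 0.035, 110.0], [1.98, 0.06, 35.0]]
    baseline: 10.0

dic-popc-tmcl:
  drug: DIC
  system: "POPC:TMCL (85:15)"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.15, ec50: 160.0e-6}
  saxs:
    peaks: [[0.96, 0.05, 45.0]]
    diffuse: [1.2, 1.0, 25.0]
    baseline: 10.0

dic-popc-pi:
  drug: DIC
  system: "POPC:PI (85:15)"
  noise_frac: 0.02
  leakage: {lipid_conc: 1.0e-3, leak_max: 0.12, ec50: 150.0e-6}
  saxs:
    peaks: [[1.01, 0.05, 85.0], [2.02, 0.08, 28.0]]
    baseline: 10.0
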