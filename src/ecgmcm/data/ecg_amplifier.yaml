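# Reference configuration: two-stage ECG amplifier front-end.
# Voltages in mV; resistances in kOhm except R9 (MOhm); C1 in uF, C2 in nF.
# The 'ecg' equation is vout = (1 + 2*R1/R2)*(R5/R4) * (1 + R11/R8)
#                              * (vin_plus - vin_minus + baseline + noise);
# block 'frequency_only' quantities shape the corner frequencies
# f1 = 1/(2*pi*C1*R9) and f2 = 1/(2*pi*C2*R11) but never the static output.
name: ecg_amplifier
equation: ecg
seed: 12345
coverage: 0.95

quantities:
  - {name: vin_plus,  group: measurand,        block: input,         nominal: 0.30,   unit: mV,
     pdf: {family: normal, mu: 0.30, sigma: 0.04}}
  - {name: vin_minus, group: measurand,        block: input,         nominal: 0.00,   unit: mV,
     pdf: {family: normal, mu: 0.00, sigma: 0.04}}
  - {name: baseline,  group: measurand,        block: input,         nominal: 3.00,   unit: mV,
     pdf: {family: normal, mu: 3.00, sigma: 0.01}}
  - {name: R1,        group: measuring_system, block: preamplifier,  nominal: 22.00,  unit: kOhm,
     pdf: {family: rectangular, a: 21.78, b: 22.22}}
  - {name: R2,        group: measuring_system, block: preamplifier,  nominal: 10.00,  unit: kOhm,
     pdf: {family: rectangular, a: 9.90, b: 10.10}}
  - {name: R4,        group: measuring_system, block: preamplifier,  nominal: 10.00,  unit: kOhm,
     pdf: {family: rectangular, a: 9.90, b: 10.10}}
  - {name: R5,        group: measuring_system, block: preamplifier,  nominal: 47.00,  unit: kOhm,
     pdf: {family: rectangular, a: 46.53, b: 47.47}}
  - {name: R8,        group: measuring_system, block: final_stage,   nominal: 5.00,   unit: kOhm,
     pdf: {family: rectangular, a: 4.95, b: 5.05}}
  - {name: R11,       group: measuring_system, block: final_stage,   nominal: 150.00, unit: kOhm,
     pdf: {family: rectangular, a: 148.50, b: 151.50}}
  - {name: R9,        group: measuring_system, block: frequency_only, nominal: 3.30,  unit: MOhm,
     pdf: {family: rectangular, a: 3.267, b: 3.333}}
  - {name: C1,        group: measuring_system, block: frequency_only, nominal: 1.00,  unit: uF,
     pdf: {family: u_shaped, a: 0.99, b: 1.01}}
  - {name: C2,        group: measuring_system, block: frequency_only, nominal: 10.00, unit: nF,
     pdf: {family: u_shaped, a: 9.90, b: 10.10}}
  - {name: noise,     group: environment,      block: input,         nominal: 0.00,   unit: mV,
     pdf: {family: normal, mu: 0.00, sigma: 0.01}}

grouping:
  vin: [vin_plus, vin_minus]
  Baseline: [baseline]
  Preamplifier: [R1, R2, R4, R5]
  Final stage: [R8, R11]
  Noise: [noise]

# Design variants: swap the named resistors for 0.1% precision parts.
variants:
  preamp_0p1:
    tolerance: {R1: 0.001, R2: 0.001, R4: 0.001, R5: 0.001}
  all_resistors_0p1:
    tolerance: {R1: 0.001, R2: 0.001, R4: 0.001, R5: 0.001, R8: 0.001, R11: 0.001}

output:
  dir: reports
  formats: [csv, json]
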