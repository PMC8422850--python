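# Diestrus-stage single-compartment model parameters.
label: diestrus
Cm_pF: 17.62
VT_mV: 26.21
Ihold_pA: 0.0
leak: {g_nS: 1.06, E_mV: -70.0}
conductances:
  - name: slow
    gbar_nS: 37.4
    E_mV: -92.0
    law: GHK
    c_out_mM: 3.5
    r: 1
    m:
      V50: -1.70
      K: -7.73
      tau: {form: DOUBLE_SIGMOID, A: 1.40, B: 1.54, C: 15.81, D: -0.27, E: 8.67, F: 2.89, G: 8.50}
    h:
      - V50: -43.84
        K: 8.41
        weight: 1.0
        tau: {form: DOUBLE_SIGMOID, A: 64.50, B: 1401.00, C: 59.70, D: -6.42, E: 1.34, F: -8.26, G: 1.82}
  - name: fast
    gbar_nS: 36.9
    E_mV: -92.0
    law: GHK
    c_out_mM: 3.5
    r: 1
    m:
      V50: -19.22
      K: -7.84
      tau: {form: SINGLE_SIGMOID, A: 0.53, B: 0.00, C: -8.68, D: 7.88}
    h:
      - V50: -57.95
        K: 6.33
        weight: 0.5
        tau: {form: CONSTANT, fixed_value: 14.55}
      - V50: -57.95
        K: 6.33
        weight: 0.5
        tau: {form: CONSTANT, fixed_value: 113.55}
  - name: resid
    gbar_nS: 29.7
    E_mV: -92.0
    law: GHK
    c_out_mM: 3.5
    r: 1
    m:
      V50: -5.54
      K: -8.85
      tau: {form: DOUBLE_SIGMOID, A: 0.93, B: 16.39, C: 44.02, D: -0.33, E: 0.13, F: -6.77, G: 7.76}
    h:
      - V50: -39.16
        K: 11.29
        weight: 1.0
        tau: {form: DOUBLE_SIGMOID, A: 64.50, B: 1401.65, C: 59.77, D: -6.42, E: 1.34, F: -8.26, G: 1.82}
  - name: NaP
    gbar_nS: 0.14
    E_mV: 50.0
    law: OHMIC
    r: 1
    m:
      V50: 50.45
      K: -3.72
      sign_convention: V_PLUS_V50
      tau: {form: CONSTANT, fixed_value: 0.40}
    h:
      - V50: 31.84
        K: 3.20
        sign_convention: V_PLUS_V50
        weight: 1.0
        tau: {form: BELL, A: 67.30, B: -27.50, C: 67.30, D: 27.50, E: 4650.15, F: 62.48}
  - name: CaT
    gbar_nS: 1.60
    E_mV: 155.0
    law: OHMIC
    r: 2
    m:
      V50: -55.61
      K: -5.45
      tau: {form: SINGLE_SIGMOID, A: 1.85, B: 1.65, C: -60.60, D: 5.00}
    h:
      - V50: -76.02
        K: 10.90
        weight: 1.0
        tau: {form: SINGLE_SIGMOID, A: 15.58, B: 70.15, C: -57.66, D: 3.61}
  - name: h
    gbar_nS: 0.11
    E_mV: -19.9
    law: OHMIC
    r: 1
    m:
      V50: -97.55
      K: 4.19
      tau: {form: SINGLE_SIGMOID, A: 201.00, B: 0.00, C: -2.20, D: -5.95}
    h: []
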