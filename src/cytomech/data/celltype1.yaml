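# Reference chondrocyte-like material set ("cell type 1").
# Units are encoded in the key names: E_MPa, D1_perMPa, tau_*_s.
# C10/D1 are the tabulated Neo-Hookean pairs; they are cross-checked on load
# against the pair derived from (E_MPa, nu) within 1% relative.
label: cell type 1
materials:
  cytoplasm:
    E_MPa: 1.28e-03
    nu: 0.37
    C10_MPa: 2.33e-04
    D1_perMPa: 1.22e+03
    E_R_MPa: 4.50e-04
    tau_sigma_s: 19.7
    tau_epsilon_s: 9.5
  microtubule:
    E_MPa: 1.53e+04
    nu: 0.38
    C10_MPa: 2.78e+03
    D1_perMPa: 9.39e-05
  microfilament:
    E_MPa: 3.32e+04
    nu: 0.38
    C10_MPa: 6.02e+03
    D1_perMPa: 4.33e-05
  membrane:
    E_MPa: 1.28e-02
    nu: 0.3
    C10_MPa: 2.46e-03
    D1_perMPa: 1.88e+02
  nucleus:
    E_MPa: 5.11e-03
    nu: 0.37
    C10_MPa: 9.33e-04
    D1_perMPa: 3.05e+02
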