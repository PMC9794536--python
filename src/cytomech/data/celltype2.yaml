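# Softer reference material set ("cell type 2"): cytoplasm one order of
# magnitude below cell type 1, cytoskeleton/membrane/nucleus scaled down by
# the same ratio Q = 12.78.  Same SLS relaxation times as cell type 1.
label: cell type 2
materials:
  cytoplasm:
    E_MPa: 1.00e-04
    nu: 0.37
    C10_MPa: 1.83e-05
    D1_perMPa: 1.56e+04
    E_R_MPa: 4.50e-04
    tau_sigma_s: 19.7
    tau_epsilon_s: 9.5
  microtubule:
    E_MPa: 1.20e+03
    nu: 0.38
    C10_MPa: 2.17e+02
    D1_perMPa: 1.20e-03
  microfilament:
    E_MPa: 2.60e+03
    nu: 0.38
    C10_MPa: 4.71e+02
    D1_perMPa: 5.54e-04
  membrane:
    E_MPa: 1.00e-03
    nu: 0.3
    C10_MPa: 1.92e-04
    D1_perMPa: 2.40e+03
  nucleus:
    E_MPa: 4.00e-04
    nu: 0.37
    C10_MPa: 7.30e-05
    D1_perMPa: 3.90e+03
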