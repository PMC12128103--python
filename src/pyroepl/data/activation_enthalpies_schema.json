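{
  "description": "Standard activation enthalpies (kcal/mol) of 30 pyrolysis reactions of three functionalized xylopyranoses at five levels of theory and two temperatures.",
  "columns": {
    "reactant": "reactant species name",
    "product": "product label (acyclic sugar, furanic FF/FFL channel, or anhydro AXP/AXPL channel)",
    "leaving": "leaving molecule: H2O, CH3COOH, CH3OH, or none",
    "dft_0": "M06-2X/6-311++G(d,p), 0 K",
    "cbs_0": "CBS-QB3, 0 K",
    "g4_0": "G4, 0 K",
    "dlpno_0": "DLPNO-CCSD(T)-F12/cc-pVTZ-F12//M06-2X/6-311++G(d,p), 0 K",
    "dlpnocbs_0": "DLPNO with two-point CBS extrapolation (cc-pVDZ/cc-pVTZ), 0 K",
    "dft_298": "M06-2X/6-311++G(d,p), 298 K",
    "cbs_298": "CBS-QB3, 298 K",
    "g4_298": "G4, 298 K",
    "dlpno_298": "DLPNO-CCSD(T)-F12, 298 K",
    "dlpnocbs_298": "DLPNO/CBS, 298 K"
  },
  "cell_markers": {
    "a": "suffix: transition state located under relaxed SCF convergence criteria; excluded from model fitting",
    "-": "barrier not available (transition state never converged at any level)"
  },
  "units": "kcal/mol"
}
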