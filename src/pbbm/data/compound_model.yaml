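# Model input parameters of the studied compound (a BCS IV zwitterion)
# and its absorption/dissolution/elimination configuration.  Keys mirror
# the tabulated input-parameter labels of the source datasets.

compound:
  name: GSK254
  mol_weight: 727.07
  logP: 5.49
  pKa1: 4.63
  pKa2: 8.65
  intrinsic_solubility: 0.00015   # mg/mL, fitted to clinical data
  fu: 0.14
  b_p: 0.53
  fu_gut: 0.226                   # carried; no gut-wall metabolism modelled

absorption:
  effective_concentration_for_permeation: total
  include_ion_transcellular_permeation: false
  paracellular_scalar: 0.00039
  ptrans0_reported_1e6_cm_s: 4565.23   # platform value; recomputed from logP
  peff_regional_1e4_cm_s:
    duodenum: 0.13
    jejunum_I: 0.14
    jejunum_II: 0.095
    ileum_I: 0.037
    ileum_II: 0.037
    ileum_III: 0.037
    ileum_IV: 0.035
    colon: 0.015
  colon_absorption_scalar: 0.001

dissolution:
  psd:
    d10_um: 3.2
    d50_um: 8.1
    d90_um: 23.1
    density_g_mL: 1.2
    n_bins: 50
  heff_cutoff_um: 30
  precipitation:
    model: first-order
    prc_per_h: 0.0001
    csr: 1000.0
    reference: unbound-unionised

partition_siva:                    # platform-fitted constants (provenance
  logk_neutral: 0.019              # only; this package refits its own)
  logk_ion: 4.559

distribution:
  vss_l_per_kg: 0.34

elimination:
  clint:
    - {pathway: CYP3A4, value: 0.003, units: uL/min/pmol}
    - {pathway: UGT1A4, value: 0.009, units: uL/min/pmol}
    - {pathway: UGT2B7, value: 0.007, units: uL/min/pmol}
    - {pathway: additional_HLM, value: 0.354, units: uL/min/mg}
    - {pathway: biliary, value: 0.111, units: uL/min/1e6cells}
  cl_renal_l_h: 0.020
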