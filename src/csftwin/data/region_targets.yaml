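# Regional calibration targets for the NHP CSF geometry fixture.
# Spinal rows and cranial compartments carry CSF volume, dura-contact surface
# area, CNS-tissue-contact surface area and (spine only) cord+rootlet tissue
# volume. Totals are always recomputed as sums of constituents.
spinal:
  lumbar:      {csf_volume_mL: 3.60, dura_sa_cm2: 42.0, cns_sa_cm2: 11.9, rootlet_volume_cm3: 1.4}
  thoracic:    {csf_volume_mL: 2.75, dura_sa_cm2: 36.4, cns_sa_cm2: 23.4, rootlet_volume_cm3: 1.9}
  cervical:    {csf_volume_mL: 1.45, dura_sa_cm2: 16.4, cns_sa_cm2: 11.7, rootlet_volume_cm3: 0.6}
cranial:
  left_hemisphere:  {csf_volume_mL: 2.79, dura_sa_cm2: 38.9, cns_sa_cm2: 37.7}
  right_hemisphere: {csf_volume_mL: 3.13, dura_sa_cm2: 41.3, cns_sa_cm2: 38.8}
  cerebellum:       {csf_volume_mL: 0.39, dura_sa_cm2: 7.2,  cns_sa_cm2: 7.2}
  basal_cisterns:   {csf_volume_mL: 1.59, dura_sa_cm2: 8.9,  cns_sa_cm2: 16.4}
  ventricular:      {csf_volume_mL: 0.53, dura_sa_cm2: 0.0,  cns_sa_cm2: 11.2}
# Separately printed spinal rootlet surface areas (cm^2); stored independently
# of the CNS-contact column because the printed text is ambiguous about
# whether the 47.0 cm^2 spinal CNS figure already includes them.
rootlet_sa_cm2: {cervical: 4.3, thoracic: 10.5, lumbar: 7.8}
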