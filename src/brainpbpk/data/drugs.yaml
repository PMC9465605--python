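# Drug-specific parameters for the three non-binding tool antibodies.
# sigma values are the fitted barrier reflection coefficients (dimensionless),
# k_deg the endosomal degradation rate (1/h), recovery the in-vitro
# microdialysis probe recovery (fraction), lloq_ng_ml the ELISA lower limit
# of quantification. None of the three antibodies cross-reacts with rat
# targets, so disposition is linear apart from FcRn binding.
EGFRvIII-TCB:
  MW: 195000.0          # g/mol (2+1 T-cell bispecific format)
  sigma_BBB: 0.9853
  sigma_BCSFB: 0.9767
  sigma_CSF_ISF: 0.9994
  k_deg: 82.4
  recovery: 0.14
  lloq_ng_ml: 2.5
DP47-IgG:
  MW: 143000.0          # g/mol (1+1 IgG format)
  sigma_BBB: 0.9919
  sigma_BCSFB: 0.9865
  sigma_CSF_ISF: 0.9994  # fixed to the EGFRvIII-TCB estimate (IV-only design)
  k_deg: 27.3
  recovery: 0.10
  lloq_ng_ml: 1.4
DP47-TCB:
  MW: 195000.0
  sigma_BBB: 0.9946
  sigma_BCSFB: 0.9855
  sigma_CSF_ISF: 0.9994  # fixed to the EGFRvIII-TCB estimate (IV-only design)
  k_deg: 7.76
  recovery: 0.10
  lloq_ng_ml: 1.4
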