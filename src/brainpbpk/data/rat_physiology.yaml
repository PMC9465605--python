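# Fixed rat physiological constants for the reduced brain PBPK model.
# Volumes in L, flows in L/h, concentrations in nM, rates in 1/h.
# Serum (plasma) volume derived from body-weight-corrected blood volume
# (310 g rat, hematocrit 0.45); CSF/ISF volumes and flows from the full
# rat brain PBPK literature; rest-of-body endosomal/FcRn constants from
# the minimal-PBPK antibody disposition lineage.
V_plasma: 0.0067        # L, serum/plasma
V_lymph: 0.0011         # L, lymph
V_tissue_vasc: 0.0079   # L, rest-of-body vascular plasma
V_tissue_endo: 0.0013   # L, rest-of-body endosomal space
V_tissue_isf: 0.0483    # L, rest-of-body interstitial fluid
V_brain_vasc: 5.02e-5   # L, brain vascular plasma
V_brain_isf: 4.1e-4     # L, brain interstitial fluid
V_LV: 5.0e-5            # L, both lateral ventricles
V_TFV: 5.0e-5           # L, third + fourth ventricles
V_CM: 1.7e-5            # L, cisterna magna (CSF sampling site)
V_SAS: 1.8e-4           # L, subarachnoid space
Q_t: 2.88               # L/h, rest-of-body blood (plasma) flow
Q_b: 0.0653             # L/h, brain blood (plasma) flow
L_t: 0.0058             # L/h, tissue lymph flow
L_b: 1.62e-4            # L/h, brain lymph flow = Q_CSF + Q_ISF
Q_CSF: 1.32e-4          # L/h, CSF production/circulation flow
Q_ISF: 3.0e-5           # L/h, brain ISF production flow
sigma_TV: 0.9212        # -, vascular reflection, tissue vasc -> tissue ISF
sigma_TL: 0.2           # -, lymphatic reflection, tissue ISF -> lymph
sigma_BISF: 0.2         # -, reflection on outflow from brain ISF
sigma_CSF: 0.2          # -, reflection on outflow from SAS
FcRn_SS: 49800.0        # nM, steady-state endosomal FcRn concentration
FR: 0.715               # -, fraction of FcRn-bound antibody recycled to plasma side
k_CLupT: 0.55           # 1/h, endosomal uptake rate (tissue)
k_on_FcRn: 0.8          # 1/(nM*h), FcRn association rate constant
k_off_FcRn: 144.0       # 1/h, FcRn dissociation rate
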