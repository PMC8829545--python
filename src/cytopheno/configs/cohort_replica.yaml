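# Default synthetic cohort: 19 subjects in three clinical groups
# (5 controllers, 8 acute-treated, 6 chronic-treated), paired blood and
# lymph-node compartments, the 42-marker panel, and 8 latent T/NK
# populations with bimodal marker profiles on the arcsinh scale
# (negative 0.3, positive 3.5; CD56 dim 2.5 / bright 5.0; per-marker SD
# 0.35). Planted effects: acute-treated enrichment of naive-like CD8 T
# and Tfh-like CD4 T cells, chronic-treated depletion of naive CD4 T
# cells, and LN-vs-blood shifts (more Tfh and CD56-bright NK, fewer
# activated effector CD8 and CD56-dim NK in LN).
markers: &markers
  [CD3, CD4, CD8, CD19, CD14, CD33, CD7, CD45RO, CD45RA, CCR7, CD27,
   CD62L, CD28, CD95, CD127, CD25, CXCR5, PD1, ICOS, OX40, CD69, CD38,
   HLADR, CD57, KLRG1, TCF1, Ki67, CTLA4, TIGIT, CCR6, CXCR4, CD161,
   CD56, CD16, CD94, NKG2A, NKG2C, NKG2D, KIR2DL1, DNAM1, NKp46, NKp30]
groups: [controller, acute, chronic]
subjects_per_group: {controller: 5, acute: 8, chronic: 6}
cells_per_subject: 5000
subject_sd: 0.3
compartments: [blood, LN]
seed: 0
populations:
  - name: CD4_Tn
    base_logit: 1.2
    sd: 0.35
    mean: {default: 0.3, CD3: 3.5, CD4: 3.5, CD7: 3.5, CD45RA: 3.5,
           CCR7: 3.5, CD27: 3.5, CD62L: 3.5, CD28: 3.5, TCF1: 3.5, CD127: 3.5}
  - name: CD4_Tcm
    base_logit: 1.0
    sd: 0.35
    mean: {default: 0.3, CD3: 3.5, CD4: 3.5, CD7: 3.5, CD45RO: 3.5,
           CCR7: 3.5, CD27: 3.5, CD62L: 3.5, CD127: 3.5, CD28: 3.5, CD95: 3.5}
  - name: CD4_Tfh
    base_logit: 0.2
    sd: 0.35
    mean: {default: 0.3, CD3: 3.5, CD4: 3.5, CD7: 3.5, CD45RO: 3.5,
           CD27: 3.5, CXCR5: 3.5, PD1: 3.5, CD69: 3.5, ICOS: 3.5, CD127: 3.5}
  - name: CD4_Treg
    base_logit: 0.0
    sd: 0.35
    mean: {default: 0.3, CD3: 3.5, CD4: 3.5, CD7: 3.5, CD45RO: 3.5,
           CD27: 3.5, CD25: 3.5, CTLA4: 3.5, Ki67: 3.5}
  - name: CD8_Tn
    base_logit: 0.8
    sd: 0.35
    mean: {default: 0.3, CD3: 3.5, CD8: 3.5, CD7: 3.5, CD45RA: 3.5,
           CCR7: 3.5, CD27: 3.5, CD62L: 3.5, CD28: 3.5, TCF1: 3.5}
  - name: CD8_Tem_act
    base_logit: 0.6
    sd: 0.35
    mean: {default: 0.3, CD3: 3.5, CD8: 3.5, CD7: 3.5, CD45RO: 3.5,
           CD38: 3.5, HLADR: 3.5, CD95: 3.5, KLRG1: 3.5, CD57: 3.5}
  - name: NK_bright
    base_logit: -0.5
    sd: 0.35
    mean: {default: 0.3, CD7: 3.5, CD56: 5.0, TCF1: 3.5, CD94: 3.5,
           NKG2A: 3.5, NKG2D: 3.5, NKp46: 3.5, NKp30: 3.5, DNAM1: 3.5,
           CCR7: 3.5, CD62L: 3.5}
  - name: NK_dim
    base_logit: 0.5
    sd: 0.35
    mean: {default: 0.3, CD7: 3.5, CD56: 2.5, CD16: 3.5, CD57: 3.5,
           KIR2DL1: 3.5, NKG2D: 3.5, NKp46: 3.5}
enrichment:
  acute: {CD8_Tn: 1.0, CD4_Tfh: 0.8}
  chronic: {CD4_Tn: -0.8}
compartment_shift:
  LN: {CD4_Tfh: 1.5, NK_bright: 1.2, CD8_Tem_act: -1.0, NK_dim: -0.8}
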