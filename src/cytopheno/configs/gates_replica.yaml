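# Canonical T/NK gating hierarchy on the arcsinh scale.
#
# Thresholds are dataset-specific by nature (manual gates); the defaults
# here are midpoints between the synthetic archetype levels (negative
# 0.3, positive 3.5; CD56 dim 2.5, bright 5.0). For real data, edit the
# thresholds block. Sign atoms: `M+` is value >= threshold, `M-` is
# value < threshold. Interval atoms have a closed lower, open upper
# bound, so boundary values fall in the higher stratum.
#
# Tdp/Tdn are the remaining CD45RO x CD45RA quadrants, included so the
# declared quadrant partitions are exhaustive of the parent.
thresholds:
  default: 1.9
gates:
  - {name: T, parent: root, atoms: [CD19-, CD14-, CD33-, CD3+]}
  - {name: CD4_T, parent: T, atoms: [CD8-]}
  - {name: CD4_Tn, parent: CD4_T, atoms: [CD45RO-, CD45RA+]}
  - {name: CD4_Tm, parent: CD4_T, atoms: [CD45RO+, CD45RA-]}
  - {name: CD4_Tdp, parent: CD4_T, atoms: [CD45RO+, CD45RA+]}
  - {name: CD4_Tdn, parent: CD4_T, atoms: [CD45RO-, CD45RA-]}
  - {name: CD4_Tcm, parent: CD4_Tm, atoms: [CCR7+, CD27+]}
  - {name: CD4_Tem, parent: CD4_Tm, atoms: [CCR7-, CD27-]}
  - {name: CD4_Tfh, parent: CD4_Tm, atoms: [CXCR5+, PD1+]}
  - {name: CD4_Treg, parent: CD4_Tm, atoms: [CD25+, CD127-]}
  - {name: CD4_Trm, parent: CD4_T, atoms: [CD45RO+, CD69+]}
  - {name: CD4_activated, parent: CD4_T, atoms: [CD38+, HLADR+]}
  - {name: CD8_T, parent: T, atoms: [CD8+]}
  - {name: CD8_Tn, parent: CD8_T, atoms: [CD45RO-, CD45RA+]}
  - {name: CD8_Tm, parent: CD8_T, atoms: [CD45RO+, CD45RA-]}
  - {name: CD8_Tdp, parent: CD8_T, atoms: [CD45RO+, CD45RA+]}
  - {name: CD8_Tdn, parent: CD8_T, atoms: [CD45RO-, CD45RA-]}
  - {name: CD8_Tcm, parent: CD8_Tm, atoms: [CCR7+, CD27+]}
  - {name: CD8_Tem, parent: CD8_Tm, atoms: [CCR7-, CD27-]}
  - {name: CD8_Trm, parent: CD8_T, atoms: [CD45RO+, CD69+]}
  - {name: CD8_activated, parent: CD8_T, atoms: [CD38+, HLADR+]}
  - {name: CD8_Tm_CXCR5pos, parent: CD8_Tm, atoms: [CXCR5+]}
  - {name: CD8_Trm_CXCR5pos, parent: CD8_Trm, atoms: [CXCR5+]}
  - {name: NK, parent: root, atoms: [CD19-, CD14-, CD33-, CD3-, CD4-, CD7+]}
  - {name: NK_CD56bright, parent: NK, atoms: ["CD56 in [3.75, inf)"]}
  - {name: NK_CD56dim, parent: NK, atoms: ["CD56 in [1.4, 3.75)"]}
  - {name: NK_CD56neg, parent: NK, atoms: ["CD56 in [-inf, 1.4)"]}
  - {name: NK_CD56neg_CD16pos, parent: NK_CD56neg, atoms: [CD16+]}
  - {name: NK_CD56neg_CD16neg, parent: NK_CD56neg, atoms: [CD16-]}
  - {name: NK_bright_TCF1pos, parent: NK_CD56bright, atoms: [TCF1+]}
  - {name: NK_dim_TCF1neg, parent: NK_CD56dim, atoms: [TCF1-]}
partitions:
  - {gates: [CD4_Tn, CD4_Tm, CD4_Tdp, CD4_Tdn], exhaustive: true}
  - {gates: [CD8_Tn, CD8_Tm, CD8_Tdp, CD8_Tdn], exhaustive: true}
  - {gates: [NK_CD56bright, NK_CD56dim, NK_CD56neg], exhaustive: true}
  - {gates: [NK_CD56neg_CD16pos, NK_CD56neg_CD16neg], exhaustive: true}
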