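# 42-marker T/NK immunophenotyping panel. Clustering uses 39 channels:
# the B-cell/monocyte dump markers CD19, CD14 and CD33 serve only the
# upstream lineage gates and are excluded from clustering features.
markers:
  - CD3
  - CD4
  - CD8
  - CD19
  - CD14
  - CD33
  - CD7
  - CD45RO
  - CD45RA
  - CCR7
  - CD27
  - CD62L
  - CD28
  - CD95
  - CD127
  - CD25
  - CXCR5
  - PD1
  - ICOS
  - OX40
  - CD69
  - CD38
  - HLADR
  - CD57
  - KLRG1
  - TCF1
  - Ki67
  - CTLA4
  - TIGIT
  - CCR6
  - CXCR4
  - CD161
  - CD56
  - CD16
  - CD94
  - NKG2A
  - NKG2C
  - NKG2D
  - KIR2DL1
  - DNAM1
  - NKp46
  - NKp30
clustering_markers:
  exclude: [CD19, CD14, CD33]
gating_markers:
  - CD3
  - CD4
  - CD8
  - CD19
  - CD14
  - CD33
  - CD7
  - CD45RO
  - CD45RA
  - CCR7
  - CD27
  - CXCR5
  - PD1
  - CD25
  - CD127
  - CD69
  - CD38
  - HLADR
  - CD56
  - CD16
  - TCF1
cofactor: 5.0
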