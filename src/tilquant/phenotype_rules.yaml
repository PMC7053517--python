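hi_threshold: 0.5
lo_threshold: -0.1
rules:
- phenotype: Treg
  high:
  - CD3
  - CD4
  - FOXP3
  low: []
  priority: 0
  hi_override: null
  lo_override: null
- phenotype: Tcy
  high:
  - CD3
  - CD8
  low: []
  priority: 1
  hi_override: null
  lo_override: null
- phenotype: Th
  high:
  - CD3
  - CD4
  low:
  - FOXP3
  priority: 2
  hi_override: null
  lo_override: 0.2
- phenotype: Tfh
  high:
  - CXCL13
  - PD-1
  low: []
  priority: 3
  hi_override: null
  lo_override: null
- phenotype: BC
  high:
  - CD20
  low: []
  priority: 4
  hi_override: null
  lo_override: null
- phenotype: PC
  high:
  - IRF4
  - Blimp1
  low:
  - CD20
  priority: 5
  hi_override: null
  lo_override: null
- phenotype: Melanoma
  high:
  - S100AB
  - MelanA
  low: []
  priority: 6
  hi_override: null
  lo_override: null
- phenotype: Melanoma
  high:
  - S100AB
  low:
  - MelanA
  priority: 7
  hi_override: null
  lo_override: null
- phenotype: Melanoma
  high:
  - MelanA
  low:
  - S100AB
  priority: 8
  hi_override: null
  lo_override: null
- phenotype: Macroph
  high:
  - CD68
  - Lysozyme
  low: []
  priority: 9
  hi_override: null
  lo_override: null
- phenotype: cDC1
  high:
  - CD141
  - IRF8
  low: []
  priority: 10
  hi_override: null
  lo_override: null
- phenotype: cDC2
  high:
  - CD1c
  - HLA-DR
  low:
  - CD3
  - CD20
  priority: 11
  hi_override: null
  lo_override: null
- phenotype: Lang
  high:
  - CD1a
  - Langerin
  low: []
  priority: 12
  hi_override: null
  lo_override: null
- phenotype: pDC
  high:
  - CD123
  low: []
  priority: 13
  hi_override: null
  lo_override: null
- phenotype: NK
  high:
  - CD56
  low:
  - CD3
  priority: 14
  hi_override: null
  lo_override: null
- phenotype: LV
  high:
  - Podoplanin
  low: []
  priority: 15
  hi_override: null
  lo_override: null
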