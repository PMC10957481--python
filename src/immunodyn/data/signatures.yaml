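# Gene signatures shipped as editable data.
#
# "TIS" is the published 18-gene tumor inflammation signature capturing an
# IFN-gamma-responsive, antigen-presentation-competent, T-cell-inflamed
# microenvironment. Edit or extend freely; all scoring treats these as data.
TIS:
  - CCL5
  - CD27
  - CD274
  - CD276
  - CD8A
  - CMKLR1
  - CXCL9
  - CXCR6
  - HLA-DQA1
  - HLA-DRB1
  - HLA-E
  - IDO1
  - LAG3
  - NKG7
  - PDCD1LG2
  - PSMB10
  - STAT1
  - TIGIT
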