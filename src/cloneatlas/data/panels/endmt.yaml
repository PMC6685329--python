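# Endothelial-to-mesenchymal transition (EndMT) signature panel.
# Reconstructed panel: the five markers named in the primary report
# (Icam1, Vcam1, Vim, Fn1, Smtn) plus canonical early (regulatory /
# intermediate-state) and late (mesenchymal / ECM) EndMT markers.
name: endmt
genes:
  - Snai1: early
  - Snai2: early
  - Twist1: early
  - Zeb1: early
  - Zeb2: early
  - Icam1: early
  - Vcam1: early
  - Vim: early
  - Cdh2: early
  - S100a4: late
  - Acta2: late
  - Tagln: late
  - Cnn1: late
  - Fn1: late
  - Col1a1: late
  - Col3a1: late
  - Postn: late
  - Smtn: late
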