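{
  "tumor": ["EPCAM", "CEACAM5"],
  "immune": ["PTPRC", "CD3D", "CD8A", "MS4A1"],
  "stromal": ["COL1A1"],
  "endothelial": ["PECAM1"]
}
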