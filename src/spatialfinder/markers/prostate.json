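{
  "tumor": ["AMACR", "KLK3"],
  "basal_epithelial": ["KRT5"],
  "luminal_epithelial": ["KRT8"]
}
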