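{
  "wt": "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA",
  "variants": ["A2T", "D7N", "E22G", "E22Q", "D23N", "G25P"]
}
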