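{
  "slope": 0.00042,
  "intercept": -0.017,
  "r": 0.8,
  "n": 25,
  "index": "delta_L",
  "note": "Published gloss-to-moisture regression: moisture_mg = 4.2e-4 * gloss_degree - 0.017, fitted to 25 subjects (12 normal, 13 dry), Pearson r = 0.80."
}
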