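{
  "ob_min": 30.0,
  "dl_min": 0.18,
  "hl_min": 4.0,
  "hl_max": 8.0
}
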