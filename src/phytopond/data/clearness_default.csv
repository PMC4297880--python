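latitude_deg,clearness
0.0,0.52
20.0,0.48
35.0,0.55
55.0,0.45
65.0,0.5
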