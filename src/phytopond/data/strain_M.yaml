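Um: 1.04
NCmin: 0.055
NCmax: 0.15
PCmin: 0.002
PCmax: 0.02
KQN: 10.0
KQP: 0.1
ChlCmax: 0.06
ChlC_floor: 0.015
alpha_chl: 0.45
KsN: 0.03
KsP: 0.005
Vscale: 3.0
r_basal: 0.05
r_growth: 0.2
Pq_surge: 1.25
hCex: 0.3
h_uptake: 0.5
kChl: null
name: M
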