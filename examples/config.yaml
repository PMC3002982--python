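model:
  profiles:
    - path: bcd.pfm
      name: bcd
    - path: hb.pfm
      name: hb
  pseudocount: 0.1
  delta: 0.1        # expected fraction of residues inside binding sites
  mu: 0.08          # site death rate per unit branch length
  alpha: 0.02       # gap-open rate
  beta: 0.55        # gap extension probability
  epsilon: 1.0e-5
  c_indel: 1.0
  c_branch: 1.0
  background:
    exchangeabilities: [0.9, 2.2, 0.7, 1.0, 2.5, 1.0]
    equilibrium: [0.3, 0.2, 0.2, 0.3]
run:
  seed: 7
  log_level: INFO
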