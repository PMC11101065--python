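# Demonstration pipeline config: the default class-conditional feature
# distributions at reduced sample sizes, feature-level simulation (no
# image rendering), 7:3 split, selection at alpha=0.05, 200-replicate
# bootstrap for the AUC confidence intervals.
benign:
  n: 509
malignant:
  n: 2214
seed: 11
pipeline:
  n_boot: 200
  dca_step: 0.02
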