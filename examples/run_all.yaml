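# End-to-end demo configuration: a small simulated genome with planted
# tandem arrays, then metrics -> paralogs -> tandem -> enrichment.
seed: 11
simulate:
  n_scaffolds: 4
  genes_per_scaffold: [40, 60]
  n_families: 12
  family_size: [2, 4]
alpha: 1.0e-4
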