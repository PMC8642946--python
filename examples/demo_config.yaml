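seed: 7
simulation:
  n_proteins: 250
  n_genes: 400
  n_variant_pairs: 80
  n_reference_proteins: 40
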