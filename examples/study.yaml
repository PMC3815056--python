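# Two-strain simulated mapping study at study-shaped defaults:
# ~100 random spores per cross, 14 markers on chromosome 3 and 10 on
# chromosome 8, nondisjunction/death rates per strain.
out_dir: sporemap_out
seed: 1
strains:
  wildtype:
    simulate:
      strain: wildtype
      n_meioses: 25
  nbs1-2:
    simulate:
      strain: nbs1-2
      n_meioses: 25
analysis:
  B: 2000
  n_boot: 1000
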