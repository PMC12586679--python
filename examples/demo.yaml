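# Demo-scale end-to-end run on a synthetic community with planted structure.
# Thresholds omitted here fall back to the standard defaults (spacer
# mismatches 2; homology ANI 90 / AF 50 / prophage AF 80; clustering 95/85;
# presence 5x / 0.5 / 0.7; popANI 99.9; 1000 nulls; 10,000 permutations).
seed: 42
n_null: 1000
mantel_permutations: 2000
min_bees: 10          # demo has 20 samples; the field default of 15 suits 49
synthetic:
  n_samples: 20
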