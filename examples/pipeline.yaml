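# End-to-end pipeline config: a 640-head herd with two low-frequency InDels
# (mutant-allele frequencies 5.2% and 0.9%), full coupling (D' = 1) between
# the two mutant alleles, and one female-restricted carcass trait
# parameterized from reported per-genotype moments.
seed: 1
herd:
  n_individuals: 640
  sex_counts: {male: 172, female: 466, missing: 2}
  d_prime: 1.0
  loci:
    - {name: P1-Ins-4-bp, mutant_allele: I, mutant_freq: 0.052}
    - {name: P2-Del-8-bp, mutant_allele: D, mutant_freq: 0.009}
  traits:
    - name: beef_shoulder
      locus: P1-Ins-4-bp
      sex: female
      genotypes:
        ID: {mean: 1.30, se: 0.10, n: 29}
        DD: {mean: 1.02, se: 0.02, n: 163}
pooling:
  P1-Ins-4-bp: {carrier_freq: 0.02, n_max: 64}
  P2-Del-8-bp: {carrier_freq: 0.01, n_max: 64}
association:
  by_sex: true
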