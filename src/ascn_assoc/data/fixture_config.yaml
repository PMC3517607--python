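# ascn-assoc packaged fixture: small synthetic cohort (16 samples, ~350 probes)
# Deterministic stand-in for a discovery cohort; coordinates are synthetic.
n_samples: 16
chrom_lengths:
  "7": 8000000
  "9": 6000000
  X: 3000000
probe_spacing: 50000
probes_per_planted_locus: 10
variant_id: rs17172430
variant_chrom: "7"
variant_pos: 2100000
maf: 0.14
risk_allele_is_major: true
fixed_group_sizes: [11, 5]
frac_tetraploid: 0.25
planted:
  - name: EGFR_like
    chrom: "7"
    start: 2000000
    end: 2200000
    event: LOH
    p_risk: 0.55
    p_other: 0.1
  - name: CDKN2AB_like
    chrom: "9"
    start: 1000000
    end: 1040000
    event: HD
    p_risk: 0.6
    p_other: 0.2
co_occur: 0.0
background_rate_per_mb: 0.03
background_mean_length: 500000.0
background_states:
  - {nA: 0, nB: 1, weight: 0.35}
  - {nA: 1, nB: 2, weight: 0.30}
  - {nA: 0, nB: 2, weight: 0.15}
  - {nA: 2, nB: 2, weight: 0.10}
  - {nA: 0, nB: 0, weight: 0.05}
  - {nA: 4, nB: 4, weight: 0.05}
missing_rate: 0.01
sample_prefix: S
seed: 20120
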