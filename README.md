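# ascn-assoc

Do inherited risk alleles shape which somatic copy-number lesions a tumor
acquires? `ascn-assoc` is a reusable pipeline for testing that question in
glioma-style cohorts: it links **germline genotypes at published risk
variants** (EGFR, CDKN2A/B, TERT, RTEL1, ...) to **somatic allele-specific
copy-number (ASCN) events** — loss of heterozygosity, homozygous deletion,
amplification — called from the per-probe output of an ASCAT-style caller.

It is written for statistical geneticists and cancer-genomics analysts who
have per-sample ASCN profiles (allele-specific copy numbers `nA`, `nB` per
SNP-array probe, plus a tumor-ploidy estimate) and germline genotype calls,
and want a reproducible discovery + independent-validation analysis.

## The method

1. **Ploidy normalization.** Samples with ASCAT ploidy > 2.8 are classed
   tetraploid-like (whole-genome duplicated) and their copy numbers are
   halved, so a balanced tetraploid genome reads as (1, 1) like a normal
   diploid one.
2. **Event calculus.** Each probe is assigned to every event type whose
   predicate holds on the rescaled values, with `nTot = nA + nB`:
   Normal `nA=1 ∧ nB=1`; Loss `nTot<2`; increased copy number (ICN)
   `nTot>2`; LOH `nA=0 ∨ nB=0`; copy-number-neutral event (CNNE)
   `nA≠1 ∧ nB≠1 ∧ nTot=2`; homozygous deletion (HD) `nTot=0`;
   amplification `nTot≥8`; simultaneous LOH and ICN `(nA=0 ∨ nB=0) ∧ nTot>2`.
3. **Recurrence cutoff.** Per event, every sample's autosomal calls are
   permuted across probe positions (100 repetitions); the event-frequency
   cutoff is the mean of the per-repetition 99.5th-percentile null
   frequencies (false-positive rate 0.5%).
4. **Genotype association (global route).** Samples split into
   major-allele homozygotes vs heterozygotes + rare homozygotes (a
   surrogate marker in LD substitutes for unassayed variants); at every
   probe where the risk-allele group's frequency exceeds the cutoff, a
   one-sided Fisher's exact test asks whether that group has more events.
   Genome-wide significance comes from 100 random relabelings of the
   groups: the p cutoff is set so 95% of the per-relabeling minimum
   p-values lie above it (familywise 5%).
5. **Genes-of-interest route.** For 27 glioma-relevant genes, a sample is
   event-positive when > 50% of the locus probes carry the event; each
   (gene, event, variant) 2×2 table is Fisher-tested at α = 0.05.
6. **Validation.** Every shortlisted region is re-tested with the
   gene-level method on an independent cohort; regions with ≤ 2 probes on
   the validation array are untestable.

A first-class synthetic-data generator (`ascn_assoc.simulate`) emulates the
caller's output contract — Hardy–Weinberg genotypes, a diploid/tetraploid
ploidy mixture, segmental background aberrations and planted
genotype-conditional events with a truth table — so the whole pipeline is
testable without patient data.

## Worked example

```python
from ascn_assoc import EventType, fisher_one_sided, run_discovery
from ascn_assoc.io import load_fixture_config_path
from ascn_assoc.simulate import load_sim_config, simulate_cohort

# A published 2x2 table: 60 risk-allele carriers (19 with EGFR LOH)
# vs 21 others (2 with LOH)
p = fisher_one_sided(19, 41, 2, 19)
print(f"one-sided Fisher p = {p:.4f}")

# Discovery on the packaged synthetic cohort (16 samples, ~350 probes)
cfg = load_sim_config(load_fixture_config_path())
sim = simulate_cohort(cfg, seed=11)
report = run_discovery(
    sim.profiles, sim.genotypes, sim.manifest, [sim.variant], sim.regions,
    events=[EventType.HD], seed=11,
)
print("frequency cutoff (HD):", round(report.freq_cutoffs[EventType.HD], 3))
cols = ["approach", "variant_id", "name", "event", "a", "b", "c", "d", "p"]
print(report.shortlist[cols].to_string(index=False))
```

prints

```
one-sided Fisher p = 0.0385
frequency cutoff (HD): 0.094
approach variant_id      name event  a  b  c  d        p
     GOI rs17172430 EGFR_like  LOSS  8  3  0  5 0.012821
     GOI rs17172430 EGFR_like   LOH  8  3  0  5 0.012821
```

The 0.0385 is the exact upper-tail hypergeometric probability that the
risk group shows at least 19 of the 21 events under fixed margins. In the
synthetic run, the planted LOH effect at the EGFR-like locus is shortlisted
by the genes-of-interest route (8 of 11 risk-group samples positive vs 0 of
5 others; LOSS co-triggers because the planted LOH state is a hemizygous
deletion); at 16 samples the global route's genome-wide cutoff is not
cleared, which is the expected behavior at this toy size.

The same stages are scriptable from a shell:

```sh
ascn-assoc simulate --out-dir sim/ --seed 11
ascn-assoc discover --profiles sim/profiles.tsv --genotypes sim/genotypes.tsv \
    --manifest sim/manifest.tsv --regions sim/regions.tsv \
    --variants variants.tsv --seed 11 --out-dir disc/
ascn-assoc validate --shortlist disc/shortlist.tsv ... --out-dir val/
ascn-assoc report --validation val/validation.tsv
```

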