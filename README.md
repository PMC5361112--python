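# paleomito

Ancient-DNA (aDNA) mitogenome processing: a tested, reusable implementation of
the bespoke computational steps needed to turn pooled, barcoded, mapped aDNA
reads into clade-assigned consensus mitochondrial genomes — plus a read
simulator with complete ground truth so every stage can be validated without
real specimens.

It is aimed at palaeogenomicists and methods developers who work with
capture-enriched, non-UDG-treated libraries of short (~30–150 bp) fragments,
where three artefacts dominate: terminal cytosine deamination (C→T at the 5′
end, complementary G→A at the 3′ end), heavy PCR duplication, and barcode
bleeding (index hopping) between samples pooled in one capture reaction.

## The pipeline

1. **Quality/length filter** — keep reads ≥ 30 bp with at most five bases
   below Phred 10.
2. **Barcode-bleed de-multiplexing** — group reads by exact alignment
   coordinates (*coordinate clusters*, presumed PCR copies of one molecule);
   discard clusters observed fewer than 3 times; assign each remaining
   cluster wholesale to its strictly most frequent barcode, discarding it on
   a tie.
3. **Duplicate collapse** — one consensus sequence per coordinate cluster
   (per-column majority, quality tie-break, N on residual ties).
4. **Two-tier consensus calling** from the per-site pileup of unique reads,
   with depth *d* and majority-base frequency *f* at each site:
   - *relaxed*: call iff d ≥ 3 and f > 1/3; genome included iff ≤ 33% N;
   - *strict*: call iff d ≥ 10 and f > 0.90; genome included iff ≤ 20% missing.
   All other sites are N (never ambiguity codes). Strict calls are provably a
   subset of relaxed calls.
5. **Partitioning** — extract annotated features, reverse-complement
   reverse-strand genes, and concatenate into the four blocks used in
   mitogenome phylogenetics (protein-coding, control region, tRNA, rRNA),
   written as per-category FASTA and a NEXUS file with `charset` lines.
6. **Clade assignment** — p-distances with pairwise deletion, a Saitou–Nei
   neighbor-joining tree (exact on additive matrices), bootstrap support from
   100 column-resampled replicates, and assignment of each query to the clade
   of the smallest supported group that contains it with uniformly labeled
   references.

The simulator (`paleomito.simulate`) generates annotated circular references,
sample haplotypes at an exact Hamming distance, and barcoded read sets with
truncated-normal fragment lengths, geometric-decay terminal deamination,
sequencing error, shared-coordinate PCR duplicates and barcode bleeding —
returning a truth record for every emitted read copy.

## Worked example

```python
from paleomito import (SimulationParams, generate_reference, process_batch,
                       simulate_batch)
from paleomito.pipeline import consensus_accuracy

ref = generate_reference(2000, n_features_per_category=1, seed=7)
params = SimulationParams(coverage=30, damage_rate=0.1, error_rate=0.002,
                          duplication_rate=2.0, bleed_rate=0.02)
batch = simulate_batch(ref, n_samples=3, n_substitutions=25, params=params, seed=1)
result = process_batch(batch.pooled_reads, ref.length)
print(f"pooled read copies: {len(batch.pooled_reads)}")
print(f"clusters discarded (size/tie): {result.discarded_clusters}")
for bc, s in result.samples.items():
    strict, relaxed = s.genomes["strict"], s.genomes["relaxed"]
    m, c = consensus_accuracy(strict.sequence, batch.haplotypes[bc])
    print(f"{bc}: {s.n_clusters} unique molecules | strict called {c} sites, "
          f"identity {100*m/c:.2f}% | relaxed called {relaxed.n_called}")
```

prints

```
pooled read copies: 8820
clusters discarded (size/tie): 1206
S1: 555 unique molecules | strict called 1941 sites, identity 100.00% | relaxed called 1992
S2: 577 unique molecules | strict called 1838 sites, identity 100.00% | relaxed called 1993
S3: 563 unique molecules | strict called 1929 sites, identity 100.00% | relaxed called 1983
```

i.e. at 30× coverage with 10% terminal damage, the conservative filters
discard the singleton/tied clusters, the strict consensus reproduces each
true haplotype perfectly at ~95% of sites, and the relaxed consensus calls
slightly more sites at the same accuracy. Every stage is also available as a
CLI subcommand (`paleomito simulate|demux|dedup|call|partition|assign`).

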