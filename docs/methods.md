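# Methods

## Scope and assumptions

`paleomito` operates downstream of mapping and upstream of phylogenetic
dating. It assumes single-end (post-merge) reads already aligned to a single
circular mitochondrial reference, a substitution-only world (no indels, so a
read's columns line up with the reference by offset from its start and all
consensus genomes are reference-length and column-compatible without multiple
sequence alignment), and a haploid target (no diploid genotypes, no
heteroplasmy model). Adapter trimming, mapping, model selection and Bayesian
dating are out of scope; the NEXUS output with `charset` blocks is the
hand-off to dating tools.

## The de-multiplexing model

Reads sharing exact (start, end) alignment coordinates are treated as PCR
copies of one original molecule (a *coordinate cluster*). Barcode bleeding
moves individual read copies between samples but cannot move the underlying
molecule, so the cluster's barcode majority identifies the true sample far
more reliably than any single copy's barcode. The filter therefore:

1. drops reads shorter than 30 bp or with more than five bases below Phred
   10 (the quality filter runs *before* clustering, so rejected reads never
   count toward cluster occurrence);
2. drops clusters observed fewer than `min_cluster_occurrence = 3` times;
3. assigns each remaining cluster wholesale to its strictly most frequent
   barcode, counted within the cluster across the pooled batch, and drops
   clusters whose maximum is tied — within-cluster counting is the only
   reading under which the tie rule is meaningful.

Minority-barcode members of a retained cluster are presumed bleed copies of
the winner's molecule; by default they are kept and reassigned (they collapse
into the same consensus read at dedup), with a `minority=drop` option. On
simulated batches (duplication ≥ 2 extra copies, bleed ≤ 10%) cluster-level
assignment measurably beats trusting per-read barcodes, which the test suite
asserts against the simulation truth.

Barcode error-correction (Hamming-distance rescue of corrupted barcodes) is
deliberately not implemented; bleeding is modeled as wholesale reassignment.

## Duplicate collapse

Each cluster collapses to one consensus read: per column, the majority base
over the copies (member N bases abstain); ties broken toward the larger
summed Phred quality among the tied bases; an N where the tie persists. This
is the minimal deterministic completion of "one consensus sequence per
coordinate pair" — majority voting is the obvious rule, the quality tie-break
uses the only other per-base evidence available, and N propagates residual
ambiguity to the consensus caller whose thresholds are designed to absorb it.
The consensus read carries a support count but no per-base qualities:
downstream calling counts unique reads, not quality-weighted evidence.
Whether a quality-weighted or representative-read rule would differ
materially is untested; at realistic error rates the majority rule dominates.

## Consensus calling

Per-site pileups count A/C/G/T over unique reads (read N bases contribute to
neither counts nor depth). A site is called under a policy iff

* depth ≥ `min_depth`,
* exactly one base attains the maximum count, and
* that count / depth **strictly exceeds** `majority_fraction`.

Policies: relaxed = (3, 1/3) with inclusion at ≤ 33% N; strict = (10, 9/10)
with inclusion at ≤ 20% missing. "Higher than 33%" is implemented as > 1/3
exactly (one-in-three shorthand), "more than 90%" as > 9/10; both bounds are
stored as `fractions.Fraction` and compared by cross-multiplication so that
boundary pileups (1 of 3, 9 of 10, 18 of 20) are decided exactly, never by
floating-point luck. Inclusion bounds are inclusive ("no more than") and are
taken over the full reference length, uncovered sites counting as N. Since
(d ≥ 10 ∧ f > 0.9) ⇒ (d ≥ 3 ∧ f > 1/3) and the sole-maximum condition is
shared, every strict call equals the relaxed call at that site; the suite
verifies this exhaustively for all 46,376 count vectors of depth ≤ 30.

No damage-aware probabilistic genotyper is attempted: the two-policy design
*is* the damage control — deaminated bases are diluted below the majority
bounds by coverage, and sites where they are not are masked as N.

## Partitioning

Features carry one of four categories (protein_coding, control_region, tRNA,
rRNA), a strand and 0-based half-open coordinates. Extraction
reverse-complements reverse-strand genes (N complements to N); blocks
concatenate a category's features in ascending reference-start order — the
simplest deterministic order, phylogenetically equivalent to any other. A
single feature with `end <= start` is interpreted as wrapping the origin of
the circular genome (extracted as suffix + prefix, flagged in the coordinate
map); inter-genic sites belonging to no feature are dropped. Codon-position
splitting of protein-coding genes is left to the downstream modeling tool.

## Distances, neighbor joining, clade assignment

Distances are uncorrected p-distances with pairwise deletion: for each pair,
only sites where both sequences have A/C/G/T are compared, and a pair with
zero comparable sites is an error naming the pair. p-distance is the minimal
assumption and adequate at intraspecific divergence; a Jukes–Cantor
correction (−3/4·ln(1 − 4p/3)) is available behind `model="jc"`.

Neighbor joining follows the Saitou–Nei recurrences: minimise
Q(i,j) = (m−2)·d(i,j) − r(i) − r(j), join, update
d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2. Ties in Q are broken by the
lexicographically smallest taxon pair (each internal node keyed by the
smallest leaf label beneath it), making the tree invariant to input order.
Negative branch-length estimates are clamped to zero with the deficit
transferred to the sibling branch (standard practice), counted on the tree
object. On additive matrices the algorithm is exact; the test suite verifies
topology and path-length recovery against an independent oracle that
enumerates all unrooted topologies and least-squares-fits each.

Bootstrap support resamples alignment columns with replacement, rebuilds
distances and the NJ tree per replicate, and scores each internal edge of the
full-data tree by the percentage of replicates containing the same
bipartition (canonicalised as the side not holding the first taxon, hence
invariant to rooting). 100 replicates by default.

A query is assigned clade X iff the smallest supported group (internal edge
with support ≥ `min_support`, default 70 — a conventional threshold, as no
principled one exists for "grouping") contains the query together with at
least one labeled reference and all references in that group carry label X;
label conflicts or the absence of such a group yield "unassigned". The
nearest labeled neighbor and its distance are always reported so that
unassigned queries remain interpretable.

## The simulator

The generator emulates a non-UDG, capture-enriched, post-merge aDNA library:

| parameter | default | meaning |
|---|---|---|
| `coverage` | 30× | expected unique (pre-duplication) fold-coverage |
| `fragment_length_mean/sd` | 60 / 15 bp | truncated normal, bounds 30–150 bp |
| `damage_rate` | 0.10 | C→T probability at the 5′-terminal position (G→A at 3′) |
| `damage_decay` | 0.5 | geometric per-position decay of the damage rate |
| `error_rate` | 0.002 | per-base sequencing error, uniform over alternatives |
| `duplication_rate` | 2.0 | Poisson mean of *extra* PCR copies per molecule |
| `bleed_rate` | 0.02 | probability a read copy is recorded under another barcode |
| `base_quality` | Q30 | fixed, with an optional fraction of Q8 bases |

No published magnitudes exist for damage or bleeding in this setting; the
defaults are field conventions — ~10% terminal deamination with rapid decay
is typical of Pleistocene material, and a few percent bleeding is the scale
at which pooled single-index capture becomes a design concern — chosen once
and used everywhere (tests, validation script) as the standard study
conditions. Damage is applied once per molecule, before duplication, so PCR
copies share their template's damage (as in real chemistry); sequencing
errors are independent per copy. Fragment starts are uniform; origin-spanning
fragments are off by default so that (start, end) stays a well-defined
cluster key, behind an `allow_origin_spanning` flag. The number of molecules
is `round(coverage · L / E[fragment length])` with the truncated-normal mean
taken from `scipy.stats.truncnorm`, so empirical coverage converges to the
parameter (tested at 3σ of the analytic sampling distribution, as are the
damage, error and bleed rates).

Deliberately not modeled: indels, capture bias along the genome, paired reads
(the simulator emits the post-merge state), barcode sequencing errors,
quality-score correlation with damage, and contamination from other taxa.
Passing tests therefore demonstrate correctness of the *filtering and calling
logic* under the stated noise model, not robustness to every real-data
pathology.

## Problem sizes and numerical choices

The test-bench reference is 2 kb with one feature per category; the standard
batch is 5 samples at 25 substitutions each (~8,800–15,000 read copies),
which the full pipeline processes in seconds; calibration runs use ≥ 10,000
reads; NJ validation uses 100 random additive 5-taxon matrices (3-taxon
closed forms checked to 1e−9) and clade recovery uses 3 clades × 2 references
× 2 queries at 20 fixed differences over 600 bp with 100 bootstrap
replicates. These sizes were chosen so the complete suite and the validation
script each run in well under a minute while every rate check retains 3σ
power. All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give byte-identical outputs at every stage.
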