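"""End-to-end convenience: simulate a pooled batch, run the full pipeline.

These helpers wire the stages together in their canonical order —
quality/length filter → coordinate clustering → conservative de-multiplexing
→ duplicate collapse → pileup → two-tier consensus — and are what the CLI,
the test-bench and the validation script drive. Each stage remains usable on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import caller, dedup, demux, simulate
from .caller import ConsensusGenome, SitePileup
from .reads import ConsensusRead, MappedRead
from .reference import AnnotatedReference


@dataclass
class SimulatedBatch:
    """A pooled multi-sample simulation with its complete ground truth."""

    reference: AnnotatedReference
    haplotypes: dict[str, str]
    pooled_reads: list[MappedRead]
    truth: simulate.SimulationTruth


def simulate_batch(
    reference: AnnotatedReference,
    n_samples: int,
    n_substitutions: int,
    params: simulate.SimulationParams,
    seed: int = 0,
) -> SimulatedBatch:
    """Simulate ``n_samples`` haplotypes from one reference, pool with bleed.

    Per-sample seeds are derived deterministically from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    barcodes = [f"S{i + 1}" for i in range(n_samples)]
    haplotypes = {}
    per_sample = {}
    truths = {}
    for i, bc in enumerate(barcodes):
        hap = simulate.mutate_haplotype(reference, n_substitutions, seed=seed * 1009 + i)
        haplotypes[bc] = hap
        reads, truth = simulate.simulate_reads(hap, params, bc, seed=seed * 2003 + i)
        per_sample[bc] = reads
        truths[bc] = truth
    bleed = params.bleed_rate if n_samples > 1 else 0.0
    pooled, truth = simulate.pool_with_bleed(
        per_sample, bleed, seed=seed * 4001 + 7, truths=truths
    )
    return SimulatedBatch(
        reference=reference, haplotypes=haplotypes, pooled_reads=pooled, truth=truth
    )


@dataclass
class SampleResult:
    """One sample's pipeline products under both calling policies."""

    barcode: str
    n_clusters: int
    unique_reads: list[ConsensusRead]
    pileup: SitePileup
    genomes: dict[str, ConsensusGenome]  # policy name → genome


@dataclass
class BatchResult:
    samples: dict[str, SampleResult]
    demux_result: demux.DemuxResult
    attrition: demux.AttritionReport
    discarded_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.discarded_clusters = len(self.demux_result.discard_log)


def process_batch(
    pooled_reads: list[MappedRead],
    reference_length: int,
    filter_policy: demux.FilterPolicy | None = None,
    policies=(caller.RELAXED, caller.STRICT),
    minority: str = "keep",
) -> BatchResult:
    """Run filter → demux → dedup → pileup → consensus on a pooled batch."""
    filter_policy = filter_policy or demux.FilterPolicy()
    demux_result, attrition = demux.run_demux(
        pooled_reads, filter_policy, minority=minority
    )
    samples = {}
    for barcode, clusters in sorted(demux_result.by_sample.items()):
        unique = dedup.deduplicate_clusters(clusters)
        pileup = caller.build_pileup(unique, reference_length)
        genomes = {p.name: caller.call_consensus(pileup, p) for p in policies}
        samples[barcode] = SampleResult(
            barcode=barcode,
            n_clusters=len(clusters),
            unique_reads=unique,
            pileup=pileup,
            genomes=genomes,
        )
    return BatchResult(samples=samples, demux_result=demux_result, attrition=attrition)


def consensus_accuracy(consensus: str, truth: str) -> tuple[int, int]:
    """(matching called sites, called sites) of a consensus against its truth."""
    called = 0
    match = 0
    for c, t in zip(consensus, truth):
        if c == "N":
            continue
        called += 1
        if c == t:
            match += 1
    return match, called
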