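"""Quality/length filtering and conservative barcode-bleed de-multiplexing.

When multiple barcoded libraries are pooled in one capture reaction, a small
fraction of reads is recorded under the wrong sample's barcode ("barcode
bleeding" / index hopping). The conservative filter implemented here works on
coordinate clusters — sets of reads sharing exact (start, end) alignment
coordinates, presumed PCR copies of one molecule — and retains reads meeting
three criteria:

(a) minimum read length of 30 bp (applied together with a base-quality filter
    that discards reads with more than five bases below Phred 10);
(b) the cluster was observed at least three times;
(c) the whole cluster is assigned to the strictly most frequent barcode within
    it, or discarded if several barcodes tie for the maximum.

Minority-barcode members of a retained cluster are presumed bleed copies of
the winner's molecule; by default they are kept and reassigned to the winning
sample (they are collapsed by deduplication anyway), with an option to drop
them instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .reads import MappedRead, ReadCluster


@dataclass
class FilterPolicy:
    """Thresholds of the read filter and de-multiplexer."""

    min_read_length: int = 30
    max_low_quality_bases: int = 5
    low_quality_threshold: int = 10
    min_cluster_occurrence: int = 3

    def __post_init__(self) -> None:
        if self.min_read_length < 1:
            raise ValueError("min_read_length must be positive")
        if self.max_low_quality_bases < 0:
            raise ValueError("max_low_quality_bases must be >= 0")
        if self.low_quality_threshold < 1:
            raise ValueError("low_quality_threshold must be positive")
        if self.min_cluster_occurrence < 1:
            raise ValueError("min_cluster_occurrence must be positive")


@dataclass
class AttritionReport:
    """Read counts removed by each quality-filter criterion."""

    n_input: int = 0
    n_retained: int = 0
    n_removed: int = 0
    failed_length: int = 0
    failed_quality: int = 0


@dataclass
class DiscardedCluster:
    key: tuple[int, int]
    size: int
    barcode_counts: dict[str, int]
    reason: str  # "below_min_occurrence" or "barcode_tie"


@dataclass
class DemuxResult:
    by_sample: dict[str, list[ReadCluster]]
    discard_log: list[DiscardedCluster] = field(default_factory=list)
    n_minority_reassigned: int = 0
    n_minority_dropped: int = 0

    def retained_read_count(self) -> int:
        return sum(c.size for cs in self.by_sample.values() for c in cs)

    def discarded_read_count(self) -> int:
        return sum(d.size for d in self.discard_log) + self.n_minority_dropped


def quality_filter(
    reads: list[MappedRead], policy: FilterPolicy | None = None
) -> tuple[list[MappedRead], AttritionReport]:
    """Retain reads with length >= min and at most ``max_low_quality_bases``
    bases below the Phred threshold.

    The report counts failures per criterion (a read failing both counts
    toward both), plus totals.
    """
    policy = policy or FilterPolicy()
    retained: list[MappedRead] = []
    report = AttritionReport(n_input=len(reads))
    for r in reads:
        ok_len = r.length >= policy.min_read_length
        n_lowq = sum(1 for q in r.qualities if q < policy.low_quality_threshold)
        ok_qual = n_lowq <= policy.max_low_quality_bases
        if not ok_len:
            report.failed_length += 1
        if not ok_qual:
            report.failed_quality += 1
        if ok_len and ok_qual:
            retained.append(r)
    report.n_retained = len(retained)
    report.n_removed = report.n_input - report.n_retained
    return retained, report


def cluster_reads(reads: list[MappedRead]) -> list[ReadCluster]:
    """Partition reads into coordinate clusters by exact (start, end)."""
    by_key: dict[tuple[int, int], list[MappedRead]] = {}
    for r in reads:
        by_key.setdefault(r.key, []).append(r)
    return [ReadCluster(key=k, members=v) for k, v in sorted(by_key.items())]


def demultiplex(
    clusters: list[ReadCluster],
    policy: FilterPolicy | None = None,
    minority: str = "keep",
) -> DemuxResult:
    """Assign coordinate clusters to samples by the conservative bleed filter.

    Clusters smaller than ``min_cluster_occurrence`` are discarded; a retained
    cluster goes whole to its strictly most frequent barcode, or is discarded
    on a tie. ``minority="keep"`` reassigns minority-barcode members to the
    winner; ``minority="drop"`` removes them.
    """
    if minority not in ("keep", "drop"):
        raise ValueError("minority must be 'keep' or 'drop'")
    policy = policy or FilterPolicy()
    result = DemuxResult(by_sample={})
    for cluster in clusters:
        counts = cluster.barcode_counts
        if cluster.size < policy.min_cluster_occurrence:
            result.discard_log.append(
                DiscardedCluster(cluster.key, cluster.size, dict(counts), "below_min_occurrence")
            )
            continue
        top = max(counts.values())
        winners = [bc for bc, n in counts.items() if n == top]
        if len(winners) > 1:
            result.discard_log.append(
                DiscardedCluster(cluster.key, cluster.size, dict(counts), "barcode_tie")
            )
            continue
        winner = winners[0]
        members = []
        for r in cluster.members:
            if r.barcode == winner:
                members.append(r)
            elif minority == "keep":
                members.append(dataclasses.replace(r, barcode=winner))
                result.n_minority_reassigned += 1
            else:
                result.n_minority_dropped += 1
        result.by_sample.setdefault(winner, []).append(
            ReadCluster(key=cluster.key, members=members)
        )
    return result


def run_demux(
    reads: list[MappedRead],
    policy: FilterPolicy | None = None,
    minority: str = "keep",
) -> tuple[DemuxResult, AttritionReport]:
    """Full stage: quality/length filter, then cluster, then de-multiplex.

    The quality filter precedes clustering, so undersized or low-quality reads
    never count toward cluster occurrence.
    """
    policy = policy or FilterPolicy()
    retained, report = quality_filter(reads, policy)
    clusters = cluster_reads(retained)
    return demultiplex(clusters, policy, minority=minority), report
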