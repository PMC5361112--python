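"""PCR-duplicate collapse: one consensus read per coordinate cluster.

Reads sharing exact (start, end) alignment coordinates are presumed PCR
copies of one original molecule and are collapsed to a single consensus
sequence. The column rule is: majority base over the copies (member N bases
abstain), ties broken by the larger summed Phred quality among the tied
bases, and an N where the tie persists — a deterministic completion that
propagates genuine ambiguity to the consensus caller, whose depth and
majority thresholds handle it.

Downstream stages count unique reads, not quality-weighted evidence, so the
consensus read carries a support count but no per-base qualities.
"""

from __future__ import annotations

from .reads import ConsensusRead, MappedRead, ReadCluster


def collapse_cluster(cluster: ReadCluster) -> ConsensusRead:
    """Collapse one coordinate cluster into a single consensus read."""
    if cluster.size == 0:
        raise ValueError("cannot collapse an empty cluster")
    start, end = cluster.key
    n = end - start
    out = []
    for col in range(n):
        votes: dict[str, int] = {}
        qual: dict[str, int] = {}
        for r in cluster.members:
            base = r.bases[col]
            if base == "N":
                continue
            votes[base] = votes.get(base, 0) + 1
            qual[base] = qual.get(base, 0) + r.qualities[col]
        if not votes:
            out.append("N")
            continue
        top = max(votes.values())
        tied = [b for b, v in votes.items() if v == top]
        if len(tied) == 1:
            out.append(tied[0])
            continue
        topq = max(qual[b] for b in tied)
        tied_q = [b for b in tied if qual[b] == topq]
        out.append(tied_q[0] if len(tied_q) == 1 else "N")
    return ConsensusRead(start=start, end=end, bases="".join(out), support=cluster.size)


def deduplicate(reads: list[MappedRead]) -> list[ConsensusRead]:
    """Collapse a sample's reads to one consensus read per (start, end).

    Output is coordinate-sorted; supports sum to the input read count.
    """
    by_key: dict[tuple[int, int], list[MappedRead]] = {}
    for r in reads:
        by_key.setdefault(r.key, []).append(r)
    return [
        collapse_cluster(ReadCluster(key=k, members=v))
        for k, v in sorted(by_key.items())
    ]


def deduplicate_clusters(clusters: list[ReadCluster]) -> list[ConsensusRead]:
    """Collapse already-formed coordinate clusters (the post-demux path)."""
    return [collapse_cluster(c) for c in sorted(clusters, key=lambda c: c.key)]


def duplicate_fraction(n_reads: int, n_unique: int) -> float:
    """Fraction of read copies that were duplicates of an earlier copy."""
    if n_reads == 0:
        return 0.0
    return 1.0 - n_unique / n_reads
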