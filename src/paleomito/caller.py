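"""Two-tier consensus calling from per-site pileups of unique reads.

Ancient-DNA libraries that were not UDG-treated carry deaminated bases
(C→T / G→A) concentrated at fragment ends; calling a haploid mitogenome
consensus from such reads therefore trades coverage against accuracy. Two
named threshold bundles implement the trade-off:

* ``relaxed`` — a base is called where at least 3 unique (non-duplicate)
  reads cover the site and the majority base has frequency strictly greater
  than 1/3; a genome enters the relaxed alignment if no more than 33% of its
  sites are N.
* ``strict`` — at least 10-fold unique coverage and majority frequency
  strictly greater than 90%; no more than 20% of sites may be missing.

All other sites are called N; the only non-ACGT output symbol is N (no
ambiguity codes). Majority thresholds are exact rationals compared by
cross-multiplication, so boundary pileups (e.g. 1 of 3, or 9 of 10) behave
exactly as the exclusive bounds dictate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .reads import ConsensusRead

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class CallingPolicy:
    """A named bundle of consensus-calling thresholds.

    ``majority_fraction`` is an exclusive lower bound on the majority base
    frequency; ``max_missing_fraction`` is an inclusive upper bound on the
    genome-wide N fraction for inclusion in an alignment.
    """

    name: str
    min_depth: int
    majority_fraction: Fraction
    max_missing_fraction: Fraction

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.majority_fraction < 1:
            raise ValueError("majority_fraction must be in (0, 1)")
        if not 0 < self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in (0, 1)")


RELAXED = CallingPolicy("relaxed", 3, Fraction(1, 3), Fraction(33, 100))
STRICT = CallingPolicy("strict", 10, Fraction(9, 10), Fraction(20, 100))
POLICIES = {"relaxed": RELAXED, "strict": STRICT}


@dataclass
class SitePileup:
    """Per-site A/C/G/T counts over the unique reads of one sample.

    ``counts`` has shape (reference_length, 4) in A,C,G,T order; N bases in
    reads contribute to neither counts nor depth.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (L, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def reference_length(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ConsensusGenome:
    """A called consensus with its inclusion verdict under one policy."""

    sequence: str
    policy: str
    missing_fraction: float
    included: bool

    def __post_init__(self) -> None:
        n = self.sequence.count("N")
        expect = n / len(self.sequence) if self.sequence else 0.0
        if abs(expect - self.missing_fraction) > 1e-12:
            raise ValueError("missing_fraction inconsistent with sequence")

    @property
    def n_called(self) -> int:
        return len(self.sequence) - self.sequence.count("N")


def build_pileup(unique_reads: list[ConsensusRead], reference_length: int) -> SitePileup:
    """Count A/C/G/T per reference site over unique (post-dedup) reads."""
    counts = np.zeros((reference_length, 4), dtype=np.int64)
    for r in unique_reads:
        if r.start < 0 or r.end > reference_length:
            raise ValueError(
                f"read [{r.start}, {r.end}) out of reference bounds "
                f"[0, {reference_length})"
            )
        for offset, base in enumerate(r.bases):
            if base == "N":
                continue
            counts[r.start + offset, _BASE_INDEX[base]] += 1
    return SitePileup(counts)


def call_base(counts, policy: CallingPolicy) -> str:
    """Call one site from its base counts, or N.

    ``counts`` is a mapping base→count or a length-4 A,C,G,T vector. The site
    is called iff depth >= min_depth, a single base attains the maximum count,
    and that count exceeds ``majority_fraction`` of the depth (strictly).
    """
    if isinstance(counts, dict):
        vec = [int(counts.get(b, 0)) for b in _BASES]
    else:
        vec = [int(c) for c in counts]
    depth = sum(vec)
    if depth < policy.min_depth:
        return "N"
    top = max(vec)
    if vec.count(top) != 1:
        return "N"
    q = policy.majority_fraction
    if top * q.denominator <= depth * q.numerator:  # frequency not > bound
        return "N"
    return _BASES[vec.index(top)]


def call_consensus(pileup: SitePileup, policy: CallingPolicy) -> ConsensusGenome:
    """Call every reference site; uncovered sites are N.

    ``missing_fraction`` is computed over the full reference length, and the
    inclusion flag compares it (inclusively) with the policy bound.
    """
    seq = "".join(call_base(row, policy) for row in pileup.counts)
    n_missing = seq.count("N")
    length = len(seq)
    included = n_missing * policy.max_missing_fraction.denominator <= (
        length * policy.max_missing_fraction.numerator
    )
    return ConsensusGenome(
        sequence=seq,
        policy=policy.name,
        missing_fraction=n_missing / length if length else 0.0,
        included=bool(included),
    )
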