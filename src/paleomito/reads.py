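"""Read containers: mapped read copies, coordinate clusters, consensus reads.

A :class:`MappedRead` is one sequenced copy of one original DNA molecule,
already mapped: it carries its sample barcode, its alignment interval on the
reference (0-based half-open) and its bases/qualities. Reads sharing an exact
``(start, end)`` interval are presumed PCR copies of the same molecule and are
grouped into a :class:`ReadCluster`; collapsing a cluster yields a single
:class:`ConsensusRead` whose ``support`` counts the collapsed copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


@dataclass
class MappedRead:
    read_id: str
    barcode: str
    start: int
    end: int
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if isinstance(self.qualities, list):
            self.qualities = tuple(self.qualities)
        n = self.end - self.start
        if n < 1:
            raise ValueError(f"read {self.read_id!r}: empty interval")
        if len(self.bases) != n or len(self.qualities) != n:
            raise ValueError(
                f"read {self.read_id!r}: interval length {n} != "
                f"{len(self.bases)} bases / {len(self.qualities)} qualities"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ReadCluster:
    """All read copies sharing one exact (start, end) alignment interval."""

    key: tuple[int, int]
    members: list[MappedRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.members:
            if r.key != self.key:
                raise ValueError(
                    f"read {r.read_id!r} at {r.key} does not match cluster key {self.key}"
                )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def barcode_counts(self) -> Counter:
        return Counter(r.barcode for r in self.members)


@dataclass
class ConsensusRead:
    """One collapsed molecule: per-column consensus over its PCR copies."""

    start: int
    end: int
    bases: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.bases):
            raise ValueError("consensus read length mismatch")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start
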