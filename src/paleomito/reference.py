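"""Reference genomes and their feature annotation.

Everything downstream of the simulator shares one coordinate frame: the
0-based, half-open interval system of the annotated reference. Features are
typed by the four partition categories used for phylogenetic analysis of
mitochondrial genomes (protein-coding genes, the control region, tRNAs and
rRNAs) and carry a strand so reverse-strand genes can be reverse-complemented
before concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PARTITION_CATEGORIES = ("protein_coding", "control_region", "tRNA", "rRNA")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence over {A,C,G,T,N,-}; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """An annotated interval on the reference.

    ``start``/``end`` are 0-based half-open. A feature with ``end <= start``
    is interpreted as wrapping through the origin of a circular reference
    (only the control region is expected to do this in mitogenomes).
    """

    name: str
    start: int
    end: int
    strand: str  # "+" or "-"
    category: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")
        if self.category not in PARTITION_CATEGORIES:
            raise ValueError(
                f"feature {self.name!r}: category {self.category!r} not in "
                f"{PARTITION_CATEGORIES}"
            )
        if self.start < 0 or self.end < 0:
            raise ValueError(f"feature {self.name!r}: negative coordinate")

    @property
    def wraps_origin(self) -> bool:
        return self.end <= self.start

    def length(self, reference_length: int) -> int:
        if self.wraps_origin:
            return (reference_length - self.start) + self.end
        return self.end - self.start


@dataclass
class AnnotatedReference:
    """A (typically circular mitochondrial) reference with typed features."""

    sequence: str
    is_circular: bool = True
    features: list[Feature] = field(default_factory=list)
    name: str = "reference"

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"reference contains non-ACGT symbols: {sorted(bad)}")
        length = len(self.sequence)
        for f in self.features:
            if f.wraps_origin:
                if not self.is_circular:
                    raise ValueError(
                        f"feature {f.name!r} wraps the origin of a linear reference"
                    )
                if f.start >= length or f.end > length:
                    raise ValueError(f"feature {f.name!r} outside [0, {length})")
            elif f.end > length:
                raise ValueError(f"feature {f.name!r} outside [0, {length})")
        # Non-wrapping features must not overlap; the wrap feature (if any)
        # occupies [start, L) + [0, end) and is checked against the rest.
        spans: list[tuple[int, int, str]] = []
        for f in self.features:
            if f.wraps_origin:
                spans.append((f.start, length, f.name))
                spans.append((0, f.end, f.name))
            else:
                spans.append((f.start, f.end, f.name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1 and n1 != n2:
                raise ValueError(f"features {n1!r} and {n2!r} overlap")

    @property
    def length(self) -> int:
        return len(self.sequence)
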