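"""Build the four phylogenetic sequence partitions from consensus genomes.

Mitogenome phylogenetics conventionally models four site classes separately:
protein-coding genes, the control region, tRNAs and rRNAs. Because consensus
genomes here are called in reference coordinates, they are already
column-compatible; partitioning is therefore pure extraction and
concatenation: each feature is cut out of each genome, reverse-strand genes
are reverse-complemented, and features of the same category are concatenated
in ascending reference-start order (any fixed order is phylogenetically
equivalent). Inter-genic sites covered by no feature are dropped.

A control-region feature may wrap the origin of the circular genome
(``end <= start``); it is extracted as suffix + prefix and flagged in the
coordinate map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reference import PARTITION_CATEGORIES, Feature, reverse_complement

CATEGORY_ORDER = tuple(PARTITION_CATEGORIES)


@dataclass
class BlockSegment:
    """Where one feature landed inside its category block."""

    feature: str
    start: int  # within-block, 0-based
    end: int    # within-block, exclusive
    ref_start: int
    ref_end: int
    strand: str
    wraps_origin: bool = False


@dataclass
class PartitionedAlignment:
    """Per-category concatenated blocks for every sample.

    ``blocks[category][sample]`` is the concatenated sequence; all samples
    have equal-length blocks per category and share one coordinate map.
    """

    blocks: dict[str, dict[str, str]] = field(default_factory=dict)
    coordinate_maps: dict[str, list[BlockSegment]] = field(default_factory=dict)
    category_order: tuple[str, ...] = CATEGORY_ORDER

    def block_length(self, category: str) -> int:
        samples = self.blocks.get(category, {})
        if not samples:
            return 0
        return len(next(iter(samples.values())))

    def samples(self) -> list[str]:
        for cat in self.category_order:
            if self.blocks.get(cat):
                return sorted(self.blocks[cat])
        return []

    def concatenated(self, sample: str) -> str:
        """All four blocks of one sample joined in category order."""
        return "".join(self.blocks[cat].get(sample, "") for cat in self.category_order)


def extract_feature(genome: str, feature: Feature, reference_length: int | None = None) -> str:
    """Extract one feature from a genome, reverse-complementing reverse-strand genes.

    ``reference_length`` defaults to ``len(genome)`` and is the circular frame
    for wrap-around features.
    """
    length = reference_length if reference_length is not None else len(genome)
    if len(genome) != length:
        raise ValueError(f"genome length {len(genome)} != reference length {length}")
    if feature.wraps_origin:
        if feature.start >= length or feature.end > length:
            raise ValueError(f"feature {feature.name!r} outside [0, {length})")
        sub = genome[feature.start:] + genome[: feature.end]
    else:
        if feature.end > length:
            raise ValueError(f"feature {feature.name!r} outside [0, {length})")
        sub = genome[feature.start : feature.end]
    return reverse_complement(sub) if feature.strand == "-" else sub


def concatenate_partitions(
    genomes: dict[str, str], annotation: list[Feature]
) -> PartitionedAlignment:
    """Concatenate features of each category, in ascending start order, per sample.

    All four category blocks are emitted even when a category has no features
    (zero-length block). Raises if any genome length differs from the others.
    """
    if not genomes:
        raise ValueError("no genomes given")
    lengths = {s: len(g) for s, g in genomes.items()}
    ref_len = next(iter(lengths.values()))
    for sample, n in lengths.items():
        if n != ref_len:
            raise ValueError(
                f"genome {sample!r} has length {n}, expected {ref_len}"
            )

    result = PartitionedAlignment()
    for cat in CATEGORY_ORDER:
        feats = sorted(
            (f for f in annotation if f.category == cat), key=lambda f: (f.start, f.name)
        )
        segments: list[BlockSegment] = []
        pos = 0
        for f in feats:
            flen = f.length(ref_len)
            segments.append(
                BlockSegment(
                    feature=f.name,
                    start=pos,
                    end=pos + flen,
                    ref_start=f.start,
                    ref_end=f.end,
                    strand=f.strand,
                    wraps_origin=f.wraps_origin,
                )
            )
            pos += flen
        result.coordinate_maps[cat] = segments
        result.blocks[cat] = {
            sample: "".join(
                extract_feature(genome, f, ref_len) for f in feats
            )
            for sample, genome in genomes.items()
        }
    return result


def write_category_fastas(alignment: PartitionedAlignment, out_dir) -> dict[str, str]:
    """Write one FASTA per category; returns category → path."""
    from pathlib import Path

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for cat in alignment.category_order:
        path = out_dir / f"{cat}.fasta"
        records = [
            SeqRecord(Seq(seq), id=sample, description=f"partition={cat}")
            for sample, seq in sorted(alignment.blocks.get(cat, {}).items())
        ]
        SeqIO.write(records, str(path), "fasta")
        paths[cat] = str(path)
    return paths


def write_nexus(alignment: PartitionedAlignment, path) -> None:
    """Write the concatenated alignment as NEXUS with charset partition lines.

    This is the hand-off format for downstream partitioned phylogenetic
    dating tools; charsets delimit the four category blocks (1-based,
    inclusive, NEXUS convention). Empty categories are omitted from charsets.
    """
    samples = alignment.samples()
    seqs = {s: alignment.concatenated(s) for s in samples}
    total = len(next(iter(seqs.values()))) if seqs else 0
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(samples)} NCHAR={total};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        width = max((len(s) for s in samples), default=0) + 2
        for s in samples:
            fh.write(f"    {s:<{width}}{seqs[s]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        offset = 0
        for cat in alignment.category_order:
            n = alignment.block_length(cat)
            if n > 0:
                fh.write(f"  charset {cat} = {offset + 1}-{offset + n};\n")
            offset += n
        fh.write("END;\n")
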