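"""File-format round trips: SAM, FASTA/FASTQ, BED/GFF3 annotation, truth JSON.

Coordinates are 0-based half-open everywhere in memory; pysam handles the
1-based SAM text convention on write, and GFF3 (1-based inclusive) is
converted on read. Barcodes travel in the ``BC`` read tag (with a read-name
suffix fallback), dedup support counts in the locally-defined ``sp`` integer
tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import ConsensusRead, MappedRead
from .reference import AnnotatedReference, Feature
from .simulate import SimulationTruth

BARCODE_TAG = "BC"
SUPPORT_TAG = "sp"


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(records: dict[str, str], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_labeled_fasta(path, labels_tsv=None) -> tuple[dict[str, str], dict[str, str]]:
    """Read an alignment FASTA plus clade labels.

    Labels come from a ``clade=X`` token in the description line, overridden
    by an optional two-column TSV (taxon, clade). Unlabeled records are
    queries.
    """
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("clade="):
                labels[rec.id] = token.split("=", 1)[1]
    if labels_tsv:
        with open(labels_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                taxon, clade = line.split("\t")[:2]
                labels[taxon] = clade
    return seqs, labels


def write_fastq(reads: list[MappedRead], path) -> None:
    """FASTQ with the barcode recorded in the header comment."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id} {BARCODE_TAG}:{r.barcode}\n{r.bases}\n+\n{qual}\n")


# ----------------------------------------------------------------------- SAM

def _sam_header(reference_name: str, reference_length: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": reference_name, "LN": reference_length}],
        }
    )


def write_sam(
    reads: list[MappedRead],
    path,
    reference_name: str,
    reference_length: int,
) -> None:
    """Write mapped reads as coordinate-sorted SAM text, barcode in BC tag."""
    header = _sam_header(reference_name, reference_length)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in sorted(reads, key=lambda x: (x.start, x.end, x.read_id)):
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.mapping_quality = 60
            seg.cigartuples = [(0, r.length)]
            seg.query_sequence = r.bases
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities)
            )
            seg.set_tag(BARCODE_TAG, r.barcode, value_type="Z")
            out.write(seg)


def read_sam(path, barcode_tag: str = BARCODE_TAG) -> list[MappedRead]:
    """Read mapped reads; barcode from the tag, else a read-name ``#`` suffix."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if seg.has_tag(barcode_tag):
                barcode = str(seg.get_tag(barcode_tag))
            elif "#" in seg.query_name:
                barcode = seg.query_name.rsplit("#", 1)[1]
            else:
                raise ValueError(
                    f"read {seg.query_name!r}: no {barcode_tag} tag or '#' name suffix"
                )
            quals = seg.query_qualities
            reads.append(
                MappedRead(
                    read_id=seg.query_name,
                    barcode=barcode,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    bases=seg.query_sequence.upper(),
                    qualities=tuple(int(q) for q in quals),
                )
            )
    return reads


def write_consensus_sam(
    reads: list[ConsensusRead], path, reference_name: str, reference_length: int
) -> None:
    """Write unique (deduplicated) reads; support count in the ``sp`` tag."""
    header = _sam_header(reference_name, reference_length)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, r in enumerate(sorted(reads, key=lambda x: (x.start, x.end))):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"unique.{i}"
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.mapping_quality = 60
            seg.cigartuples = [(0, r.length)]
            seg.query_sequence = r.bases
            seg.set_tag(SUPPORT_TAG, r.support, value_type="i")
            out.write(seg)


def read_consensus_sam(path) -> list[ConsensusRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            support = int(seg.get_tag(SUPPORT_TAG)) if seg.has_tag(SUPPORT_TAG) else 1
            reads.append(
                ConsensusRead(
                    start=seg.reference_start,
                    end=seg.reference_end,
                    bases=seg.query_sequence.upper(),
                    support=support,
                )
            )
    return reads


# ---------------------------------------------------------------- annotation

def write_bed(features: list[Feature], path, chrom: str = "ref") -> None:
    """BED6+1: chrom, start, end, name, score, strand, category."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\t{f.category}\n"
            )


def read_bed(path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ValueError(f"BED line needs 7 columns (category in col 7): {line!r}")
            feats.append(
                Feature(
                    name=cols[3],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5],
                    category=cols[6],
                )
            )
    return feats


def read_gff3(path) -> list[Feature]:
    """GFF3 with the partition category in the type column; 1-based inclusive
    coordinates are converted to 0-based half-open on read."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"{cols[2]}_{cols[3]}"
            feats.append(
                Feature(
                    name=name,
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    category=cols[2],
                )
            )
    return feats


def read_annotation(path) -> list[Feature]:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_gff3(path)
    return read_bed(path)


# ---------------------------------------------------------------------- JSON

def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        return SimulationTruth.from_dict(json.load(fh))


def write_reference(ref: AnnotatedReference, fasta_path, bed_path=None) -> None:
    write_fasta({ref.name: ref.sequence}, fasta_path)
    if bed_path:
        write_bed(ref.features, bed_path, chrom=ref.name)
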