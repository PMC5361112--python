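"""Synthetic ancient-DNA read simulation with complete ground truth.

The simulator emulates the state of a non-UDG-treated, single-end (post-merge)
ancient-DNA capture library as it reaches the processing pipeline:

* short fragments with truncated-normal length (defaults ~60 bp, 30-150 bp);
* elevated terminal cytosine deamination — C→T substitutions entering from the
  5' end and complementary G→A from the 3' end of the read as sequenced, with
  a geometrically decaying per-position rate (the standard phenomenology of
  post-mortem damage);
* per-base sequencing error and base-quality noise;
* PCR duplicates: each unique molecule is emitted ``1 + Poisson(duplication_rate)``
  times, all copies sharing the exact (start, end) alignment interval;
* pooled multi-sample batches with a low rate of barcode bleeding, i.e. read
  copies recorded under the wrong sample's barcode.

Damage is applied once per unique molecule (it is template damage, shared by
all PCR copies); sequencing errors are drawn independently per copy. Every
emitted read copy has exactly one truth record, so downstream filters can be
scored exactly. Mapping is out of scope: alignment coordinates in the truth
are exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .reads import MappedRead
from .reference import PARTITION_CATEGORIES, AnnotatedReference, Feature

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SimulationParams:
    """Tunable knobs of the read simulator.

    Defaults describe a moderately damaged, moderately duplicated non-UDG
    library: 30x coverage of ~60 bp fragments, 10% terminal deamination
    decaying geometrically into the read, 0.2% sequencing error, two extra
    PCR copies per molecule on average, and 2% barcode bleeding.
    """

    coverage: float = 30.0
    fragment_length_mean: float = 60.0
    fragment_length_sd: float = 15.0
    min_fragment: int = 30
    max_fragment: int = 150
    damage_rate: float = 0.1
    damage_decay: float = 0.5
    error_rate: float = 0.002
    duplication_rate: float = 2.0
    bleed_rate: float = 0.02
    base_quality: int = 30
    low_quality_fraction: float = 0.0
    low_quality_value: int = 8
    allow_origin_spanning: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("damage_rate", "error_rate", "bleed_rate", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.damage_decay < 1.0:
            raise ValueError("damage_decay must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.min_fragment < 1:
            raise ValueError("min_fragment must be >= 1")
        if self.max_fragment < self.min_fragment:
            raise ValueError("max_fragment must be >= min_fragment")
        if self.duplication_rate < 0:
            raise ValueError("duplication_rate must be >= 0")

    def expected_fragment_length(self) -> float:
        """Mean of the truncated-normal fragment length distribution."""
        a = (self.min_fragment - self.fragment_length_mean) / self.fragment_length_sd
        b = (self.max_fragment - self.fragment_length_mean) / self.fragment_length_sd
        return float(
            stats.truncnorm.mean(
                a, b, loc=self.fragment_length_mean, scale=self.fragment_length_sd
            )
        )


@dataclass
class ReadTruth:
    """Ground truth for one emitted read copy."""

    read_id: str
    true_barcode: str
    observed_barcode: str
    molecule_id: str
    damaged_positions: tuple[int, ...] = ()
    error_positions: tuple[int, ...] = ()

    @property
    def is_bleed(self) -> bool:
        return self.observed_barcode != self.true_barcode


@dataclass
class SimulationTruth:
    """Complete ground truth of a simulation: haplotypes and per-read records."""

    haplotypes: dict[str, str] = field(default_factory=dict)
    records: dict[str, ReadTruth] = field(default_factory=dict)

    def merge(self, other: "SimulationTruth") -> None:
        overlap = self.records.keys() & other.records.keys()
        if overlap:
            raise ValueError(f"duplicate read ids across truths: {sorted(overlap)[:3]}")
        self.haplotypes.update(other.haplotypes)
        self.records.update(other.records)

    def to_dict(self) -> dict:
        return {
            "haplotypes": dict(self.haplotypes),
            "records": {
                rid: dataclasses.asdict(rec) for rid, rec in self.records.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        truth = cls(haplotypes=dict(d["haplotypes"]))
        for rid, rec in d["records"].items():
            rec = dict(rec)
            rec["damaged_positions"] = tuple(rec["damaged_positions"])
            rec["error_positions"] = tuple(rec["error_positions"])
            truth.records[rid] = ReadTruth(**rec)
        return truth


def generate_reference(
    length: int,
    n_features_per_category: int = 1,
    seed: int = 0,
    is_circular: bool = True,
) -> AnnotatedReference:
    """Generate a uniform-random reference with non-overlapping typed features.

    Features are placed in random order along the genome with random gaps,
    ``n_features_per_category`` per category, strands assigned at random.
    Deterministic given ``seed``.
    """
    if length <= 0:
        raise ValueError(f"reference length must be positive, got {length}")
    if length < 200:
        raise ValueError(f"reference length must be >= 200, got {length}")
    if n_features_per_category < 0:
        raise ValueError("n_features_per_category must be >= 0")
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list(_BASES), size=length))

    n_features = 4 * n_features_per_category
    features: list[Feature] = []
    if n_features:
        lo, hi = 50, 200
        # shrink feature lengths if the genome is small
        max_len = max(10, length // (2 * n_features))
        hi = min(hi, max_len)
        lo = min(lo, hi)
        lengths = rng.integers(lo, hi + 1, size=n_features)
        total = int(lengths.sum())
        if total > length:
            raise ValueError(
                f"cannot fit {n_features} features totalling {total} bp "
                f"in a {length} bp reference"
            )
        # distribute the slack as random gaps before each feature
        slack = length - total
        cuts = np.sort(rng.integers(0, slack + 1, size=n_features))
        gaps = np.diff(np.concatenate([[0], cuts]))
        categories = [c for c in PARTITION_CATEGORIES for _ in range(n_features_per_category)]
        order = rng.permutation(n_features)
        pos = 0
        counters: dict[str, int] = {}
        for i, (gap, flen) in enumerate(zip(gaps, lengths)):
            pos += int(gap)
            cat = categories[order[i]]
            counters[cat] = counters.get(cat, 0) + 1
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(
                    name=f"{cat}_{counters[cat]}",
                    start=pos,
                    end=pos + int(flen),
                    strand=strand,
                    category=cat,
                )
            )
            pos += int(flen)
    return AnnotatedReference(sequence=sequence, is_circular=is_circular, features=features)


def mutate_haplotype(ref: AnnotatedReference, n_substitutions: int, seed: int = 0) -> str:
    """Derive a sample haplotype at exact Hamming distance ``n_substitutions``.

    Positions are chosen without replacement; each substitution replaces the
    reference base with a different base chosen uniformly.
    """
    length = ref.length
    if not 0 <= n_substitutions <= length:
        raise ValueError(
            f"n_substitutions must be in [0, {length}], got {n_substitutions}"
        )
    rng = np.random.default_rng(seed)
    seq = list(ref.sequence)
    positions = rng.choice(length, size=n_substitutions, replace=False)
    for p in positions:
        old = seq[p]
        alternatives = [b for b in _BASES if b != old]
        seq[p] = alternatives[rng.integers(0, 3)]
    return "".join(seq)


def _damage_positions(fragment: str, rate: float, decay: float, rng) -> list[int]:
    """Deamination sites: C→T from the 5' end, G→A from the 3' end."""
    if rate == 0.0:
        return []
    n = len(fragment)
    hit = []
    for p, base in enumerate(fragment):
        if base == "C":
            if rng.random() < rate * decay**p:
                hit.append(p)
        elif base == "G":
            d3 = n - 1 - p
            if rng.random() < rate * decay**d3:
                hit.append(p)
    return hit


_DAMAGE_SUB = {"C": "T", "G": "A"}


def simulate_reads(
    haplotype: str,
    params: SimulationParams,
    barcode: str,
    seed: int | None = None,
) -> tuple[list[MappedRead], SimulationTruth]:
    """Simulate a barcoded read set from one haplotype.

    The number of unique molecules is chosen so expected unique bases equal
    ``coverage * len(haplotype)``. Each molecule is damaged once, then emitted
    ``1 + Poisson(duplication_rate)`` times with independent per-copy
    sequencing errors and qualities. Returns coordinate-sorted reads plus the
    truth. Deterministic given the seed (``params.seed`` unless overridden).
    """
    if not haplotype:
        raise ValueError("haplotype must be non-empty")
    L = len(haplotype)
    rng = np.random.default_rng(params.seed if seed is None else seed)

    mean_len = params.expected_fragment_length()
    n_molecules = max(1, int(round(params.coverage * L / mean_len)))

    a = (params.min_fragment - params.fragment_length_mean) / params.fragment_length_sd
    b = (params.max_fragment - params.fragment_length_mean) / params.fragment_length_sd
    lengths = stats.truncnorm.rvs(
        a,
        b,
        loc=params.fragment_length_mean,
        scale=params.fragment_length_sd,
        size=n_molecules,
        random_state=rng,
    )
    lengths = np.clip(np.rint(lengths).astype(int), params.min_fragment, params.max_fragment)
    lengths = np.minimum(lengths, L)

    reads: list[MappedRead] = []
    truth = SimulationTruth(haplotypes={barcode: haplotype})
    for m, flen in enumerate(lengths):
        flen = int(flen)
        if params.allow_origin_spanning:
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, L - flen + 1))
        end = start + flen
        if end <= L:
            fragment = haplotype[start:end]
        else:  # origin-spanning fragment of a circular genome
            fragment = haplotype[start:] + haplotype[: end - L]
        mol_id = f"{barcode}.m{m}"

        dmg = _damage_positions(fragment, params.damage_rate, params.damage_decay, rng)
        damaged = list(fragment)
        for p in dmg:
            damaged[p] = _DAMAGE_SUB[damaged[p]]
        damaged_seq = "".join(damaged)

        n_copies = 1 + int(rng.poisson(params.duplication_rate))
        for c in range(n_copies):
            bases = list(damaged_seq)
            err_positions = []
            if params.error_rate > 0:
                hits = np.nonzero(rng.random(flen) < params.error_rate)[0]
                for p in hits:
                    p = int(p)
                    alternatives = [x for x in _BASES if x != bases[p]]
                    bases[p] = alternatives[rng.integers(0, 3)]
                    err_positions.append(p)
            quals = np.full(flen, params.base_quality, dtype=int)
            if params.low_quality_fraction > 0:
                lowq = rng.random(flen) < params.low_quality_fraction
                quals[lowq] = params.low_quality_value
            read_id = f"{mol_id}.c{c}"
            reads.append(
                MappedRead(
                    read_id=read_id,
                    barcode=barcode,
                    start=start,
                    end=end,
                    bases="".join(bases),
                    qualities=tuple(int(q) for q in quals),
                )
            )
            truth.records[read_id] = ReadTruth(
                read_id=read_id,
                true_barcode=barcode,
                observed_barcode=barcode,
                molecule_id=mol_id,
                damaged_positions=tuple(dmg),
                error_positions=tuple(err_positions),
            )
    reads.sort(key=lambda r: (r.start, r.end, r.read_id))
    return reads, truth


def pool_with_bleed(
    per_sample_reads: dict[str, list[MappedRead]],
    bleed_rate: float,
    seed: int = 0,
    truths: dict[str, SimulationTruth] | None = None,
) -> tuple[list[MappedRead], SimulationTruth]:
    """Pool per-sample read sets into one batch with barcode bleeding.

    Each read copy is independently recorded under a uniformly chosen *other*
    barcode with probability ``bleed_rate``. Existing per-sample truths, if
    given, are merged and updated with the observed barcodes.
    """
    if not 0.0 <= bleed_rate <= 1.0:
        raise ValueError(f"bleed_rate must be in [0, 1], got {bleed_rate}")
    barcodes = sorted(per_sample_reads)
    if bleed_rate > 0 and len(barcodes) < 2:
        raise ValueError("bleed_rate > 0 requires at least two samples")
    rng = np.random.default_rng(seed)

    truth = SimulationTruth()
    if truths:
        for t in truths.values():
            truth.merge(t)

    pooled: list[MappedRead] = []
    for bc in barcodes:
        for read in per_sample_reads[bc]:
            observed = bc
            if bleed_rate > 0 and rng.random() < bleed_rate:
                others = [x for x in barcodes if x != bc]
                observed = others[int(rng.integers(0, len(others)))]
            out = dataclasses.replace(read, barcode=observed)
            pooled.append(out)
            rec = truth.records.get(read.read_id)
            if rec is None:
                truth.records[read.read_id] = ReadTruth(
                    read_id=read.read_id,
                    true_barcode=bc,
                    observed_barcode=observed,
                    molecule_id=read.read_id,
                )
            else:
                truth.records[read.read_id] = dataclasses.replace(
                    rec, observed_barcode=observed
                )
    pooled.sort(key=lambda r: (r.start, r.end, r.read_id))
    return pooled, truth
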