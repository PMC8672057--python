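"""Circular-aware interval algebra for genic/intergenic accounting.

The length bookkeeping used throughout the comparative tables projects
every feature onto a single unstranded axis, removes coordinate overlaps,
and takes the union's total length as the genic length; the intergenic
length is the genome length minus that union.  On circular genomes an
origin-spanning feature contributes two segments of the linearized axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation_io import CIRCULAR, AnnotatedGenome, Feature


@dataclass
class IntervalSet:
    """Canonical union of 0-based half-open segments on one genome axis.

    After canonicalization segments are sorted, pairwise disjoint and
    non-adjacent (touching segments are merged), and each lies within
    ``[0, genome_length)``.
    """

    genome_length: int
    topology: str = CIRCULAR
    segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def covered_length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def contains(self, s0: int, e0: int) -> bool:
        """True if [s0, e0) is fully inside the union."""
        if e0 <= s0:
            return True
        return any(cs <= s0 and e0 <= ce for cs, ce in self.segments)

    def overlaps(self, s0: int, e0: int) -> bool:
        """True if [s0, e0) shares >= 1 position with the union."""
        return any(cs < e0 and s0 < ce for cs, ce in self.segments)


def _merge(segments: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    segs = sorted((s, e) for s, e in segments if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1]:  # overlap or adjacency
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def canonicalize(
    features: Sequence[Feature], genome_length: int, topology: str = CIRCULAR
) -> IntervalSet:
    """Project features (both strands) onto one axis and merge overlaps.

    Origin-wrapping features are split into their two linear segments
    before merging.
    """
    raw: list[tuple[int, int]] = []
    for f in features:
        f.validate(genome_length, topology)
        raw.extend(f.segments0(genome_length))
    return IntervalSet(genome_length, topology, _merge(raw))


def covered_length(s: IntervalSet) -> int:
    return s.covered_length


def intergenic_length(genome: AnnotatedGenome) -> int:
    """Genome length minus the overlap-removed union of ALL features."""
    iset = canonicalize(
        genome.features, len(genome.record), genome.record.topology
    )
    return len(genome.record) - iset.covered_length


def genic_length(genome: AnnotatedGenome) -> int:
    return canonicalize(
        genome.features, len(genome.record), genome.record.topology
    ).covered_length


@dataclass
class OverlapReport:
    """Counts of A features touching / contained in the union of B.

    ``n_a_overlapping_b`` counts A features sharing >= 1 bp with union(B)
    ("overlap"); ``n_a_within_b`` counts A features fully contained in
    union(B) ("within").  Fractions are ``None`` when ``n_a == 0``.
    """

    n_a: int
    n_a_overlapping_b: int
    n_a_within_b: int

    def __post_init__(self) -> None:
        assert 0 <= self.n_a_within_b <= self.n_a_overlapping_b <= self.n_a

    @property
    def frac_overlapping(self) -> float | None:
        return None if self.n_a == 0 else self.n_a_overlapping_b / self.n_a

    @property
    def frac_within(self) -> float | None:
        return None if self.n_a == 0 else self.n_a_within_b / self.n_a


def overlap_report(
    a_features: Sequence[Feature],
    b_features: Sequence[Feature],
    genome_length: int,
    topology: str = CIRCULAR,
) -> OverlapReport:
    """Overlap statistics of feature set A against the union of set B.

    Each A feature is counted at most once per mode regardless of how
    many B features it touches.  A wrapped A feature is "within" only if
    both of its linear segments are contained.
    """
    b_union = canonicalize(b_features, genome_length, topology)
    n_over = 0
    n_within = 0
    for f in a_features:
        f.validate(genome_length, topology)
        segs = f.segments0(genome_length)
        if any(b_union.overlaps(s, e) for s, e in segs):
            n_over += 1
            if all(b_union.contains(s, e) for s, e in segs):
                n_within += 1
    return OverlapReport(len(a_features), n_over, n_within)


def pool_reports(reports: Iterable[OverlapReport]) -> OverlapReport:
    """Dataset-level report over summed counts (not means of fractions)."""
    n_a = n_over = n_within = 0
    for r in reports:
        n_a += r.n_a
        n_over += r.n_a_overlapping_b
        n_within += r.n_a_within_b
    return OverlapReport(n_a, n_over, n_within)
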