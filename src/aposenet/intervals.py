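"""Genomic coordinate primitives shared by every pipeline stage.

All coordinates are 0-based, half-open (BED convention).  GTF input, which is
1-based inclusive, is converted on read by the I/O layer; nothing downstream
ever sees 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name; matched by exact string equality throughout
        (no "chr" normalisation).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor midpoint of the interval."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base (strand ignored).

    Half-open semantics: adjacent intervals (``a.end == b.start``) do not
    overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals on the same chromosome.

    0 for overlapping or adjacent intervals.  Raises if chromosomes differ
    (the distance is undefined across chromosomes).
    """
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def point_to_interval_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance in bp from a point to an interval (0 if the point is inside)."""
    if iv.start <= pos < iv.end:
        return 0
    return iv.start - pos if pos < iv.start else pos - (iv.end - 1)


@dataclass
class SignalTrack:
    """Step-function coverage signal (bedGraph semantics), values in CPM.

    Per chromosome: parallel arrays of step starts, ends and non-negative
    values; steps within a chromosome are non-overlapping and sorted.
    Regions without a step have value 0.
    """

    steps: dict = field(default_factory=dict)  # chrom -> (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}")
            if not (0 <= start < end):
                raise ValueError(f"invalid step {chrom}:[{start},{end})")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        steps = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedGraph steps on {chrom}")
            steps[chrom] = (starts, ends, values)
        return cls(steps)

    @classmethod
    def uniform(cls, chrom_sizes: Mapping[str, int], value: float) -> "SignalTrack":
        """A constant-value track covering each chromosome end to end."""
        return cls.from_records(
            [(c, 0, size, value) for c, size in chrom_sizes.items()]
        )

    def to_records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self.steps):
            starts, ends, values = self.steps[chrom]
            out.extend(
                (chrom, int(s), int(e), float(v))
                for s, e, v in zip(starts, ends, values)
            )
        return out

    def region_signal(self, region: GenomicInterval) -> float:
        """Total signal over a region: sum of value x overlap-length (CPM*bp)."""
        if region.chrom not in self.steps:
            return 0.0
        starts, ends, values = self.steps[region.chrom]
        if len(starts) == 0:
            return 0.0
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], region.start)
        e = np.minimum(ends[lo:hi], region.end)
        lengths = np.maximum(e - s, 0)
        return float(np.dot(lengths, values[lo:hi]))


def region_signal(track: SignalTrack, region: GenomicInterval) -> float:
    """Functional alias for :meth:`SignalTrack.region_signal`."""
    return track.region_signal(region)


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its body interval, strand-resolved TSS and biotype.

    ``tss`` is the transcription start of the longest isoform (its 5' end:
    ``start`` on "+", ``end - 1`` on "-").  ``longest_isoform_length`` feeds
    FPKM conversion.
    """

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    tss: int
    biotype: str
    longest_isoform_length: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body {self.interval} for {self.gene_id}"
            )
        if self.longest_isoform_length < 1:
            raise ValueError(f"longest_isoform_length < 1 for {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.interval.strand


def tss_from_interval(iv: GenomicInterval) -> int:
    """Strand-resolved TSS: ``start`` on "+", ``end - 1`` on "-" or ".". """
    return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class BindingSite:
    """An apoER-alpha ChIP-seq peak (aERBS), optionally carrying the
    epigenetic class label of the region (e.g. "EnhT")."""

    interval: GenomicInterval
    epigenetic_class: str | None = None


@dataclass(frozen=True)
class InteractionPair:
    """A ChIA-PET pair of interacting anchors with a pair-count multiplicity."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    experiment_id: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("interaction count must be >= 1")
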