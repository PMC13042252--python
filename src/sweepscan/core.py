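"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open internally.  VCF input is 1-based
(converted on read); BED input is already 0-based half-open; tabular
output is 1-based inclusive, the convention population-genetic scan
results are usually reported in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a masked/unknown diploid dosage.
MISSING = -1

#: The five sweep classes, in the fixed order used for posteriors and
#: confusion matrices throughout the package.
CLASS_LABELS = ("neutral", "hard-linked", "soft-linked", "hard", "soft")

#: Indices of the sweep (positive) classes within CLASS_LABELS.
SWEEP_CLASS_INDICES = (3, 4)


def to_one_based_inclusive(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def from_one_based_inclusive(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic region (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenotypeMatrix:
    """Unphased diploid dosages at segregating sites within an interval.

    ``dosages`` is an (individuals x sites) integer array with values in
    {0, 1, 2, MISSING}; ``positions`` are 0-based site coordinates, strictly
    increasing and contained in ``interval``.
    """

    interval: GenomicInterval
    positions: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        if self.dosages.shape[1] != self.positions.shape[0]:
            raise ValueError("positions/dosages site-count mismatch")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if (
                self.positions[0] < self.interval.start
                or self.positions[-1] >= self.interval.end
            ):
                raise ValueError("positions must lie inside interval")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def slice(self, sub: GenomicInterval) -> "GenotypeMatrix":
        """Restrict to sites falling in ``sub`` (half-open)."""
        lo = np.searchsorted(self.positions, sub.start, side="left")
        hi = np.searchsorted(self.positions, sub.end, side="left")
        return GenotypeMatrix(sub, self.positions[lo:hi], self.dosages[:, lo:hi])


@dataclass
class RecombinationMap:
    """Per-interval crossover rates (per bp per generation)."""

    intervals: list[tuple[GenomicInterval, float]]

    def __post_init__(self) -> None:
        for iv, rate in self.intervals:
            if rate < 0:
                raise ValueError(f"negative recombination rate at {iv}")
        self.intervals = sorted(self.intervals, key=lambda t: (t[0].chrom, t[0].start))
        by_chrom: dict[str, int] = {}
        for iv, _ in self.intervals:
            prev_end = by_chrom.get(iv.chrom, -1)
            if iv.start < prev_end:
                raise ValueError(f"overlapping recombination intervals at {iv}")
            by_chrom[iv.chrom] = iv.end


@dataclass
class MaskProfile:
    """Inaccessible subintervals of a window, e.g. low-quality regions."""

    window: GenomicInterval
    masked_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.masked_intervals, key=lambda iv: iv.start)
        prev_end = self.window.start
        for iv in ivs:
            if iv.chrom != self.window.chrom:
                raise ValueError("masked interval on wrong chromosome")
            if iv.start < self.window.start or iv.end > self.window.end:
                raise ValueError("masked interval outside window")
            if iv.start < prev_end and iv is not ivs[0]:
                raise ValueError("masked intervals overlap")
            prev_end = iv.end
        self.masked_intervals = ivs

    @property
    def masked_fraction(self) -> float:
        total = sum(len(iv) for iv in self.masked_intervals)
        return total / len(self.window)

    def rescale_to(self, window: GenomicInterval) -> "MaskProfile":
        """Map masked intervals proportionally onto a new window."""
        scale = len(window) / len(self.window)
        ivs = []
        for iv in self.masked_intervals:
            s = window.start + int(round((iv.start - self.window.start) * scale))
            e = window.start + int(round((iv.end - self.window.start) * scale))
            if e > s:
                ivs.append(GenomicInterval(window.chrom, s, min(e, window.end)))
        return MaskProfile(window, ivs)


@dataclass
class DemographicModel:
    """Piecewise-constant diploid effective population size history.

    Epochs are (start_time_in_generations_before_present, Ne) pairs; the
    first epoch must start at time 0 and times must strictly increase.
    """

    epochs: list[tuple[float, float]]
    generation_time: float = 0.067

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        times = [t for t, _ in self.epochs]
        if times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch times must be strictly increasing")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("Ne must be positive")

    @property
    def current_ne(self) -> float:
        return self.epochs[0][1]

    @classmethod
    def constant(cls, ne: float, generation_time: float = 0.067) -> "DemographicModel":
        return cls(epochs=[(0.0, ne)], generation_time=generation_time)
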