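"""Genome-wide scan: sliding windows, filters, sweep calls, intersections.

The scan slides a feature window (default 2.75 Mb) along each chromosome
in steps of one subwindow (default 250 kb); each feature window's
classification is attributed to its central subwindow.  Two
classification-independent filters mirror the study design: windows whose
central subwindow has zero weighted recombination rate are dropped (the
spatial LD signal is uninformative without recombination), and windows
whose feature footprint is masked above a threshold fraction (default
0.85, strict inequality) are dropped as low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import CLASS_LABELS, GenomicInterval, MaskProfile, RecombinationMap
from .classifier import ClassPosterior
from .featurize import DEFAULT_SUBWINDOWS

#: decision vocabulary for a scanned window at a threshold
DECISIONS = ("neutral", "hard-linked", "soft-linked", "sweep-hard", "sweep-soft", "uncertain")


@dataclass
class SweepCall:
    """One scanned window's classification and downstream annotations."""

    window: GenomicInterval  # central subwindow (the classified unit)
    feature_window: GenomicInterval
    posterior: ClassPosterior
    decision: str
    q_value: Optional[float] = None

    @property
    def combined_sweep_prob(self) -> float:
        return self.posterior.combined_sweep_prob

    @property
    def is_sweep(self) -> bool:
        return self.decision in ("sweep-hard", "sweep-soft")


def enumerate_windows(
    chrom_lengths: dict[str, int],
    window_len: int,
    step: int,
    k: int = DEFAULT_SUBWINDOWS,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All (feature window, central subwindow) pairs on the window grid.

    Windows start at 0, step, 2*step, ... and must fit entirely on the
    chromosome; chromosomes shorter than the window contribute none.
    """
    if window_len % k != 0:
        raise ValueError("window_len must be divisible by k")
    if step <= 0:
        raise ValueError("step must be positive")
    sub_len = window_len // k
    central_off = ((k - 1) // 2) * sub_len
    out = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        start = 0
        while start + window_len <= length:
            fw = GenomicInterval(chrom, start, start + window_len)
            cw = GenomicInterval(
                chrom, start + central_off, start + central_off + sub_len
            )
            out.append((fw, cw))
            start += step
    return out


def weighted_recomb_rate(rmap: RecombinationMap, interval: GenomicInterval) -> float:
    """Overlap-weighted mean rate over ``interval``; uncovered bp count as 0."""
    total = 0.0
    for iv, rate in rmap.intervals:
        ol = iv.overlap_length(interval)
        if ol:
            total += rate * ol
    return total / len(interval)


def masked_fraction_of(masks: Sequence[MaskProfile] | MaskProfile | None,
                       interval: GenomicInterval) -> float:
    """Fraction of ``interval`` covered by the union of mask intervals.

    Profiles of overlapping windows may carry clipped copies of the same
    underlying mask regions, so spans are union-merged before measuring.
    """
    if masks is None:
        return 0.0
    if isinstance(masks, MaskProfile):
        masks = [masks]
    spans = []
    for profile in masks:
        for iv in profile.masked_intervals:
            if iv.chrom == interval.chrom and iv.overlap_length(interval):
                spans.append(
                    (max(iv.start, interval.start), min(iv.end, interval.end))
                )
    if not spans:
        return 0.0
    spans.sort()
    covered = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return covered / len(interval)


@dataclass
class FilterReport:
    n_input: int = 0
    n_zero_recomb: int = 0
    n_overmasked: int = 0
    n_retained: int = 0


def filter_windows(
    windows: Sequence[tuple[GenomicInterval, GenomicInterval]],
    rmap: Optional[RecombinationMap],
    masks: Sequence[MaskProfile] | None,
    max_masked_fraction: float = 0.85,
    recomb_footprint: str = "central",
    mask_footprint: str = "feature",
) -> tuple[list[tuple[GenomicInterval, GenomicInterval]], FilterReport]:
    """Apply the zero-recombination and over-masking filters.

    ``recomb_footprint`` / ``mask_footprint`` select whether each filter is
    evaluated over the central subwindow or the full feature window
    (defaults: recombination on the classified central subwindow, masking
    on the full featurization footprint).  The masking filter drops
    strictly above ``max_masked_fraction``.
    """
    if not 0 <= max_masked_fraction <= 1:
        raise ValueError("max_masked_fraction must be in [0, 1]")
    report = FilterReport(n_input=len(windows))
    retained = []
    for fw, cw in windows:
        if rmap is not None:
            target = cw if recomb_footprint == "central" else fw
            if weighted_recomb_rate(rmap, target) == 0:
                report.n_zero_recomb += 1
                continue
        if masks is not None:
            target = fw if mask_footprint == "feature" else cw
            if masked_fraction_of(masks, target) > max_masked_fraction:
                report.n_overmasked += 1
                continue
        retained.append((fw, cw))
    report.n_retained = len(retained)
    return retained, report


def call_sweeps(
    posteriors: Sequence[ClassPosterior], threshold: Optional[float]
) -> list[str]:
    """Decision per window at a combined-sweep-probability threshold.

    If the argmax class is hard or soft, the window is a sweep (typed by
    the larger of the two sweep posteriors, ties toward soft) when
    p_hard + p_soft >= threshold, else uncertain.  Otherwise the decision
    is the argmax class.  threshold None means pure argmax.
    """
    if threshold is not None and not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1] or None")
    out = []
    for post in posteriors:
        arr = post.as_array()
        arg = int(arr.argmax())
        label = CLASS_LABELS[arg]
        if label in ("hard", "soft"):
            if threshold is None or post.combined_sweep_prob >= threshold:
                kind = "hard" if post.p_hard > post.p_soft else "soft"
                out.append(f"sweep-{kind}")
            else:
                out.append("uncertain")
        else:
            out.append(label)
    return out


@dataclass
class IntersectionResult:
    """Sweep-call overlap structure across population samples."""

    calls_per_window: dict[tuple[str, int, int], frozenset[str]]
    intersection_counts: dict[frozenset, int] = field(default_factory=dict)

    @property
    def shared(self) -> list[tuple[str, int, int]]:
        return [w for w, pops in self.calls_per_window.items() if len(pops) > 1]

    @property
    def population_specific(self) -> list[tuple[str, int, int]]:
        return [w for w, pops in self.calls_per_window.items() if len(pops) == 1]


def intersect_populations(
    calls_by_population: dict[str, Sequence[SweepCall]],
    threshold: float,
) -> IntersectionResult:
    """Window-keyed sweep-call intersections across populations.

    All populations must share the same central-subwindow grid.  A window
    enters a population's sweep set when its decision is a sweep and its
    combined probability reaches ``threshold``.
    """
    grids = {
        pop: tuple((c.window.chrom, c.window.start, c.window.end) for c in calls)
        for pop, calls in calls_by_population.items()
    }
    ref = None
    for pop, grid in grids.items():
        if ref is None:
            ref = grid
        elif grid != ref:
            raise ValueError(f"window grid of {pop!r} differs from the reference grid")
    per_window: dict[tuple[str, int, int], set[str]] = {}
    for pop, calls in calls_by_population.items():
        for call in calls:
            if call.is_sweep and call.combined_sweep_prob >= threshold:
                key = (call.window.chrom, call.window.start, call.window.end)
                per_window.setdefault(key, set()).add(pop)
    frozen = {w: frozenset(p) for w, p in per_window.items()}
    counts: dict[frozenset, int] = {}
    for pops in frozen.values():
        counts[pops] = counts.get(pops, 0) + 1
    return IntersectionResult(calls_per_window=frozen, intersection_counts=counts)
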