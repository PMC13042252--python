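"""Readers and writers for the formats the pipeline touches.

VCF is read through cyvcf2; BED and the small TSV side files (recombination
map, demographic history, gene -> GO map) through pandas.  Output scan
tables are 1-based inclusive, matching how scan windows are conventionally
reported; everything internal stays 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    DemographicModel,
    GenomicInterval,
    GenotypeMatrix,
    MaskProfile,
    RecombinationMap,
    to_one_based_inclusive,
)
from .classifier import ClassPosterior
from .scan import SweepCall

SCAN_COLUMNS = [
    "chrom",
    "start",
    "end",
    "predicted_class",
    "prob_neutral",
    "prob_hard_linked",
    "prob_soft_linked",
    "prob_hard",
    "prob_soft",
    "combined_sweep_prob",
    "q_value",
]


def read_vcf_window(
    path: str, interval: GenomicInterval, min_gq: int = 20
) -> GenotypeMatrix:
    """Read biallelic SNP dosages for one genomic interval.

    Genotypes with GQ below ``min_gq`` become MISSING (records without a
    GQ field pass); indels and non-biallelic records are skipped; sites
    where every genotype is missing are dropped.  An interval overlapping
    no records yields an empty matrix.
    """
    if min_gq < 0:
        raise ValueError("min_gq must be nonnegative")
    vcf = VCF(path)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    try:
        for variant in vcf:
            pos0 = variant.POS - 1  # VCF is 1-based
            if variant.CHROM != interval.chrom or not interval.contains(pos0):
                continue
            if len(variant.ALT) != 1 or not variant.is_snp:
                continue
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 gts012=False -> 3=hom-alt)
            gts = variant.genotype.array()
            dos = np.where(
                (gts[:, 0] < 0) | (gts[:, 1] < 0), MISSING, gts[:, 0] + gts[:, 1]
            ).astype(np.int8)
            gqs = variant.gt_quals
            if gqs is not None and len(gqs) == len(dos) and not np.all(gqs < 0):
                low = (gqs >= 0) & (gqs < min_gq)
                dos[low] = MISSING
            if np.all(dos == MISSING):
                continue
            positions.append(pos0)
            columns.append(dos)
    finally:
        vcf.close()
    if not positions:
        return GenotypeMatrix(interval, np.empty(0, dtype=np.int64), np.empty((0, 0)))
    dosages = np.column_stack(columns)
    return GenotypeMatrix(interval, np.array(positions), dosages)


def vcf_chrom_lengths(path: str) -> dict[str, int]:
    """Chromosome lengths from the VCF header contigs."""
    vcf = VCF(path)
    try:
        return dict(zip(vcf.seqnames, vcf.seqlens))
    finally:
        vcf.close()


def read_recomb_map(path: str) -> RecombinationMap:
    """TSV with columns chrom, start, end, rate (per bp per generation)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "rate"}
    if not required <= set(df.columns):
        raise ValueError(f"recombination map needs columns {sorted(required)}")
    intervals = [
        (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), float(r.rate))
        for r in df.itertuples()
    ]
    return RecombinationMap(intervals)


def read_demography(path: str, generation_time: float = 0.067) -> DemographicModel:
    """TSV of (time_generations, Ne) rows, earliest epoch first."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "time_generations" in cols and "Ne" in cols:
        epochs = [(float(r.time_generations), float(r.Ne)) for r in df.itertuples()]
    else:  # headerless two-column file
        df = pd.read_csv(path, sep="\t", header=None)
        epochs = [(float(r[1]), float(r[2])) for r in df.itertuples()]
    return DemographicModel(epochs=epochs, generation_time=generation_time)


def read_mask_bed(path: str) -> list[GenomicInterval]:
    """BED (0-based half-open) of masked intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        GenomicInterval(str(r[1]), int(r[2]), int(r[3])) for r in df.itertuples()
    ]


def mask_profiles_for_windows(
    masked: Sequence[GenomicInterval],
    windows: Sequence[GenomicInterval],
) -> list[MaskProfile]:
    """Clip a genome-wide mask BED into per-window MaskProfiles."""
    out = []
    for w in windows:
        ivs = []
        for m in masked:
            ol = m.overlap_length(w)
            if ol:
                ivs.append(
                    GenomicInterval(w.chrom, max(m.start, w.start), min(m.end, w.end))
                )
        out.append(MaskProfile(window=w, masked_intervals=ivs))
    return out


def read_gene_bed(path: str) -> list[tuple[str, GenomicInterval]]:
    """BED4 of gene intervals: chrom, start, end, gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene BED needs 4 columns (chrom, start, end, name)")
    return [
        (str(r[4]), GenomicInterval(str(r[1]), int(r[2]), int(r[3])))
        for r in df.itertuples()
    ]


def read_go_map(path: str) -> dict[str, set[str]]:
    """TSV with columns gene_id, term (one association per row)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term"} <= set(df.columns):
        raise ValueError("GO map needs columns gene_id, term")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.gene_id), set()).add(str(r.term))
    return out


def read_gene_list(path: str) -> set[str]:
    """One gene id per line (e.g. the insecticide-resistance set)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_scan_table(calls: Sequence[SweepCall], path: str) -> str:
    """Write sweep calls as a TSV (1-based inclusive coordinates)."""
    if not calls:
        raise ValueError("no calls to write")
    rows = []
    for call in calls:
        start1, end1 = to_one_based_inclusive(call.window.start, call.window.end)
        post = call.posterior
        rows.append(
            {
                "chrom": call.window.chrom,
                "start": start1,
                "end": end1,
                "predicted_class": call.decision,
                "prob_neutral": post.p_neutral,
                "prob_hard_linked": post.p_hard_linked,
                "prob_soft_linked": post.p_soft_linked,
                "prob_hard": post.p_hard,
                "prob_soft": post.p_soft,
                "combined_sweep_prob": post.combined_sweep_prob,
                "q_value": "" if call.q_value is None else call.q_value,
            }
        )
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def write_intersections_table(
    calls_by_population: dict[str, Sequence[SweepCall]],
    threshold: float,
    path: str,
) -> str:
    """Window-per-row TSV of per-population sweep-call bits.

    Rows cover every window in any population's sweep set at ``threshold``
    (1-based inclusive coordinates); one 0/1 column per population plus
    the count of populations calling the window.
    """
    from .scan import intersect_populations

    result = intersect_populations(calls_by_population, threshold)
    pops = sorted(calls_by_population)
    rows = []
    for (chrom, start, end), called in sorted(result.calls_per_window.items()):
        start1, end1 = to_one_based_inclusive(start, end)
        row = {"chrom": chrom, "start": start1, "end": end1}
        for pop in pops:
            row[pop] = int(pop in called)
        row["n_populations"] = len(called)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", *pops, "n_populations"])
    df.to_csv(path, sep="\t", index=False)
    return path


def read_scan_table(path: str) -> list[SweepCall]:
    """Read a scan TSV back into SweepCall objects."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    calls = []
    for r in df.itertuples():
        window = GenomicInterval(str(r.chrom), int(r.start) - 1, int(r.end))
        post = ClassPosterior(
            p_neutral=float(r.prob_neutral),
            p_hard_linked=float(r.prob_hard_linked),
            p_soft_linked=float(r.prob_soft_linked),
            p_hard=float(r.prob_hard),
            p_soft=float(r.prob_soft),
        )
        q = getattr(r, "q_value", None)
        q = None if q is None or (isinstance(q, float) and np.isnan(q)) else float(q)
        calls.append(
            SweepCall(
                window=window,
                feature_window=window,
                posterior=post,
                decision=str(r.predicted_class),
                q_value=q,
            )
        )
    return calls
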