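"""Labeled coalescent training data and fully synthetic genome fixtures.

The training corpus emulates the study design used for simulation-trained
sweep classification: five classes of windowed diploid genotype data —
neutral, hard sweep, soft sweep, and their "linked" (soft-shoulder)
counterparts — generated under a piecewise-constant demographic history
with per-replicate mutation, recombination, and selection parameters drawn
from broad priors.

Class geometry: a feature window is divided into ``n_subwindows`` (odd,
default 11) adjacent subwindows.  A replicate whose selected site falls in
the central subwindow is labeled ``hard`` or ``soft``; in any other
subwindow, ``hard-linked`` or ``soft-linked``; with no selected site,
``neutral``.

Sweep replicates are simulated with msprime's structured-coalescent sweep
model: the beneficial allele fixes ``tau`` coalescent units (of 4N
generations, N the most recent epoch size) before sampling; soft sweeps
start from a standing variant at frequency ``f0``.  A limitation of the
backward sweep machinery is that demographic events may not fall inside
the sweep phase; sweep classes therefore require histories whose epoch
boundaries predate the sweep, and the scaled experiment defaults below use
a constant size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import msprime
import numpy as np

from .core import (
    MISSING,
    CLASS_LABELS,
    DemographicModel,
    GenomicInterval,
    GenotypeMatrix,
    MaskProfile,
)

SWEEP_KINDS = ("hard", "soft")


@dataclass(frozen=True)
class SimPriors:
    """Prior distributions for one simulation replicate's parameters.

    Defaults are the full-scale study conditions: mu uniform on
    [8.82e-10, 8.82e-9] (mean 4.85e-9), r exponential with mean 4.85e-9
    truncated at 3x the mean, s log-uniform on [0.005, 0.05], fixation
    time tau uniform on [0, 0.001] (coalescent units of 4N), standing
    frequency f0 uniform on [0, 0.05], over a 2.75 Mb window of 11
    subwindows.
    """

    mu_low: float = 8.82e-10
    mu_high: float = 8.82e-9
    r_mean: float = 4.85e-9
    r_cap_factor: float = 3.0
    s_low: float = 0.005
    s_high: float = 0.05
    tau_high: float = 0.001
    f0_high: float = 0.05
    L: int = 2_750_000
    n: int = 20
    n_subwindows: int = 11

    def __post_init__(self) -> None:
        if not (0 < self.mu_low < self.mu_high):
            raise ValueError("need 0 < mu_low < mu_high")
        if self.r_mean <= 0 or self.r_cap_factor <= 0:
            raise ValueError("r_mean and r_cap_factor must be positive")
        if not (0 < self.s_low < self.s_high):
            raise ValueError("need 0 < s_low < s_high")
        if self.tau_high <= 0:
            raise ValueError("tau_high must be positive")
        if not (0 < self.f0_high <= 1):
            raise ValueError("need 0 < f0_high <= 1")
        if self.n_subwindows % 2 != 1:
            raise ValueError("n_subwindows must be odd")
        if self.L % self.n_subwindows != 0:
            raise ValueError("L must be divisible by n_subwindows")

    @property
    def central_subwindow(self) -> int:
        return (self.n_subwindows - 1) // 2

    @property
    def subwindow_length(self) -> int:
        return self.L // self.n_subwindows


@dataclass(frozen=True)
class SimParams:
    """One replicate's drawn parameters and class label."""

    class_label: str
    mu: float
    r: float
    s: float
    tau: float
    f0: float
    sweep_subwindow: Optional[int]
    sweep_pos: Optional[int]
    seed: int

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        selected = self.class_label != "neutral"
        if selected != (self.s > 0):
            raise ValueError("s > 0 exactly for selected classes")
        soft = self.class_label in ("soft", "soft-linked")
        if soft != (self.f0 > 0):
            raise ValueError("f0 > 0 exactly for soft classes")
        if selected and (self.sweep_subwindow is None or self.sweep_pos is None):
            raise ValueError("selected classes need a sweep location")


@dataclass
class LabeledReplicate:
    params: SimParams
    genotypes: GenotypeMatrix
    mask: Optional[MaskProfile] = None

    @property
    def label(self) -> str:
        return self.params.class_label


def label_for(sweep_kind: Optional[str], sweep_subwindow: Optional[int], central: int) -> str:
    """Class label as a pure function of sweep type and subwindow index."""
    if sweep_kind is None:
        return "neutral"
    if sweep_kind not in SWEEP_KINDS:
        raise ValueError(f"unknown sweep kind {sweep_kind!r}")
    return sweep_kind if sweep_subwindow == central else f"{sweep_kind}-linked"


def draw_truncated_exponential(mean: float, cap_factor: float, rng: np.random.Generator) -> float:
    # Rejection sampling keeps the exponential shape below the cap; the
    # realized mean is therefore below the nominal mean parameter.
    while True:
        x = rng.exponential(mean)
        if x <= cap_factor * mean:
            return x


def draw_sim_params(
    class_label: str,
    sweep_subwindow: Optional[int],
    priors: SimPriors,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> SimParams:
    """Draw one replicate's parameters from the priors.

    mu ~ U(mu_low, mu_high); r ~ truncated Exponential(r_mean); for
    selected classes s ~ log-uniform on [s_low, s_high] and tau ~
    U(0, tau_high); for soft classes f0 ~ U(0, f0_high); the selected site
    is uniform within the designated subwindow.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    selected = class_label != "neutral"
    central = priors.central_subwindow
    if selected:
        if sweep_subwindow is None or not (0 <= sweep_subwindow < priors.n_subwindows):
            raise ValueError("selected classes need sweep_subwindow in range")
        expected = label_for(
            "soft" if "soft" in class_label else "hard", sweep_subwindow, central
        )
        if expected != class_label:
            raise ValueError(
                f"sweep_subwindow {sweep_subwindow} inconsistent with {class_label!r}"
            )
    elif sweep_subwindow is not None:
        raise ValueError("neutral draws take no sweep_subwindow")

    mu = rng.uniform(priors.mu_low, priors.mu_high)
    r = draw_truncated_exponential(priors.r_mean, priors.r_cap_factor, rng)
    s = tau = f0 = 0.0
    sweep_pos = None
    if selected:
        s = math.exp(rng.uniform(math.log(priors.s_low), math.log(priors.s_high)))
        tau = rng.uniform(0.0, priors.tau_high)
        if "soft" in class_label:
            f0 = rng.uniform(0.0, priors.f0_high)
            f0 = max(f0, 1e-9)  # degenerate f0=0 would be a hard sweep
        w = priors.subwindow_length
        sweep_pos = int(rng.integers(sweep_subwindow * w, (sweep_subwindow + 1) * w))
    if seed is None:
        seed = int(rng.integers(1, 2**31 - 1))
    return SimParams(
        class_label=class_label,
        mu=mu,
        r=r,
        s=s,
        tau=tau,
        f0=f0,
        sweep_subwindow=sweep_subwindow if selected else None,
        sweep_pos=sweep_pos,
        seed=seed,
    )


def _msprime_demography(model: DemographicModel) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=model.epochs[0][1])
    for time, ne in model.epochs[1:]:
        dem.add_population_parameters_change(time=time, initial_size=ne)
    return dem


def simulate_replicate(
    params: SimParams,
    demography: DemographicModel,
    L: Optional[int] = None,
    n: Optional[int] = None,
    priors: Optional[SimPriors] = None,
) -> GenotypeMatrix:
    """Simulate one replicate under its drawn parameters.

    Neutral classes use the standard coalescent with recombination under
    the demographic model; sweep classes insert a genic-selection sweep at
    ``sweep_pos`` completing ``tau * 4N`` generations before sampling.
    Haplotypes are paired into unphased diploid dosages; only biallelic
    sites are retained.
    """
    if priors is not None:
        L = L or priors.L
        n = n or priors.n
    if L is None or n is None:
        raise ValueError("region length L and sample size n are required")
    ne0 = demography.current_ne
    dem = _msprime_demography(demography)
    if params.class_label == "neutral":
        model = "hudson"
    else:
        start = params.f0 if params.f0 > 0 else 1.0 / (2 * ne0)
        sweep = msprime.SweepGenicSelection(
            position=min(params.sweep_pos, L - 1),
            start_frequency=start,
            end_frequency=1.0 - 1.0 / (2 * ne0),
            s=params.s,
            dt=1.0 / (40 * ne0),
        )
        model = [
            msprime.StandardCoalescent(duration=params.tau * 4 * ne0),
            sweep,
            msprime.StandardCoalescent(),
        ]
    try:
        ts = msprime.sim_ancestry(
            samples=n,
            sequence_length=L,
            recombination_rate=params.r,
            demography=dem,
            model=model,
            random_seed=params.seed % (2**31 - 2) + 1,
        )
        ts = msprime.sim_mutations(
            ts, rate=params.mu, random_seed=(params.seed + 1) % (2**31 - 2) + 1
        )
    except Exception as exc:  # pragma: no cover - engine failure path
        raise RuntimeError(f"coalescent engine failed for {params!r}") from exc
    g = ts.genotype_matrix()  # sites x haplotypes, ancestral=0
    positions = ts.tables.sites.position.astype(np.int64)
    biallelic = (g <= 1).all(axis=1)
    g = g[biallelic]
    positions = positions[biallelic]
    dosages = (g[:, 0::2] + g[:, 1::2]).T.astype(np.int8)  # individuals x sites
    interval = GenomicInterval("sim", 0, int(L))
    return GenotypeMatrix(interval, positions, dosages)


def rescale_for_region(priors: SimPriors, new_L: int) -> SimPriors:
    """Rescale the selection prior for a different region length.

    Multiplying the s bounds by new_L / L keeps the ratio of the sweep's
    LD footprint (which scales as s/r bp) to the window length constant,
    so simulated sweeps occupy the same fraction of the window.
    """
    if new_L <= 0:
        raise ValueError("new_L must be positive")
    factor = new_L / priors.L
    return replace(
        priors, L=int(new_L), s_low=priors.s_low * factor, s_high=priors.s_high * factor
    )


def apply_mask_transfer(
    replicate: GenotypeMatrix,
    mask_library: Sequence[MaskProfile],
    rng: np.random.Generator,
    params: Optional[SimParams] = None,
) -> LabeledReplicate:
    """Impose an empirical-style missingness profile on a simulated window.

    One profile is chosen uniformly from the library, its masked intervals
    are rescaled proportionally to the replicate's length, and variants
    falling inside masked intervals are removed — mirroring how masked
    empirical sites are invisible to the scan.
    """
    if not mask_library:
        raise ValueError("mask library is empty")
    profile = mask_library[int(rng.integers(len(mask_library)))]
    scaled = profile.rescale_to(replicate.interval)
    keep = np.ones(replicate.n_sites, dtype=bool)
    for iv in scaled.masked_intervals:
        keep &= ~(
            (replicate.positions >= iv.start) & (replicate.positions < iv.end)
        )
    gm = GenotypeMatrix(
        replicate.interval, replicate.positions[keep], replicate.dosages[:, keep]
    )
    return LabeledReplicate(params=params, genotypes=gm, mask=scaled)


def _spawn_seeds(seed: int, count: int) -> np.ndarray:
    """Per-replicate seeds below 2^31 from one master seed."""
    return np.random.SeedSequence(seed).generate_state(count) % (2**31 - 1)


def build_corpus(
    priors: SimPriors,
    demography: DemographicModel,
    n_per_subwindow: int,
    mask_library: Optional[Sequence[MaskProfile]] = None,
    seed: int = 0,
    n_neutral: Optional[int] = None,
) -> list[LabeledReplicate]:
    """The full per-subwindow corpus design.

    For each sweep kind (hard, soft) and each of the ``n_subwindows``
    subwindows, ``n_per_subwindow`` replicates are simulated with the
    selected site uniform within that subwindow; labels follow
    :func:`label_for`.  ``n_neutral`` neutral replicates (default
    ``n_per_subwindow``) complete the corpus.
    """
    if n_per_subwindow < 1:
        raise ValueError("n_per_subwindow must be >= 1")
    if n_neutral is None:
        n_neutral = n_per_subwindow
    k = priors.n_subwindows
    total = 2 * k * n_per_subwindow + n_neutral
    seeds = _spawn_seeds(seed, 2 * total)
    out: list[LabeledReplicate] = []
    idx = 0

    def one(class_label: str, sub: Optional[int]) -> LabeledReplicate:
        nonlocal idx
        rng = np.random.default_rng(int(seeds[idx]))
        params = draw_sim_params(class_label, sub, priors, rng, seed=int(seeds[idx + 1]))
        idx += 2
        gm = simulate_replicate(params, demography, priors=priors)
        if mask_library:
            return apply_mask_transfer(gm, mask_library, rng, params=params)
        return LabeledReplicate(params=params, genotypes=gm)

    for kind in SWEEP_KINDS:
        for sub in range(k):
            label = label_for(kind, sub, priors.central_subwindow)
            for _ in range(n_per_subwindow):
                out.append(one(label, sub))
    for _ in range(n_neutral):
        out.append(one("neutral", None))
    return out


def build_balanced_corpus(
    priors: SimPriors,
    demography: DemographicModel,
    n_per_class: int,
    mask_library: Optional[Sequence[MaskProfile]] = None,
    seed: int = 0,
) -> list[LabeledReplicate]:
    """Directly balanced corpus: ``n_per_class`` replicates per class.

    Distributionally equivalent to subsampling the per-subwindow corpus of
    :func:`build_corpus` to balanced classes: hard/soft replicates place
    the selected site in the central subwindow, linked replicates in a
    uniformly chosen non-central subwindow.  This is the economical
    sampler for scaled-down experiments, where the per-subwindow design
    would spend most simulations on the (majority) linked pools.
    """
    k = priors.n_subwindows
    central = priors.central_subwindow
    seeds = _spawn_seeds(seed, 10 * n_per_class)
    out: list[LabeledReplicate] = []
    idx = 0
    non_central = [j for j in range(k) if j != central]
    for label in CLASS_LABELS:
        for _ in range(n_per_class):
            rng = np.random.default_rng(int(seeds[idx]))
            if label == "neutral":
                sub = None
            elif label in SWEEP_KINDS:
                sub = central
            else:
                sub = int(rng.choice(non_central))
            params = draw_sim_params(label, sub, priors, rng, seed=int(seeds[idx + 1]))
            idx += 2
            gm = simulate_replicate(params, demography, priors=priors)
            if mask_library:
                out.append(apply_mask_transfer(gm, mask_library, rng, params=params))
            else:
                out.append(LabeledReplicate(params=params, genotypes=gm))
    return out


def assemble_train_test(
    corpus: Sequence[LabeledReplicate],
    n_train_per_class: int,
    n_test_per_class: int,
    rng: np.random.Generator,
) -> tuple[list[LabeledReplicate], list[LabeledReplicate]]:
    """Balanced, disjoint train/test split by subsampling class pools."""
    pools: dict[str, list[LabeledReplicate]] = {c: [] for c in CLASS_LABELS}
    for rep in corpus:
        pools[rep.label].append(rep)
    need = n_train_per_class + n_test_per_class
    train: list[LabeledReplicate] = []
    test: list[LabeledReplicate] = []
    for label in CLASS_LABELS:
        pool = pools[label]
        if len(pool) < need:
            raise ValueError(
                f"class {label!r} pool has {len(pool)} replicates, needs {need}"
            )
        order = rng.permutation(len(pool))
        train.extend(pool[i] for i in order[:n_train_per_class])
        test.extend(pool[i] for i in order[n_train_per_class:need])
    return train, test


# ---------------------------------------------------------------------------
# Synthetic genome fixture
# ---------------------------------------------------------------------------


@dataclass
class FixtureSweep:
    chrom: str
    window_start: int  # aligned to the scan grid; sweep site centered here
    kind: str  # "hard" or "soft"


@dataclass
class FixtureConfig:
    """Configuration of a fully synthetic scan-ready genome.

    The genome is assembled from adjacent, independently simulated tiles of
    ``window_len`` bp; tiles containing an implanted sweep are simulated
    under the sweep model with the selected site at the tile center, so the
    scan window aligned with that tile carries the sweep in its central
    subwindow.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_650_000, "chr2": 1_650_000, "chr3": 1_100_000}
    )
    window_len: int = 275_000
    n_subwindows: int = 11
    sweeps: list[FixtureSweep] = field(default_factory=list)
    n_genes_per_chrom: int = 30
    n_go_terms: int = 8
    masked_fraction_typical: float = 0.1
    # one window per genome is masked above the scan's dropping threshold
    overmasked_window: Optional[tuple[str, int]] = None
    overmasked_fraction: float = 0.9
    zero_rate_interval: Optional[tuple[str, int, int]] = None
    uniform_recomb_rate: float = 4.85e-9
    priors: Optional[SimPriors] = None
    demography: Optional[DemographicModel] = None

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length % self.window_len != 0:
                raise ValueError(
                    f"{chrom} length {length} not a multiple of window_len"
                )
        for sw in self.sweeps:
            if sw.kind not in SWEEP_KINDS:
                raise ValueError(f"unknown sweep kind {sw.kind!r}")
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom!r}")
            if sw.window_start % self.window_len != 0:
                raise ValueError("sweep window_start must align to the tile grid")


@dataclass
class FixtureGenome:
    vcf_path: str
    mask_bed_path: str
    recomb_map_path: str
    gene_bed_path: str
    go_map_path: str
    truth: "pd.DataFrame"  # noqa: F821 - imported lazily below


def make_fixture_genome(config: FixtureConfig, seed: int, outdir: str) -> FixtureGenome:
    """Write a complete synthetic genome fixture (VCF + BEDs + TSVs).

    Outputs are plain text and byte-deterministic for a given seed; the
    truth table records every implanted sweep.
    """
    import os

    import pandas as pd

    priors = config.priors or SimPriors()
    demography = config.demography or DemographicModel.constant(1e5)
    if priors.L != config.window_len:
        priors = rescale_for_region(priors, config.window_len)
    sweeps_by_tile = {(s.chrom, s.window_start): s for s in config.sweeps}
    seeds = _spawn_seeds(seed, 4 * sum(
        length // config.window_len for length in config.chrom_lengths.values()
    ) + 8)
    idx = 0
    os.makedirs(outdir, exist_ok=True)
    vcf_path = os.path.join(outdir, "genome.vcf")
    n = priors.n
    sample_names = [f"ind{i}" for i in range(n)]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom, length in sorted(config.chrom_lengths.items()):
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    truth_rows = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        for tile_start in range(0, length, config.window_len):
            rng = np.random.default_rng(int(seeds[idx]))
            sweep = sweeps_by_tile.get((chrom, tile_start))
            if sweep is None:
                params = draw_sim_params("neutral", None, priors, rng, seed=int(seeds[idx + 1]))
            else:
                params = draw_sim_params(
                    sweep.kind, priors.central_subwindow, priors, rng, seed=int(seeds[idx + 1])
                )
                # strong, recent, *localizable* sweep centered in the tile:
                # the log-uniform median s keeps the hitchhiking footprint
                # (~s/r bp) comparable to the window, so the diversity
                # valley stays visible as a local feature; fixed mean rates
                # stabilize that geometry across tiles
                params = replace(
                    params,
                    s=math.sqrt(priors.s_low * priors.s_high),
                    r=priors.r_mean,
                    mu=(priors.mu_low + priors.mu_high) / 2,
                    tau=0.0,
                    sweep_pos=config.window_len // 2,
                )
                truth_rows.append(
                    {
                        "chrom": chrom,
                        "window_start": tile_start,
                        "window_end": tile_start + config.window_len,
                        "sweep_pos": tile_start + config.window_len // 2,
                        "kind": sweep.kind,
                    }
                )
            idx += 2
            gm = simulate_replicate(params, demography, priors=priors)
            for j, pos in enumerate(gm.positions):
                gts = "\t".join(gt_strings[int(d)] for d in gm.dosages[:, j])
                lines.append(
                    f"{chrom}\t{tile_start + int(pos) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}"
                )
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    # mask BED: a typical masked fraction per tile plus one over-masked window
    mask_rows = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        frac = config.masked_fraction_typical
        for tile_start in range(0, length, config.window_len):
            span = int(config.window_len * frac)
            if span > 0:
                mask_rows.append((chrom, tile_start, tile_start + span))
    if config.overmasked_window is not None:
        chrom, start = config.overmasked_window
        span = int(config.window_len * config.overmasked_fraction)
        mask_rows.append((chrom, start, start + span))
    mask_rows.sort()
    # merge overlapping/adjacent rows so downstream mask profiles are valid
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in mask_rows:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    mask_rows = merged
    mask_bed_path = os.path.join(outdir, "mask.bed")
    with open(mask_bed_path, "w") as fh:
        for chrom, s, e in mask_rows:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    # recombination map: uniform rate, optionally one zero-rate interval
    recomb_map_path = os.path.join(outdir, "recomb_map.tsv")
    with open(recomb_map_path, "w") as fh:
        fh.write("chrom\tstart\tend\trate\n")
        for chrom in sorted(config.chrom_lengths):
            length = config.chrom_lengths[chrom]
            zr = config.zero_rate_interval
            if zr is not None and zr[0] == chrom:
                _, zs, ze = zr
                if zs > 0:
                    fh.write(f"{chrom}\t0\t{zs}\t{config.uniform_recomb_rate}\n")
                fh.write(f"{chrom}\t{zs}\t{ze}\t0.0\n")
                if ze < length:
                    fh.write(f"{chrom}\t{ze}\t{length}\t{config.uniform_recomb_rate}\n")
            else:
                fh.write(f"{chrom}\t0\t{length}\t{config.uniform_recomb_rate}\n")

    # genes: evenly spaced; GO terms assigned round-robin
    rng = np.random.default_rng(int(seeds[idx]))
    gene_bed_path = os.path.join(outdir, "genes.bed")
    go_map_path = os.path.join(outdir, "go_map.tsv")
    gene_id = 0
    with open(gene_bed_path, "w") as fh_bed, open(go_map_path, "w") as fh_go:
        fh_go.write("gene_id\tterm\n")
        for chrom in sorted(config.chrom_lengths):
            length = config.chrom_lengths[chrom]
            spacing = length // config.n_genes_per_chrom
            gene_len = max(1000, spacing // 4)
            for g in range(config.n_genes_per_chrom):
                start = g * spacing + spacing // 4
                end = min(start + gene_len, length)
                name = f"gene{gene_id:04d}"
                fh_bed.write(f"{chrom}\t{start}\t{end}\t{name}\n")
                term = f"GO:{1000 + int(rng.integers(config.n_go_terms)):07d}"
                fh_go.write(f"{name}\t{term}\n")
                gene_id += 1

    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "window_start", "window_end", "sweep_pos", "kind"]
    )
    return FixtureGenome(
        vcf_path=vcf_path,
        mask_bed_path=mask_bed_path,
        recomb_map_path=recomb_map_path,
        gene_bed_path=gene_bed_path,
        go_map_path=go_map_path,
        truth=truth,
    )
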