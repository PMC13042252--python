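"""Permutation enrichment tests on sweep-scan output.

Two null schemes:

* Gene-set test — the association between per-window sweep calls and
  genomic positions is destroyed by shuffling the binary call vector
  across windows; used for a focal gene set (e.g. insecticide-resistance
  genes).
* Circular-rotation GO test — all chromosomes' per-window scores are
  concatenated into a ring and rotated by a random non-zero offset; this
  preserves the spatial autocorrelation of sweep scores (runs of adjacent
  sweep windows stay intact except at the two splice points), giving a
  linkage-aware null for per-GO-term overlap counts.

In both tests genes are padded (default 1 kb each side) before overlap
counting, each gene counts at most once, and the one-sided p-value is the
plain proportion of permutations with a count >= the observed count
(optionally the +1-corrected variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GenomicInterval


@dataclass
class AnnotationSet:
    """Gene intervals, gene -> GO-term map, and an optional focal set."""

    genes: list[tuple[str, GenomicInterval]]
    go_map: dict[str, set[str]] = field(default_factory=dict)
    focal_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = {g for g, _ in self.genes}
        if not self.focal_set <= ids:
            missing = sorted(self.focal_set - ids)[:5]
            raise ValueError(f"focal genes absent from gene list: {missing}")

    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.go_map.values():
            out |= t
        return out


@dataclass
class EnrichmentResult:
    observed: int
    perm_mean: float
    fold: float
    p_one_sided: float
    n_perm: int


def _count_overlapping_genes(
    gene_items: Sequence[tuple[str, GenomicInterval]],
    sweep_windows: Sequence[GenomicInterval],
    pad: int,
) -> int:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in sweep_windows:
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end))
    count = 0
    for _, iv in gene_items:
        spans = by_chrom.get(iv.chrom)
        if not spans:
            continue
        gs, ge = iv.start - pad, iv.end + pad
        if any(gs < we and ws < ge for ws, we in spans):
            count += 1
    return count


def _incidence_matrix(
    gene_items: Sequence[tuple[str, GenomicInterval]],
    windows: Sequence[GenomicInterval],
    pad: int,
) -> np.ndarray:
    """Boolean (genes x windows): padded gene overlaps window."""
    m = np.zeros((len(gene_items), len(windows)), dtype=bool)
    win_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, w in enumerate(windows):
        win_by_chrom.setdefault(w.chrom, []).append((w.start, w.end, j))
    for i, (_, iv) in enumerate(gene_items):
        gs, ge = iv.start - pad, iv.end + pad
        for ws, we, j in win_by_chrom.get(iv.chrom, ()):
            if gs < we and ws < ge:
                m[i, j] = True
    return m


def _overlap_counts(m: np.ndarray, call_matrix: np.ndarray) -> np.ndarray:
    """Genes overlapping >=1 called window, per call vector (row-wise).

    ``call_matrix`` is (n_vectors x n_windows) boolean; returns counts of
    shape (n_vectors,).  Chunked float matmul keeps memory bounded.
    """
    counts = np.empty(call_matrix.shape[0], dtype=np.int64)
    mf = m.T.astype(np.float32)  # windows x genes
    for lo in range(0, call_matrix.shape[0], 512):
        chunk = call_matrix[lo : lo + 512].astype(np.float32)
        counts[lo : lo + 512] = (chunk @ mf > 0).sum(axis=1)
    return counts


def gene_overlap_count(
    sweep_windows: Sequence[GenomicInterval],
    annotations: AnnotationSet,
    pad: int = 1000,
    restrict_to_focal: bool = True,
) -> int:
    """Number of (focal) genes whose padded span overlaps any sweep window."""
    if pad < 0:
        raise ValueError("pad must be nonnegative")
    items = annotations.genes
    if restrict_to_focal:
        items = [(g, iv) for g, iv in items if g in annotations.focal_set]
    return _count_overlapping_genes(items, sweep_windows, pad)


def permutation_gene_set_test(
    window_scores: np.ndarray,
    window_positions: Sequence[GenomicInterval],
    annotations: AnnotationSet,
    threshold: float = 0.95,
    n_perm: int = 10_000,
    pad: int = 1000,
    rng: Optional[np.random.Generator] = None,
    plus_one: bool = False,
) -> EnrichmentResult:
    """Focal-gene enrichment by shuffling sweep calls across windows.

    Windows with score >= threshold are sweep windows; each permutation
    shuffles the binary call vector over window positions and recounts
    overlapping focal genes.  With zero sweep windows the observed count
    is 0 and p = 1 by convention.
    """
    scores = np.asarray(window_scores, dtype=float)
    if scores.shape[0] != len(window_positions):
        raise ValueError("scores/positions length mismatch")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng or np.random.default_rng()
    is_sweep = scores >= threshold
    positions = list(window_positions)
    focal = [(g, iv) for g, iv in annotations.genes if g in annotations.focal_set]
    m = _incidence_matrix(focal, positions, pad)
    observed = int(_overlap_counts(m, is_sweep[None, :])[0])
    if not is_sweep.any():
        return EnrichmentResult(0, 0.0, 0.0, 1.0, n_perm)
    perms = np.empty((n_perm, len(positions)), dtype=bool)
    for i in range(n_perm):
        perms[i] = rng.permutation(is_sweep)
    perm_counts = _overlap_counts(m, perms)
    hits = int(np.sum(perm_counts >= observed))
    if plus_one:
        p = (hits + 1) / (n_perm + 1)
    else:
        p = max(hits / n_perm, 1.0 / n_perm)  # proportion; 0 reported as < 1/n_perm
    perm_mean = float(perm_counts.mean())
    fold = observed / perm_mean if perm_mean > 0 else float("inf")
    return EnrichmentResult(observed, perm_mean, fold, float(p), n_perm)


def circular_rotation_test(
    window_scores_by_chrom: dict[str, np.ndarray],
    window_positions_by_chrom: dict[str, Sequence[GenomicInterval]],
    annotations: AnnotationSet,
    threshold: float = 0.8,
    n_perm: int = 10_000,
    pad: int = 1000,
    rng: Optional[np.random.Generator] = None,
    plus_one: bool = False,
) -> dict[str, EnrichmentResult]:
    """Per-GO-term enrichment under the circular-rotation null.

    Chromosomes are concatenated in sorted name order into a ring of
    per-window scores; each permutation rotates the whole score vector by
    an offset uniform on [1, n_windows - 1] while windows keep their
    genomic positions.
    """
    chroms = sorted(window_scores_by_chrom)
    if set(chroms) != set(window_positions_by_chrom):
        raise ValueError("scores and positions must cover the same chromosomes")
    scores = np.concatenate([np.asarray(window_scores_by_chrom[c], float) for c in chroms])
    positions: list[GenomicInterval] = []
    for c in chroms:
        positions.extend(window_positions_by_chrom[c])
    n = scores.size
    if n < 2:
        raise ValueError("need at least 2 windows for rotation")
    if len(positions) != n:
        raise ValueError("scores/positions length mismatch")
    rng = rng or np.random.default_rng()

    terms = sorted(annotations.terms())
    genes_by_term = {
        t: [(g, iv) for g, iv in annotations.genes if t in annotations.go_map.get(g, ())]
        for t in terms
    }
    is_sweep = scores >= threshold
    perms = np.empty((n_perm, n), dtype=bool)
    for i in range(n_perm):
        offset = int(rng.integers(1, n))
        perms[i] = np.roll(is_sweep, offset)
    out: dict[str, EnrichmentResult] = {}
    for t in terms:
        m = _incidence_matrix(genes_by_term[t], positions, pad)
        obs_t = int(_overlap_counts(m, is_sweep[None, :])[0])
        pc = _overlap_counts(m, perms)
        hits = int(np.sum(pc >= obs_t))
        if plus_one:
            p = (hits + 1) / (n_perm + 1)
        else:
            p = max(hits / n_perm, 1.0 / n_perm)
        mean = float(pc.mean())
        fold = obs_t / mean if mean > 0 else float("inf")
        out[t] = EnrichmentResult(obs_t, mean, fold, float(p), n_perm)
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
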