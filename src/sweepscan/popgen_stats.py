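"""Summary statistics on unphased diploid genotype matrices.

All "haplotype-spectrum" statistics (number of distinct types, H1, H12,
H2/H1) are computed on multilocus genotypes (MLGs): the string of diploid
dosages across sites for one individual, the unphased analogue of a
haplotype.  Linkage-disequilibrium statistics (Zns, omega) use the Rogers &
Huff genotype-correlation estimator of r^2, which requires no phasing.

Missing-data conventions (documented because unphased pipelines differ):

* pi / Watterson's theta / Tajima's D adjust the per-site allele count to
  the number of non-missing alleles; sites with fewer than two observed
  alleles are skipped.
* LD statistics use pairwise-complete observations.
* The MLG spectrum treats MISSING as a distinct fifth symbol.

Moments of the pairwise-difference distribution are population (biased)
moments; skewness and kurtosis are the standardized third and fourth
central moments, kurtosis *not* excess-corrected.
"""

from __future__ import annotations

import numpy as np

from .core import MISSING, GenotypeMatrix

STAT_NAMES = (
    "pi",
    "theta_w",
    "tajimas_d",
    "n_distinct_mlg",
    "h1",
    "h12",
    "h2_h1",
    "zns",
    "omega_max",
    "pwdiff_var",
    "pwdiff_skew",
    "pwdiff_kurt",
)

N_STATS = len(STAT_NAMES)


def _site_allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (derived allele count, non-missing allele count)."""
    observed = dosages != MISSING
    m = 2 * observed.sum(axis=0)
    ac = np.where(observed, dosages, 0).sum(axis=0)
    return ac.astype(np.int64), m.astype(np.int64)


def pi(gm: GenotypeMatrix) -> float:
    """Nucleotide diversity: expected pairwise differences, summed over sites.

    Per site the unbiased estimator 2*p*q*m/(m-1) is used, with p the
    non-missing allele frequency and m the non-missing allele count.
    """
    if gm.n_sites == 0:
        return 0.0
    ac, m = _site_allele_counts(gm.dosages)
    keep = m >= 2
    if not keep.any():
        return 0.0
    ac, m = ac[keep], m[keep]
    p = ac / m
    return float(np.sum(2.0 * p * (1.0 - p) * m / (m - 1)))


def _modal_allele_count(m: np.ndarray) -> int:
    m = m[m >= 2]
    if m.size == 0:
        return 0
    return int(np.bincount(m).argmax())


def _segregating(ac: np.ndarray, m: np.ndarray) -> np.ndarray:
    return (m >= 2) & (ac > 0) & (ac < m)


def theta_w(gm: GenotypeMatrix) -> float:
    """Watterson's estimator S / a1, a1 the harmonic number over the modal
    non-missing allele count."""
    if gm.n_sites == 0:
        return 0.0
    ac, m = _site_allele_counts(gm.dosages)
    s = int(_segregating(ac, m).sum())
    n = _modal_allele_count(m)
    if s == 0 or n < 2:
        return 0.0
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(s / a1)


def tajimas_d(gm: GenotypeMatrix) -> float:
    """Tajima's D with the standard constants, using the modal non-missing
    allele count as the sample size.  Returns 0 when S = 0 (convention)."""
    if gm.n_sites == 0:
        return 0.0
    ac, m = _site_allele_counts(gm.dosages)
    s = int(_segregating(ac, m).sum())
    n = _modal_allele_count(m)
    if s == 0 or n < 3:
        return 0.0
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = np.sqrt(e1 * s + e2 * s * (s - 1))
    if denom == 0:
        return 0.0
    return float((pi(gm) - s / a1) / denom)


def mlg_spectrum(gm: GenotypeMatrix) -> tuple[int, float, float, float]:
    """(n_distinct, H1, H12, H2/H1) of the multilocus-genotype spectrum.

    With sorted MLG frequencies p1 >= p2 >= ...:
    H1 = sum p_i^2, H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2,
    H2/H1 = (H1 - p1^2) / H1.  Empty input yields (0, 0, 0, 0).
    """
    if gm.n_sites == 0 or gm.n_individuals == 0:
        return 0, 0.0, 0.0, 0.0
    _, counts = np.unique(gm.dosages, axis=0, return_counts=True)
    p = np.sort(counts / gm.n_individuals)[::-1]
    h1 = float(np.sum(p**2))
    p2 = p[1] if p.size > 1 else 0.0
    h12 = float((p[0] + p2) ** 2 + np.sum(p[2:] ** 2))
    h2_h1 = float((h1 - p[0] ** 2) / h1)
    return int(p.size), h1, h12, h2_h1


def rogers_huff_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete entries (the Rogers-Huff unphased r^2)."""
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    xs -= xs.mean()
    ys -= ys.mean()
    vx = np.dot(xs, xs)
    vy = np.dot(ys, ys)
    if vx == 0 or vy == 0:
        return 0.0
    return float(np.dot(xs, ys) ** 2 / (vx * vy))


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise r^2 among sites (rows = individuals, cols = sites).

    Vectorized pairwise-complete computation; entries with fewer than two
    complete pairs or zero variance are 0.
    """
    v = dosages.T.astype(float)  # sites x individuals
    v[dosages.T == MISSING] = np.nan
    mask = np.isfinite(v)
    if mask.all():
        centered = v - v.mean(axis=1, keepdims=True)
        cov = centered @ centered.T
        var = np.diag(cov).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = cov**2 / (var[:, None] * var[None, :])
        r2[~np.isfinite(r2)] = 0.0
        np.fill_diagonal(r2, 1.0)
        r2[var == 0, :] = 0.0
        r2[:, var == 0] = 0.0
        return r2
    a = np.where(mask, v, 0.0)
    m = mask.astype(float)
    n = m @ m.T
    sxy = a @ a.T
    sx = a @ m.T
    sxx = (a**2) @ m.T
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = sx / n
        mean_y = mean_x.T
        cov = sxy / n - mean_x * mean_y
        var_x = sxx / n - mean_x**2
        var_y = var_x.T
        r2 = cov**2 / (var_x * var_y)
    bad = (n < 2) | ~np.isfinite(r2)
    r2 = np.where(bad, 0.0, r2)
    return r2


def _segregating_dosages(gm: GenotypeMatrix) -> np.ndarray:
    ac, m = _site_allele_counts(gm.dosages)
    return gm.dosages[:, _segregating(ac, m)]


def _zns_from_r2(r2: np.ndarray) -> float:
    s = r2.shape[0]
    if s < 2:
        return 0.0
    iu = np.triu_indices(s, k=1)
    return float(r2[iu].mean())


def zns(gm: GenotypeMatrix) -> float:
    """Kelly's Zns: mean r^2 over all pairs of segregating sites.

    Fewer than two segregating sites yields 0 by convention.
    """
    d = _segregating_dosages(gm)
    if d.shape[1] < 2:
        return 0.0
    return _zns_from_r2(_r2_matrix(d))


def omega_max(gm: GenotypeMatrix, min_split: int = 3) -> float:
    """Maximum of Kim & Nielsen's omega over split points.

    For a split after the l-th segregating site, omega contrasts mean LD
    within the left and right blocks against mean LD across them; elevated
    values flag the LD structure at sweep edges.  Requires at least
    2*min_split segregating sites, else 0 by convention.
    """
    d = _segregating_dosages(gm)
    if d.shape[1] < 2 * min_split:
        return 0.0
    return _omega_from_r2(_r2_matrix(d), min_split)


def _omega_from_r2(r2: np.ndarray, min_split: int = 3) -> float:
    s = r2.shape[0]
    if s < 2 * min_split:
        return 0.0
    r2 = r2.copy()
    np.fill_diagonal(r2, 0.0)
    c = r2.cumsum(axis=0).cumsum(axis=1)
    total = c[-1, -1] / 2.0
    best = 0.0
    for l in range(min_split, s - min_split + 1):
        left = c[l - 1, l - 1] / 2.0
        cross = c[l - 1, s - 1] - c[l - 1, l - 1]
        right = total - left - cross
        if cross <= 0:
            continue
        n_left = l * (l - 1) / 2.0
        n_right = (s - l) * (s - l - 1) / 2.0
        num = (left + right) / (n_left + n_right)
        den = cross / (l * (s - l))
        best = max(best, num / den)
    return float(best)


def pwdiff_moments(gm: GenotypeMatrix) -> tuple[float, float, float]:
    """(variance, skewness, kurtosis) of the pairwise-difference distribution.

    d_ij = sum over sites of |dosage_i - dosage_j| where both individuals
    are non-missing; moments over all C(n, 2) pairs.  A zero-variance
    distribution yields (0, 0, 0).
    """
    n = gm.n_individuals
    if n < 2:
        raise ValueError("pairwise-difference moments require >= 2 individuals")
    if gm.n_sites == 0:
        return 0.0, 0.0, 0.0
    v = gm.dosages.astype(float)
    obs = gm.dosages != MISSING
    diffs = np.abs(v[:, None, :] - v[None, :, :])
    both = obs[:, None, :] & obs[None, :, :]
    d = np.where(both, diffs, 0.0).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    var = float(np.var(vals))
    if var == 0:
        return 0.0, 0.0, 0.0
    centered = vals - vals.mean()
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return var, m3 / var**1.5, m4 / var**2


def stat_vector(
    gm: GenotypeMatrix, min_split: int = 3, max_ld_sites: int | None = None
) -> np.ndarray:
    """The 12 statistics in the fixed order of STAT_NAMES.

    The pairwise r^2 matrix is computed once and shared by Zns and omega.
    ``max_ld_sites`` optionally caps the number of segregating sites used
    for the LD statistics (an evenly spaced subsample), bounding their
    quadratic cost on very dense windows; all other statistics always use
    every site.
    """
    n_mlg, h1, h12, h2h1 = mlg_spectrum(gm)
    if gm.n_individuals >= 2:
        var, skew, kurt = pwdiff_moments(gm)
    else:
        var, skew, kurt = 0.0, 0.0, 0.0
    d = _segregating_dosages(gm)
    s = d.shape[1]
    if max_ld_sites is not None and s > max_ld_sites:
        idx = np.unique(np.linspace(0, s - 1, max_ld_sites).round().astype(int))
        d = d[:, idx]
        s = d.shape[1]
    if s >= 2:
        r2 = _r2_matrix(d)
        zns_val = _zns_from_r2(r2)
        omega_val = _omega_from_r2(r2, min_split)
    else:
        zns_val, omega_val = 0.0, 0.0
    return np.array(
        [
            pi(gm),
            theta_w(gm),
            tajimas_d(gm),
            float(n_mlg),
            h1,
            h12,
            h2h1,
            zns_val,
            omega_val,
            var,
            skew,
            kurt,
        ]
    )
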