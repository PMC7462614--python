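"""Pooled-sequencing diversity: per-site pi, windowed pi / Watterson's theta,
and effective population size.

Estimators are the read-level forms for pool-seq data:

* per-site heterozygosity  pi = M/(M-1) * (1 - sum_a (c_a/M)^2)  for a site
  of depth M with base counts c_a — the unbiased probability that two
  distinct reads differ;
* windowed Watterson  theta_W = S / (a_n * covered)  with S the number of
  SNPs passing the minimum minor-count filter, n the *haploid pool size*
  (the pool bounds the number of distinct lineages sampled, regardless of
  read depth) and a_n the harmonic number H_{n-1};
* N_e = theta / (2 * ploidy * mu).

Windows are non-overlapping (50 kb by default) and reported only when at
least 30% of their positions pass the coverage bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "site_pi",
    "site_pi_array",
    "harmonic",
    "window_stats",
    "NeEstimate",
    "estimate_ne",
]


def harmonic(n: int) -> float:
    """H_n = sum_{i=1}^{n} 1/i."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def site_pi(counts: np.ndarray) -> float:
    """Unbiased per-site heterozygosity from read counts (depth >= 2)."""
    counts = np.asarray(counts, dtype=np.float64)
    m = counts.sum()
    if m < 2:
        raise ValueError("site_pi requires depth >= 2")
    return float(m / (m - 1.0) * (1.0 - np.sum((counts / m) ** 2)))


def site_pi_array(counts: np.ndarray) -> np.ndarray:
    """Vectorized :func:`site_pi` over an (L, 4) count matrix.

    Sites with depth < 2 get NaN.
    """
    counts = np.asarray(counts, dtype=np.float64)
    m = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = m / (m - 1.0) * (1.0 - np.sum((counts / m[:, None]) ** 2, axis=1))
    pi[m < 2] = np.nan
    return pi


def _coverage_bounds(depth: np.ndarray, min_depth, max_depth) -> tuple[float, float]:
    # default bounds: [mean/2, 2*mean] computed from covered sites
    if min_depth is None or max_depth is None:
        mean = depth[depth > 0].mean() if (depth > 0).any() else 0.0
        if min_depth is None:
            min_depth = mean / 2.0
        if max_depth is None:
            max_depth = 2.0 * mean
    return float(min_depth), float(max_depth)


def window_stats(
    counts: np.ndarray,
    haploid_pool_size: int,
    positions: Optional[np.ndarray] = None,
    window_size: int = 50_000,
    min_count: int = 2,
    min_covered_fraction: float = 0.3,
    min_depth: Optional[float] = None,
    max_depth: Optional[float] = None,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Non-overlapping window estimates of pi and Watterson's theta.

    Parameters
    ----------
    counts : (L, 4) int array
        Pooled base counts of one population, one row per site.
    haploid_pool_size : int
        Number of haploid genomes in the pool (n of the a_n correction).
    positions : optional int array
        0-based genomic positions of the rows; defaults to 0..L-1.
    min_count : int
        A site counts as a SNP only if its two most frequent alleles each
        have at least ``min_count`` reads; the same filter gates the sites
        contributing to pi.
    min_depth, max_depth : float, optional
        Coverage bounds; sites outside are not "covered".  Defaults are
        half and twice the mean depth of the data.

    Returns a frame with chrom, start, end, covered_fraction, n_snps, pi,
    theta_w; windows below ``min_covered_fraction`` are omitted.
    """
    if haploid_pool_size < 2:
        raise ValueError("haploid_pool_size must be >= 2")
    counts = np.asarray(counts)
    if counts.size == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "covered_fraction", "n_snps", "pi", "theta_w"]
        )
    if positions is None:
        positions = np.arange(counts.shape[0], dtype=np.int64)
    depth = counts.sum(axis=1)
    lo, hi = _coverage_bounds(depth, min_depth, max_depth)
    covered = (depth >= lo) & (depth <= hi)

    part = np.partition(counts, 2, axis=1)
    minor2 = part[:, 2]  # second-largest count
    is_snp = covered & (minor2 >= min_count)

    pi_site = np.zeros(counts.shape[0])
    if is_snp.any():
        pi_site[is_snp] = site_pi_array(counts[is_snp])

    a_n = harmonic(haploid_pool_size - 1)
    win = positions // window_size
    first = positions.min() // window_size
    last = positions.max() // window_size
    rows = []
    for w in range(int(first), int(last) + 1):
        sel = win == w
        n_cov = int(covered[sel].sum())
        frac = n_cov / window_size
        if frac < min_covered_fraction:
            continue
        s = int(is_snp[sel].sum())
        rows.append(
            {
                "chrom": chrom,
                "start": w * window_size,
                "end": (w + 1) * window_size,
                "covered_fraction": frac,
                "n_snps": s,
                "pi": float(pi_site[sel].sum() / n_cov),
                "theta_w": float(s / (a_n * n_cov)),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "covered_fraction", "n_snps", "pi", "theta_w"]
    )


@dataclass(frozen=True)
class NeEstimate:
    """Effective population size from the population mutation rate."""

    theta: float
    mu: float
    ploidy: int
    ne: float


def estimate_ne(theta: float, mu: float = 2.6321e-9, ploidy: int = 2) -> NeEstimate:
    """N_e = theta / (2 * ploidy * mu), theta per site.

    The default mutation rate is the killifish per-bp per-generation rate
    (2.6321e-9, one generation per year).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return NeEstimate(theta=theta, mu=mu, ploidy=ploidy, ne=theta / (2.0 * ploidy * mu))
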