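"""Pairwise F_ST at SNP, window and gene scope, outlier scans, and trees.

F_ST uses the classical pi-based estimator: for a site (or region),
``F_ST = (pi_total - pi_within) / pi_total`` with ``pi_within`` the mean of
the two per-pool heterozygosities and ``pi_total`` the heterozygosity of
the summed counts.  Negative values are clamped to 0.  Window- and
gene-scope values average the per-SNP F_ST over the qualifying SNPs of the
region, so a gene is simply a window spanning the gene body.

The outlier scan Z-transforms the window F_ST values of each pair and
flags windows beyond the 0.5% / 99.5% empirical quantiles.  Candidate
genes under strong differentiation must satisfy three criteria: an
overlapping outlier window, a gene-scope F_ST above the 99.5th percentile
of gene values, and at least one SNP significant in a Fisher exact test
after Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import site_pi_array

__all__ = [
    "fst_from_counts",
    "fst_sites",
    "fst_windows",
    "OutlierSet",
    "zfst_outliers",
    "snp_fisher_bh",
    "nj_tree",
]


def fst_from_counts(counts_pop1: np.ndarray, counts_pop2: np.ndarray) -> float:
    """Classical pi-based F_ST for one site from two pools' base counts.

    Returns NaN where undefined (pi_total = 0); negative estimates are
    clamped to 0.  Raises on zero depth in either pool.
    """
    c1 = np.asarray(counts_pop1, dtype=np.float64)
    c2 = np.asarray(counts_pop2, dtype=np.float64)
    if c1.sum() < 1 or c2.sum() < 1:
        raise ValueError("zero depth in one of the pools")
    out = fst_sites(c1[None, :], c2[None, :])[0]
    return float(out)


def fst_sites(counts1: np.ndarray, counts2: np.ndarray) -> np.ndarray:
    """Vectorized per-site F_ST over (L, 4) count matrices (NaN = undefined)."""
    pi1 = site_pi_array(counts1)
    pi2 = site_pi_array(counts2)
    pit = site_pi_array(np.asarray(counts1) + np.asarray(counts2))
    piw = 0.5 * (pi1 + pi2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (pit - piw) / pit
    fst[~np.isfinite(fst)] = np.nan
    return np.clip(fst, 0.0, 1.0, out=fst)


def _snp_mask(
    counts1: np.ndarray,
    counts2: np.ndarray,
    min_count: int,
    min_depth: float,
    max_depth1: float,
    max_depth2: float,
) -> np.ndarray:
    d1 = counts1.sum(axis=1)
    d2 = counts2.sum(axis=1)
    ok = (d1 >= min_depth) & (d2 >= min_depth) & (d1 <= max_depth1) & (d2 <= max_depth2)
    pooled = counts1 + counts2
    part = np.partition(pooled, 2, axis=1)
    return ok & (part[:, 2] >= min_count)


def fst_windows(
    counts1: np.ndarray,
    counts2: np.ndarray,
    positions: np.ndarray | None = None,
    window_size: int = 50_000,
    min_count: int = 4,
    min_depth: float = 20,
    max_depth1: float = np.inf,
    max_depth2: float = np.inf,
    min_covered_fraction: float = 0.0,
    pair: str = "pop1:pop2",
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Mean per-SNP F_ST in non-overlapping windows for one population pair.

    SNPs qualify when both pools satisfy the coverage bounds and the two
    most frequent pooled alleles each have >= ``min_count`` reads.  Windows
    with no qualifying SNP (or, when ``min_covered_fraction`` > 0, with too
    few covered positions) are omitted.  Setting ``window_size`` to span a
    whole gene body yields the gene-scope value; ``window_size=1`` yields
    per-SNP records.
    """
    counts1 = np.asarray(counts1)
    counts2 = np.asarray(counts2)
    if positions is None:
        positions = np.arange(counts1.shape[0], dtype=np.int64)
    snp = _snp_mask(counts1, counts2, min_count, min_depth, max_depth1, max_depth2)
    fst = np.full(counts1.shape[0], np.nan)
    if snp.any():
        fst[snp] = fst_sites(counts1[snp], counts2[snp])
    d1 = counts1.sum(axis=1)
    d2 = counts2.sum(axis=1)
    covered = (d1 >= min_depth) & (d2 >= min_depth) & (d1 <= max_depth1) & (d2 <= max_depth2)

    win = positions // window_size
    rows = []
    for w in np.unique(win):
        sel = win == w
        frac = covered[sel].sum() / window_size
        if frac < min_covered_fraction:
            continue
        vals = fst[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        rows.append(
            {
                "chrom": chrom,
                "start": int(w) * window_size,
                "end": (int(w) + 1) * window_size,
                "pair": pair,
                "n_snps": int(vals.size),
                "covered_fraction": float(frac),
                "fst": float(vals.mean()),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pair", "n_snps", "covered_fraction", "fst"]
    )


@dataclass
class OutlierSet:
    """Windows in the tails of the Z_FST distribution for one pair."""

    pair: str
    lower_threshold: float
    upper_threshold: float
    windows: pd.DataFrame  # with z_fst column
    high: pd.DataFrame
    low: pd.DataFrame


def zfst_outliers(
    windows: pd.DataFrame,
    lower_q: float = 0.005,
    upper_q: float = 0.995,
    pair: str | None = None,
) -> OutlierSet:
    """Z-transform window F_ST values of one pair and flag the quantile tails.

    ``windows`` must carry an ``fst`` column (one pair).  Quantiles use the
    empirical type-7 definition.  Raises on zero variance; warns when fewer
    than 200 windows make the tail quantiles unstable.
    """
    fst = windows["fst"].to_numpy(dtype=np.float64)
    if fst.size < 200:
        warnings.warn("fewer than 200 windows: tail quantiles are unstable", stacklevel=2)
    sd = fst.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across windows: Z_FST undefined")
    z = (fst - fst.mean()) / sd
    out = windows.copy()
    out["z_fst"] = z
    lo = float(np.quantile(z, lower_q))
    hi = float(np.quantile(z, upper_q))
    return OutlierSet(
        pair=pair or (windows["pair"].iloc[0] if "pair" in windows else "pair"),
        lower_threshold=lo,
        upper_threshold=hi,
        windows=out,
        high=out[out["z_fst"] > hi],
        low=out[out["z_fst"] < lo],
    )


def snp_fisher_bh(
    tables: np.ndarray, alpha: float = 0.001
) -> pd.DataFrame:
    """Two-sided Fisher exact tests on 2x2 allele-count tables, BH-corrected.

    ``tables`` is (m, 2, 2): per SNP the major/minor allele counts in the
    two pools.  Tables with a zero margin get p = 1.  Returns columns p,
    q (Benjamini-Hochberg adjusted) and significant (q < ``alpha``).
    """
    tables = np.asarray(tables, dtype=np.int64)
    if tables.ndim != 3 or tables.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (m, 2, 2)")
    p = np.ones(tables.shape[0])
    for i, t in enumerate(tables):
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            p[i] = 1.0
        else:
            p[i] = stats.fisher_exact(t, alternative="two-sided")[1]
    if p.size:
        _, q, _, _ = multipletests(p, method="fdr_bh")
    else:
        q = p.copy()
    return pd.DataFrame({"p": p, "q": q, "significant": q < alpha})


def candidate_genes(
    gene_fst: pd.DataFrame,
    outliers: OutlierSet,
    snp_significant_genes: set,
    gene_quantile: float = 0.995,
) -> pd.DataFrame:
    """Apply the three-criteria rule for genes under strong differentiation.

    A gene qualifies iff (1) it overlaps a high-Z_FST outlier window,
    (2) its gene-scope F_ST exceeds the ``gene_quantile`` quantile of all
    gene values, and (3) it contains at least one SNP significant in the
    BH-corrected Fisher exact test.  Returns the gene frame with boolean
    criteria columns and a combined ``candidate`` flag.
    """
    out = gene_fst.copy()
    hi = out["fst"].quantile(gene_quantile)
    win = outliers.high
    in_window = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        hitting = win[
            (win["chrom"] == row.chrom)
            & (win["start"] < row.end)
            & (win["end"] > row.start)
        ]
        in_window[i] = len(hitting) > 0
    out["crit_window_z"] = in_window
    out["crit_gene_fst"] = out["fst"] > hi
    out["crit_snp_fisher"] = out["gene_id"].isin(snp_significant_genes)
    out["candidate"] = out["crit_window_z"] & out["crit_gene_fst"] & out["crit_snp_fisher"]
    return out


def nj_tree(distance_matrix: np.ndarray, labels: list[str]) -> str:
    """Unrooted neighbor-joining tree (newick) from a distance matrix.

    Branch lengths may be negative and are reported as-is.  Requires a
    symmetric, zero-diagonal matrix over >= 3 taxa.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = np.asarray(distance_matrix, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 3:
        raise ValueError("need a square matrix over at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    dm = DistanceMatrix(d, ids=list(labels))
    try:
        tree = nj(dm, neg_as_zero=False)
    except TypeError:  # older scikit-bio API
        tree = nj(dm, disallow_negative_branch_length=False)
    return str(tree).strip()
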