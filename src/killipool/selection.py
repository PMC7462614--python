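"""Selection statistics: McDonald-Kreitman tables, asymptotic alpha, DoS,
site-frequency spectra and a gamma-DFE likelihood fit.

The McDonald-Kreitman framework contrasts divergence and polymorphism at
non-synonymous (zero-fold) versus synonymous (four-fold) sites.  Because
slightly deleterious variants segregate at low frequency and depress the
classical estimate of the adaptive fraction alpha, alpha is computed per
derived-allele-frequency bin, ``alpha(x) = 1 - (Ds/Dn) * (Pn(x)/Ps(x))``,
and the asymptote of an exponential fit ``a + b * exp(-c*x)`` evaluated at
x = 1 is reported as the asymptotic alpha.

The per-gene direction of selection ``DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps)``
standardises alpha to [-1, 1]: positive under adaptive evolution, negative
when slightly deleterious variants segregate (relaxed purifying
selection).

The DFE fit models the projected non-synonymous SFS as a Poisson random
field whose per-class expectation integrates the diffusion sojourn density
``H(x; S) = (1 - exp(-S(1-x))) / (x (1-x) (1 - exp(-S)))`` (scaled
selection S = 4*Ne*s, neutral limit 1/x) over a gamma distribution of -S.
The synonymous SFS calibrates the neutral mutation rate.  Model choice
(deleterious-only gamma versus gamma plus a neutral point mass) is by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from .sites import FOUR_FOLD, ZERO_FOLD

__all__ = [
    "MKTable",
    "mk_counts",
    "aggregate_mk",
    "alpha_x",
    "AsymptoticAlphaFit",
    "fit_asymptotic_alpha",
    "bootstrap_asymptotic_alpha",
    "dos",
    "dos_table",
    "dos_gene_sets",
    "SFS",
    "build_sfs",
    "sfs_from_sample",
    "project_sfs",
    "expected_sfs",
    "DFEFit",
    "fit_gamma_dfe",
    "compare_models_aic",
]

DEFAULT_BINS = np.linspace(0.05, 0.95, 10)  # 9 equal bins spanning [0.05, 0.95]


# ---------------------------------------------------------------------------
# MK tables
# ---------------------------------------------------------------------------


@dataclass
class MKTable:
    """Per-gene divergence/polymorphism counts with frequency-binned P."""

    gene_id: str
    dn: int
    ds: int
    pn: int
    ps: int
    pn_bins: np.ndarray
    ps_bins: np.ndarray
    bins: np.ndarray

    @property
    def usable_for_dos(self) -> bool:
        return (self.dn + self.ds) > 0 and (self.pn + self.ps) > 0


def mk_counts(
    polarized: pd.DataFrame,
    bins: np.ndarray = DEFAULT_BINS,
    gene_names: Optional[Sequence[str]] = None,
) -> list[MKTable]:
    """Tally Dn/Ds/Pn/Ps per gene from a polarized-site table.

    Fixed differences are sites with status ``fixed`` (DAF > 0.95 or
    monomorphic-but-different from the outgroup); polymorphisms are
    biallelic sites with 0.05 <= DAF <= 0.95, binned by DAF.  Genes with
    no classified site yield no table.
    """
    bins = np.asarray(bins, dtype=np.float64)
    tables: list[MKTable] = []
    use = polarized[polarized["status"].isin(["fixed", "polymorphic"])]
    for gene, grp in use.groupby("gene", sort=True):
        nonsyn = grp["degeneracy"].to_numpy() == ZERO_FOLD
        syn = grp["degeneracy"].to_numpy() == FOUR_FOLD
        fixed = grp["status"].to_numpy() == "fixed"
        poly = ~fixed
        daf = grp["daf"].to_numpy()
        pn_bins, _ = np.histogram(daf[poly & nonsyn], bins=bins)
        ps_bins, _ = np.histogram(daf[poly & syn], bins=bins)
        name = str(gene) if gene_names is None else str(gene_names[int(gene)])
        tables.append(
            MKTable(
                gene_id=name,
                dn=int((fixed & nonsyn).sum()),
                ds=int((fixed & syn).sum()),
                pn=int((poly & nonsyn).sum()),
                ps=int((poly & syn).sum()),
                pn_bins=pn_bins.astype(np.int64),
                ps_bins=ps_bins.astype(np.int64),
                bins=bins,
            )
        )
    return tables


def aggregate_mk(tables: Sequence[MKTable]) -> MKTable:
    """Sum MK counts over genes (for genome-wide alpha)."""
    if not tables:
        raise ValueError("no MK tables to aggregate")
    bins = tables[0].bins
    return MKTable(
        gene_id="aggregate",
        dn=sum(t.dn for t in tables),
        ds=sum(t.ds for t in tables),
        pn=sum(t.pn for t in tables),
        ps=sum(t.ps for t in tables),
        pn_bins=np.sum([t.pn_bins for t in tables], axis=0),
        ps_bins=np.sum([t.ps_bins for t in tables], axis=0),
        bins=bins,
    )


# ---------------------------------------------------------------------------
# alpha(x) and the asymptotic fit
# ---------------------------------------------------------------------------


def alpha_x(table: MKTable) -> tuple[np.ndarray, np.ndarray]:
    """alpha per DAF bin: 1 - (Ds/Dn) * (Pn(x)/Ps(x)).

    Returns (bin midpoints, alpha values); bins with a zero Ps are NaN.
    Raises if Dn = 0 (the curve is undefined).
    """
    if table.dn == 0:
        raise ValueError("alpha(x) undefined: Dn = 0")
    mids = 0.5 * (table.bins[:-1] + table.bins[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = table.pn_bins / table.ps_bins
    alpha = 1.0 - (table.ds / table.dn) * ratio
    alpha[table.ps_bins == 0] = np.nan
    return mids, alpha


def pooled_alpha(table: MKTable) -> float:
    """Classical (pooled) alpha = 1 - (Ds * Pn) / (Dn * Ps)."""
    if table.dn == 0 or table.ps == 0:
        return np.nan
    return 1.0 - (table.ds * table.pn) / (table.dn * table.ps)


@dataclass
class AsymptoticAlphaFit:
    """Exponential extrapolation of alpha(x) to x = 1."""

    a: float
    b: float
    c: float
    alpha_asymptotic: float
    method: str  # "exponential" or "linear"
    ci: Optional[tuple[float, float]] = None


def fit_asymptotic_alpha(
    x: np.ndarray, alpha: np.ndarray, min_bins: int = 4
) -> AsymptoticAlphaFit:
    """Fit alpha(x) = a + b * exp(-c*x); the asymptotic alpha is the value
    at x = 1, a + b*e^(-c).

    Falls back to a linear extrapolation (intercept at x = 1, flagged
    ``method="linear"``) when the exponential fit does not converge, e.g.
    for a flat curve with non-identifiable c.
    """
    x = np.asarray(x, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    ok = np.isfinite(alpha)
    x, alpha = x[ok], alpha[ok]
    if x.size < min_bins:
        raise ValueError(f"need >= {min_bins} informative bins, got {x.size}")
    if np.allclose(alpha, alpha[0]):
        val = float(alpha[0])
        return AsymptoticAlphaFit(a=val, b=0.0, c=0.0, alpha_asymptotic=val, method="exponential")

    def model(xx, a, b, c):
        return a + b * np.exp(-c * xx)

    slope0 = (alpha[-1] - alpha[0]) / (x[-1] - x[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model,
                x,
                alpha,
                p0=[alpha[-1], alpha[0] - alpha[-1], 2.0],
                maxfev=10_000,
            )
        a, b, c = (float(v) for v in popt)
        if not np.all(np.isfinite(popt)) or abs(c) > 1e3:
            raise RuntimeError("degenerate exponential fit")
        return AsymptoticAlphaFit(
            a=a, b=b, c=c, alpha_asymptotic=a + b * np.exp(-c), method="exponential"
        )
    except RuntimeError:
        coef = np.polyfit(x, alpha, 1)
        val = float(np.polyval(coef, 1.0))
        return AsymptoticAlphaFit(
            a=float(coef[1]), b=float(coef[0]), c=0.0, alpha_asymptotic=val, method="linear"
        )


def bootstrap_asymptotic_alpha(
    tables: Sequence[MKTable],
    n_boot: int = 200,
    rng: np.random.Generator | int | None = None,
    ci_level: float = 0.95,
) -> AsymptoticAlphaFit:
    """Asymptotic alpha with a gene-bootstrap percentile CI."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    agg = aggregate_mk(tables)
    x, a = alpha_x(agg)
    fit = fit_asymptotic_alpha(x, a)
    vals = []
    tables = list(tables)
    for _ in range(n_boot):
        pick = rng.integers(0, len(tables), size=len(tables))
        boot = aggregate_mk([tables[i] for i in pick])
        if boot.dn == 0:
            continue
        try:
            xb, ab = alpha_x(boot)
            vals.append(fit_asymptotic_alpha(xb, ab).alpha_asymptotic)
        except (ValueError, RuntimeError):
            continue
    if vals:
        lo, hi = np.quantile(vals, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
        fit.ci = (float(lo), float(hi))
    return fit


# ---------------------------------------------------------------------------
# DoS
# ---------------------------------------------------------------------------


def dos(dn: int, ds: int, pn: int, ps: int) -> float:
    """Direction of selection: Dn/(Dn+Ds) - Pn/(Pn+Ps); NaN when undefined."""
    if dn + ds == 0 or pn + ps == 0:
        return np.nan
    return dn / (dn + ds) - pn / (pn + ps)


def dos_table(tables: Sequence[MKTable]) -> pd.DataFrame:
    """Per-gene DoS values; genes without both a substitution and a
    polymorphism are reported with NaN (excluded downstream)."""
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tables],
            "dn": [t.dn for t in tables],
            "ds": [t.ds for t in tables],
            "pn": [t.pn for t in tables],
            "ps": [t.ps for t in tables],
            "dos": [dos(t.dn, t.ds, t.pn, t.ps) for t in tables],
        }
    )


def dos_gene_sets(
    dos_values: pd.DataFrame,
    lower_percentile: float = 2.5,
    upper_percentile: float = 97.5,
    min_genes: int = 40,
) -> dict:
    """Tail gene sets and the median of the per-gene DoS distribution.

    Genes strictly below the 2.5th / strictly above the 97.5th empirical
    percentile form the lower/upper sets.  With fewer than ``min_genes``
    defined values the sets are empty (warned).
    """
    defined = dos_values.dropna(subset=["dos"])
    vals = defined["dos"].to_numpy()
    result = {
        "median": float(np.median(vals)) if vals.size else np.nan,
        "n_genes": int(vals.size),
        "lower": [],
        "upper": [],
    }
    if vals.size < min_genes:
        warnings.warn(f"only {vals.size} genes with defined DoS; tails not reported", stacklevel=2)
        return result
    lo = np.percentile(vals, lower_percentile)
    hi = np.percentile(vals, upper_percentile)
    result["lower"] = defined.loc[defined["dos"] < lo, "gene_id"].tolist()
    result["upper"] = defined.loc[defined["dos"] > hi, "gene_id"].tolist()
    return result


# ---------------------------------------------------------------------------
# SFS construction and projection
# ---------------------------------------------------------------------------


@dataclass
class SFS:
    """Unfolded site frequency spectrum of one site class.

    ``counts[i]`` for i in 1..n-1 holds the number of sites whose derived
    allele is at count i among n chromosomes (index 0 is unused and 0);
    ``fixed`` counts fixed derived differences (divergence).  ``dropped``
    records polymorphic mass that left the spectrum during projection.
    """

    site_class: str
    n: int
    counts: np.ndarray
    fixed: float = 0.0
    dropped: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (self.n + 1,):
            raise ValueError("counts must have length n + 1")

    @property
    def segregating(self) -> float:
        return float(self.counts[1 : self.n].sum())


def build_sfs(
    polarized: pd.DataFrame, degeneracy_class: int, n: int, site_class: str | None = None
) -> SFS:
    """SFS of a polarized table at native sample size ``n`` chromosomes.

    Each polymorphic site contributes at the rounded derived count
    ``round(daf * n)`` (clipped to 1..n-1); fixed-status sites count as
    divergence.
    """
    sel = polarized[polarized["degeneracy"] == degeneracy_class]
    poly = sel[sel["status"] == "polymorphic"]
    fixed = int((sel["status"] == "fixed").sum())
    counts = np.zeros(n + 1, dtype=np.float64)
    if len(poly):
        j = np.clip(np.rint(poly["daf"].to_numpy() * n).astype(int), 1, n - 1)
        np.add.at(counts, j, 1.0)
    name = site_class or ("non_synonymous" if degeneracy_class == ZERO_FOLD else "synonymous")
    return SFS(site_class=name, n=n, counts=counts, fixed=float(fixed))


def sfs_from_sample(
    derived_counts: np.ndarray, n: int, site_class: str, n_fixed: int = 0
) -> SFS:
    """SFS directly from per-variant derived counts in a sample of n
    chromosomes (counts equal to 0 or n are moved to the fixed class)."""
    counts = np.zeros(n + 1, dtype=np.float64)
    dc = np.asarray(derived_counts, dtype=int)
    dc = dc[(dc > 0)]
    fixed = int((dc == n).sum()) + n_fixed
    dc = dc[dc < n]
    np.add.at(counts, dc, 1.0)
    return SFS(site_class=site_class, n=n, counts=counts, fixed=float(fixed))


def project_sfs(sfs: SFS, n_target: int = 10) -> SFS:
    """Expected hypergeometric projection of the SFS to a smaller sample.

    ``count_i(n_target) = sum_j count_j(n) * P[Hypergeom(n, j, n_target) = i]``.
    Mass landing on classes 0 and n_target leaves the polymorphic spectrum
    and is recorded in ``dropped``; the fixed class carries over unchanged.
    """
    if n_target > sfs.n:
        raise ValueError("cannot project to a larger sample")
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    if n_target == sfs.n:
        return SFS(sfs.site_class, sfs.n, sfs.counts.copy(), sfs.fixed, sfs.dropped)
    new = np.zeros(n_target + 1, dtype=np.float64)
    i = np.arange(n_target + 1)
    for j in range(1, sfs.n):
        cj = sfs.counts[j]
        if cj == 0:
            continue
        new += cj * stats.hypergeom.pmf(i, sfs.n, j, n_target)
    dropped = (float(new[0]), float(new[n_target]))
    new[0] = 0.0
    new[n_target] = 0.0
    return SFS(sfs.site_class, n_target, new, sfs.fixed, dropped)


# ---------------------------------------------------------------------------
# Poisson random field expectations and the gamma DFE fit
# ---------------------------------------------------------------------------


def _sojourn_integrand(x: np.ndarray, S: float) -> np.ndarray:
    """H(x; S), numerically stable for strongly negative S.

    For S < 0 write T = -S:  H = exp(-T x) * expm1(-T (1-x)) / expm1(-T)
    / (x (1-x)); the neutral limit is 1/x.
    """
    x = np.asarray(x, dtype=np.float64)
    if abs(S) < 1e-8:
        return 1.0 / x
    if S < 0:
        T = -S
        num = np.exp(-T * x) * np.expm1(-T * (1.0 - x))
        den = np.expm1(-T)
    else:
        num = -np.expm1(-S * (1.0 - x))
        den = -np.expm1(-S)
    return num / (den * x * (1.0 - x))


def expected_sfs(S: float, theta_L: float, n: int) -> np.ndarray:
    """Poisson-random-field expected SFS counts for scaled selection S.

    ``E[F_i] = theta_L * int_0^1 H(x;S) C(n,i) x^i (1-x)^(n-i) dx`` for
    i = 1..n-1; at S = 0 this is the neutral ``theta_L / i`` spectrum.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if abs(S) < 1e-8:
        return theta_L / np.arange(1, n)
    # for strongly deleterious S the integrand is confined near x = 0 by
    # the exp(-|S| x) factor; truncating the domain keeps quad accurate
    x_hi = 1.0 if S > -100.0 else min(1.0, 200.0 / (-S))
    out = np.empty(n - 1)
    for i in range(1, n):
        binom = special.comb(n, i)

        def f(x, i=i, binom=binom):
            return _sojourn_integrand(x, S) * binom * x**i * (1.0 - x) ** (n - i)

        val, _ = integrate.quad(f, 0.0, x_hi, epsabs=1e-13, epsrel=1e-10, limit=200)
        out[i - 1] = theta_L * val
    return out


class _BGrid:
    """Cached b_i(T) = E[F_i]/theta for deleterious T = -S on a log grid."""

    def __init__(self, n: int, t_min: float = 1e-4, t_max: float = 1e6, n_grid: int = 120):
        self.n = n
        self.logT = np.linspace(np.log(t_min), np.log(t_max), n_grid)
        B = np.empty((n_grid, n - 1))
        for k, lt in enumerate(self.logT):
            B[k] = expected_sfs(-np.exp(lt), 1.0, n)
        self.logB = np.log(np.maximum(B, 1e-300))

    def b_mean(self, shape: float, s_mean: float, n_quad: int = 160) -> np.ndarray:
        """E_T[b_i(T)] under T ~ Gamma(shape, scale = s_mean/shape)."""
        q = (np.arange(n_quad) + 0.5) / n_quad
        T = stats.gamma.ppf(q, shape, scale=s_mean / shape)
        with np.errstate(divide="ignore"):  # ppf can hit 0 for tiny shapes
            lt = np.clip(np.log(T), self.logT[0], self.logT[-1])
        out = np.empty(self.n - 1)
        for i in range(self.n - 1):
            out[i] = np.mean(np.exp(np.interp(lt, self.logT, self.logB[:, i])))
        return out


_BGRIDS: dict[int, _BGrid] = {}


def _bgrid(n: int) -> _BGrid:
    if n not in _BGRIDS:
        _BGRIDS[n] = _BGrid(n)
    return _BGRIDS[n]


@dataclass
class DFEFit:
    """A fitted gamma DFE for the scaled selection coefficient 4*Ne*s."""

    model: str
    gamma_shape: float
    gamma_mean: float  # mean of -4*Ne*s (positive = deleterious)
    p_neutral: float
    theta_syn: float
    theta_nonsyn: float
    loglik: float
    aic: float
    n_params: int
    converged: bool
    message: str = ""


def _poisson_ll(obs: np.ndarray, mean: np.ndarray) -> float:
    mean = np.maximum(mean, 1e-12)
    return float(np.sum(obs * np.log(mean) - mean - special.gammaln(obs + 1.0)))


def fit_gamma_dfe(
    sfs_syn: SFS,
    sfs_nonsyn: SFS,
    model: str = "gamma",
) -> DFEFit:
    """Maximum composite likelihood fit of a (reflected) gamma DFE.

    ``model`` is ``"gamma"`` (deleterious-only, parameters shape and mean
    of -4*Ne*s plus the non-synonymous mutation-rate nuisance) or
    ``"gamma_neutral"`` (adds a neutral point mass).  The synonymous theta
    is fitted from the synonymous SFS under neutrality; the non-synonymous
    theta is profiled analytically at each step.
    """
    if sfs_syn.n != sfs_nonsyn.n:
        raise ValueError("spectra must be projected to a common sample size")
    n = sfs_syn.n
    i = np.arange(1, n)
    f_syn = sfs_syn.counts[1:n]
    f_ns = sfs_nonsyn.counts[1:n]
    if f_ns.sum() == 0 or f_syn.sum() == 0:
        raise ValueError("empty SFS")
    theta_syn = float(f_syn.sum() / np.sum(1.0 / i))
    grid = _bgrid(n)

    with_neutral = model == "gamma_neutral"

    def neg_ll(params):
        log_shape, log_mean = params[0], params[1]
        if not (-6 < log_shape < 6) or not (-8 < log_mean < 16):
            return 1e12
        p0 = special.expit(params[2]) if with_neutral else 0.0
        b = grid.b_mean(np.exp(log_shape), np.exp(log_mean))
        c = p0 / i + (1.0 - p0) * b
        theta = f_ns.sum() / c.sum()
        return -_poisson_ll(f_ns, theta * c)

    x0 = [np.log(0.3), np.log(200.0)] + ([0.0] if with_neutral else [])
    res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
    shape = float(np.exp(res.x[0]))
    s_mean = float(np.exp(res.x[1]))
    p0 = float(special.expit(res.x[2])) if with_neutral else 0.0
    b = grid.b_mean(shape, s_mean)
    c = p0 / i + (1.0 - p0) * b
    theta_ns = float(f_ns.sum() / c.sum())
    ll = _poisson_ll(f_ns, theta_ns * c)
    k = 4 if with_neutral else 3
    if not res.success:
        warnings.warn(f"DFE fit did not converge: {res.message}", stacklevel=2)
    if shape < 0.0035 or shape > 350 or s_mean < 5e-4 or s_mean > 5e6:
        warnings.warn("DFE parameter pinned near its bound", stacklevel=2)
    return DFEFit(
        model=model,
        gamma_shape=shape,
        gamma_mean=s_mean,
        p_neutral=p0,
        theta_syn=theta_syn,
        theta_nonsyn=theta_ns,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        n_params=k,
        converged=bool(res.success),
        message=str(res.message),
    )


def compare_models_aic(fits: Sequence[DFEFit]) -> DFEFit:
    """Best model by AIC; ties resolved in favour of fewer parameters."""
    if not fits:
        raise ValueError("no fits to compare")
    return min(fits, key=lambda f: (f.aic, f.n_params))
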