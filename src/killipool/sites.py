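"""Coding-site degeneracy, outgroup allele calls, and polarization.

The analyses downstream work on *polarized* sites: each coding position is
assigned a degeneracy class (zero-fold = every change is non-synonymous,
four-fold = no change is), the ancestral state is taken from an outgroup
pseudogenome, and the pooled read counts are converted into a derived
allele frequency (DAF) with a status in {monomorphic, polymorphic, fixed,
excluded}.

Status rules, applied in order:

* outgroup base not A/C/G/T, coverage outside the per-population bounds,
  or more than two alleles with >= 2 supporting reads -> ``excluded``;
* a minor allele supported by exactly one read is treated as absent
  (the site is monomorphic for the major allele);
* a biallelic site whose outgroup base matches neither allele (triallelic
  across species) -> ``excluded``;
* DAF < 0.05 -> ``monomorphic`` (effectively fixed for the ancestral
  allele), DAF > 0.95 -> ``fixed``, otherwise ``polymorphic``;
* a monomorphic site whose single allele differs from the outgroup is a
  fixed difference (``fixed``, DAF = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import str_to_sequence

__all__ = [
    "NONCODING",
    "ZERO_FOLD",
    "FOUR_FOLD",
    "OTHER_FOLD",
    "DegeneracyMap",
    "PolarizedSite",
    "classify_degeneracy",
    "call_major_allele",
    "polarize",
    "polarize_table",
    "segregation_posterior",
    "segregation_filter",
]

NONCODING = 0
ZERO_FOLD = 1
FOUR_FOLD = 2
OTHER_FOLD = 3

CLASS_NAMES = {NONCODING: "noncoding", ZERO_FOLD: "zero_fold", FOUR_FOLD: "four_fold", OTHER_FOLD: "other"}

_BASES = "ACGT"
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for i in _BASES:
            for j in _BASES:
                for k in _BASES:
                    codon = i + j + k
                    _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE


def _degeneracy_lut() -> np.ndarray:
    """(64, 3) int8 class of each codon position, stops marked noncoding."""
    table = _codon_table()
    lut = np.zeros((64, 3), dtype=np.int8)
    for idx in range(64):
        codon = _BASES[idx >> 4] + _BASES[(idx >> 2) & 3] + _BASES[idx & 3]
        aa = table[codon]
        if aa == "*":
            lut[idx] = NONCODING  # stop codons are not classified
            continue
        for p in range(3):
            syn = 0
            for alt in _BASES:
                if alt == codon[p]:
                    continue
                mutant = codon[:p] + alt + codon[p + 1 :]
                if table[mutant] == aa:
                    syn += 1
            if syn == 3:
                lut[idx, p] = FOUR_FOLD
            elif syn == 0:
                lut[idx, p] = ZERO_FOLD
            else:
                lut[idx, p] = OTHER_FOLD
    return lut


_LUT: Optional[np.ndarray] = None


@dataclass
class DegeneracyMap:
    """Per-position degeneracy class and gene assignment for one chromosome.

    ``classes`` is an int8 array over the chromosome (NONCODING, ZERO_FOLD,
    FOUR_FOLD, OTHER_FOLD); ``gene_index`` maps each position to an index
    into ``genes`` (-1 outside CDS).
    """

    chrom: str
    classes: np.ndarray
    gene_index: np.ndarray
    genes: list[str]

    def class_counts(self) -> dict[str, int]:
        vals, cnts = np.unique(self.classes, return_counts=True)
        return {CLASS_NAMES[int(v)]: int(c) for v, c in zip(vals, cnts)}


_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)


def classify_degeneracy(
    reference: np.ndarray | str, cds: pd.DataFrame, chrom: str = "chr1"
) -> DegeneracyMap:
    """Assign zero-fold/four-fold/other classes inside annotated CDS.

    ``cds`` is a frame with columns chrom, start, end (0-based half-open),
    strand, gene_id (as produced by :func:`killipool.io.read_gtf_cds`).
    CDS segments of one gene are concatenated in transcription order
    (reverse-complemented for minus-strand genes); codons containing an
    ambiguous base are skipped, codons encoding a stop trigger a warning
    and are skipped, and a trailing partial codon is ignored.
    """
    global _LUT
    if _LUT is None:
        _LUT = _degeneracy_lut()
    if isinstance(reference, str):
        reference = str_to_sequence(reference)
    reference = np.asarray(reference, dtype=np.int8)
    L = reference.size
    classes = np.zeros(L, dtype=np.int8)
    gene_index = np.full(L, -1, dtype=np.int32)
    genes: list[str] = []

    sel = cds[cds["chrom"] == chrom]
    stop_warned = False
    for gi, (gene, grp) in enumerate(sel.groupby("gene_id", sort=True)):
        genes.append(gene)
        strand = grp["strand"].iloc[0]
        grp = grp.sort_values("start")
        coords = np.concatenate(
            [np.arange(r.start, r.end, dtype=np.int64) for r in grp.itertuples()]
        )
        if strand == "-":
            coords = coords[::-1]
            bases = np.where(
                reference[coords] >= 0, _COMPLEMENT[np.clip(reference[coords], 0, 3)], -1
            ).astype(np.int8)
        else:
            bases = reference[coords]
        n_codons = coords.size // 3
        for c in range(n_codons):
            b = bases[3 * c : 3 * c + 3]
            p = coords[3 * c : 3 * c + 3]
            gene_index[p] = gi
            if np.any(b < 0):
                continue  # ambiguous base: codon unclassified
            idx = (int(b[0]) << 4) | (int(b[1]) << 2) | int(b[2])
            cls = _LUT[idx]
            if np.all(cls == NONCODING):  # stop codon
                if not stop_warned:
                    warnings.warn(
                        f"internal stop codon in gene {gene}; codon excluded",
                        stacklevel=2,
                    )
                    stop_warned = True
                continue
            classes[p] = cls
    return DegeneracyMap(chrom=chrom, classes=classes, gene_index=gene_index, genes=genes)


# ---------------------------------------------------------------------------
# allele calling and polarization
# ---------------------------------------------------------------------------


def call_major_allele(counts: np.ndarray) -> int:
    """Majority base call for a pseudogenome: -1 (N) if uncovered, tied,
    or more than two alleles are observed."""
    counts = np.asarray(counts)
    observed = int((counts > 0).sum())
    if observed == 0 or observed > 2:
        return -1
    order = np.argsort(counts, kind="stable")
    if observed == 2 and counts[order[-1]] == counts[order[-2]]:
        return -1  # tie: conservative masking
    return int(order[-1])


@dataclass
class PolarizedSite:
    """One coding site polarized against the outgroup."""

    chrom: str
    pos: int
    degeneracy: int
    outgroup_base: int
    derived_base: int
    derived_count: int
    total_count: int
    daf: float
    status: str


def polarize(
    counts: np.ndarray,
    outgroup_base: int,
    min_depth: int,
    max_depth: int,
    chrom: str = "chr1",
    pos: int = 0,
    degeneracy: int = NONCODING,
) -> PolarizedSite:
    """Polarize a single site's pooled counts against the outgroup base."""
    counts = np.asarray(counts, dtype=np.int64)
    depth = int(counts.sum())

    def _site(derived, dcount, total, daf, status):
        return PolarizedSite(
            chrom, int(pos), int(degeneracy), int(outgroup_base),
            int(derived), int(dcount), int(total), float(daf), status,
        )

    if outgroup_base < 0 or outgroup_base > 3:
        return _site(-1, 0, depth, np.nan, "excluded")
    if depth < min_depth or depth > max_depth:
        return _site(-1, 0, depth, np.nan, "excluded")
    strong = counts >= 2
    if int(strong.sum()) > 2:
        return _site(-1, 0, depth, np.nan, "excluded")
    present = counts > 0
    order = np.argsort(counts, kind="stable")
    major = int(order[-1])
    n_alleles = int(present.sum())
    if n_alleles == 1 or (n_alleles >= 2 and counts[order[-2]] <= 1):
        # single-read minor alleles are treated as absent -> monomorphic
        if major == outgroup_base:
            return _site(-1, 0, depth, 0.0, "monomorphic")
        return _site(major, int(counts[major]), depth, 1.0, "fixed")
    # biallelic with both alleles supported by >= 2 reads
    a, b = int(order[-1]), int(order[-2])
    total = int(counts[a] + counts[b])
    if outgroup_base not in (a, b):
        return _site(-1, 0, depth, np.nan, "excluded")
    derived = b if outgroup_base == a else a
    daf = counts[derived] / total
    if daf < 0.05:
        status = "monomorphic"
    elif daf > 0.95:
        status = "fixed"
    else:
        status = "polymorphic"
    return _site(derived, int(counts[derived]), total, daf, status)


def polarize_table(
    counts: np.ndarray,
    outgroup: np.ndarray,
    degeneracy: DegeneracyMap,
    min_depth: int,
    max_depth: int,
    positions: Optional[np.ndarray] = None,
    chrom: str = "chr1",
    classes_keep: tuple[int, ...] = (ZERO_FOLD, FOUR_FOLD),
) -> pd.DataFrame:
    """Vectorized polarization of all zero-fold/four-fold sites of one pool.

    ``counts`` is (L, 4) for the chromosome (or for ``positions`` when
    given); returns a frame with columns pos, gene, degeneracy, outgroup,
    derived, derived_count, total_count, daf, status — one row per site in
    ``classes_keep`` (excluded rows retained with status ``excluded``).
    The per-site rules are identical to :func:`polarize`.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if positions is None:
        positions = np.arange(counts.shape[0], dtype=np.int64)
    cls_at = degeneracy.classes[positions]
    keep = np.isin(cls_at, classes_keep)
    pos = positions[keep]
    C = counts[keep]
    og = np.asarray(outgroup, dtype=np.int8)[pos]
    cls = cls_at[keep]
    gene = degeneracy.gene_index[pos]
    n = pos.size

    depth = C.sum(axis=1)
    order = np.argsort(C, axis=1, kind="stable")
    major = order[:, -1]
    second = order[:, -2]
    cmaj = C[np.arange(n), major]
    csec = C[np.arange(n), second]

    excluded = (og < 0) | (depth < min_depth) | (depth > max_depth)
    excluded |= (C >= 2).sum(axis=1) > 2

    mono = ~excluded & (csec <= 1)
    mono_diff = mono & (major != og)

    bial = ~excluded & ~mono
    og_is_major = og == major
    og_is_second = og == second
    tri_species = bial & ~(og_is_major | og_is_second)
    excluded |= tri_species
    bial &= ~tri_species

    derived = np.where(og_is_major, second, major)
    dcount = np.where(og_is_major, csec, cmaj).astype(np.int64)
    total = (cmaj + csec).astype(np.int64)
    daf = np.full(n, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        daf[bial] = dcount[bial] / total[bial]
    daf[mono] = np.where(mono_diff[mono], 1.0, 0.0)
    daf[excluded] = np.nan

    status = np.full(n, "excluded", dtype=object)
    status[mono] = np.where(mono_diff[mono], "fixed", "monomorphic")
    status[bial & (daf < 0.05)] = "monomorphic"
    status[bial & (daf > 0.95)] = "fixed"
    status[bial & (daf >= 0.05) & (daf <= 0.95)] = "polymorphic"

    out_derived = np.where(excluded, -1, np.where(mono & ~mono_diff, -1, np.where(mono_diff, major, derived)))
    out_dcount = np.where(excluded | (mono & ~mono_diff), 0, np.where(mono_diff, cmaj, dcount))
    out_total = np.where(bial, total, depth)

    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "gene": gene,
            "degeneracy": cls,
            "outgroup": og,
            "derived": out_derived.astype(np.int8),
            "derived_count": out_dcount.astype(np.int64),
            "total_count": out_total.astype(np.int64),
            "daf": daf,
            "status": status,
        }
    )


# ---------------------------------------------------------------------------
# segregation posterior filter
# ---------------------------------------------------------------------------


def segregation_posterior(
    minor_count: int, depth: int, error_rate: float = 0.01
) -> float:
    """Posterior probability that a site truly segregates.

    A dependency-free Bayesian filter standing between raw pooled counts
    and the polymorphism set: with equal prior odds, the site is either
    monomorphic (minor reads arise from sequencing error at ``error_rate``,
    symmetric in the two alleles) or segregating with a uniform prior on
    the allele frequency, under which the marginal likelihood of any minor
    count is 1 / (depth + 1) (beta-binomial with a flat beta).
    """
    if depth < 1:
        return 0.0
    l_seg = 1.0 / (depth + 1.0)
    l_mono = 0.5 * (
        stats.binom.pmf(minor_count, depth, error_rate)
        + stats.binom.pmf(depth - minor_count, depth, error_rate)
    )
    return float(l_seg / (l_seg + l_mono))


def segregation_filter(
    table: pd.DataFrame, posterior_threshold: float = 0.9, error_rate: float = 0.01
) -> pd.DataFrame:
    """Demote low-confidence polymorphic sites to ``excluded``.

    Polymorphic rows are kept iff their segregation posterior exceeds the
    threshold; monomorphic/fixed/excluded rows pass through unchanged.
    """
    if not 0.0 < posterior_threshold < 1.0:
        raise ValueError("posterior_threshold must lie strictly in (0, 1)")
    out = table.copy()
    poly = out["status"].to_numpy() == "polymorphic"
    if not poly.any():
        return out
    minor = np.minimum(
        out.loc[poly, "derived_count"].to_numpy(),
        out.loc[poly, "total_count"].to_numpy() - out.loc[poly, "derived_count"].to_numpy(),
    )
    depth = out.loc[poly, "total_count"].to_numpy()
    post = np.array(
        [segregation_posterior(int(k), int(m), error_rate) for k, m in zip(minor, depth)]
    )
    demote = np.zeros(len(out), dtype=bool)
    demote[np.nonzero(poly)[0][post <= posterior_threshold]] = True
    out.loc[demote, "status"] = "excluded"
    return out
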