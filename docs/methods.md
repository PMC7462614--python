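# Methods

`killipool` re-implements, as a tested library, the population-genomic
inference chain used to study relaxed purifying selection in wild turquoise
killifish (*Nothobranchius furzeri*) populations of very different effective
size: pooled-sequencing diversity, differentiation, McDonald–Kreitman-style
selection statistics, distribution-of-fitness-effects (DFE) inference, and
the forward simulations that connect small N_e to the accumulation of
slightly deleterious variation.  This note records the models, defaults and
numerical choices, and what the synthetic data do and do not emulate.

## Forward simulation (`simgen`)

The simulator is a diploid Wright–Fisher model with selection and
recombination on a linear genome of `n_cds` coding blocks (default 1500 ×
500 bp) separated by non-coding spacers.  Coding positions follow a
codon-like 3-periodic layout: the third position of each codon is neutral
(synonymous-like), the first two are selected (non-synonymous-like), i.e.
1/3 : 2/3 by default.  Only complete codons are mutable; spacers carry no
mutations (they exist to give windows and genes realistic geometry, not to
model intergenic evolution).

Each generation: parents are drawn with probability proportional to fitness
(multiplicative across sites, heterozygote `1 + h s`, homozygote `1 + s`,
floored at 0); each gamete receives a Poisson number of crossovers at the
per-bp recombination rate, placed uniformly; new mutations arise Poisson
per gamete over coding positions.  Selected mutations draw `s` from a
*reflected gamma* (all deleterious) with mean −2.5 and shape 0.35 on the
unscaled `s` scale, dominance `h = 0.1`.  The mean is read literally on the
`s` scale; because that convention is ambiguous in parts of the literature
it is a configurable parameter of `DFEParams`, not a constant.

Demography: a single ancestral population of `ancestral_size` diploids runs
a burn-in (default 50,000 generations, i.e. five ancestral sizes at the
canonical N = 10,000), then daughters split.  The four canonical scenarios
are built by `build_demography`: instant size change then constant (A, B)
or exponential growth to the target reached exactly at the final generation
(C, D), splitting either right after the burn-in (B, D) or later (A, C).
`build_star_demography` generalises to k daughters splitting at once — the
three-population study layout.  Trajectories are deterministic integer
arrays; two runs with the same seed are bit-identical.

Canonical rates are the rescaled values tied to N = 10,000: mutation
5.468928e-8 and recombination 6.604764e-6 per bp per generation.

Implementation notes: haplotypes are a boolean carriage matrix over
segregating columns; columns fixed in a population move to a per-population
fixed ledger (a fixed deleterious allele shifts all fitnesses equally, so
it can leave the matrix without changing dynamics); selection is soft
(relative fitness), so the population cannot go extinct through load — the
stated extinction error can only arise from a degenerate size trajectory.
Recurrent mutation at a site is allowed as separate columns; when emitting
sequences, the younger allele wins on haplotypes carrying both (a handful
of sites per run at desk scale).

### Emission of pipeline inputs

`simulate_study` writes everything the analysis consumes, with truth
tables: reference FASTA (codons drawn from two-base prefixes whose third
position is exactly four-fold and first two exactly zero-fold degenerate,
with no stop codon one substitution away), CDS GTF (1-based, closed,
`gene_id` attributes), an outgroup pseudogenome (independent per-site
substitutions at a configurable divergence, default 2%, recorded
positions), and PoPoolation2-style sync counts from pooled sequencing
emulation: per site, depth ~ Poisson(coverage), base reads multinomial at
the sample's allele frequencies perturbed by a uniform error model
(mis-read probability `error_rate`, default 0.002, spread equally over the
other three bases).

### Desk scale

Tests and the acceptance script run the study at a reduced scale chosen
once: ancestral N = 500 (daughters 10:1, e.g. 500 vs 50; three-population
study 100/250/500), burn-in 5N = 2500 generations, 500 post-split
generations, 150 CDS × 500 bp, per-bp mutation rate raised by the same
factor the sizes were reduced (4Nμ preserved; 1.0937856e-6 at N = 500).
The per-bp recombination rate stays at the canonical value (~0.6 crossovers
per gamete) rather than being rescaled upward; this weakens linkage
interference slightly and is immaterial to the contrasts tested.  The
neutral-recovery check keeps N = 1000, ~1 Mb and 10N generations so that
θ_W and π can be compared with 4Nμ directly.

What the generator does *not* emulate: mapping artefacts, indels, base
quality, GC / CpG mutation-rate heterogeneity, gene conversion, linked
non-coding regulation, migration, and overlapping reads.  Passing tests
therefore validate the estimators and inference chain, not robustness to
alignment noise.

## Site classification and polarization (`sites`)

Degeneracy is computed per codon from the standard genetic code: a position
is four-fold if all four bases encode the same amino acid, zero-fold if
every change is non-synonymous, otherwise "other" (excluded from MK/DFE
analyses, which use only 0-fold and 4-fold sites).  Minus-strand CDS are
read reverse-complemented; codons with ambiguous bases are skipped; codons
encoding a stop raise a warning and are skipped.

Pseudogenome calls use majority rule: most-supported base; `N` for zero
coverage, more than two observed alleles, or a tie (the tie rule is
conservative masking; the source rule only covers a strict majority).

Polarization of pooled counts against the outgroup base, in order:
outgroup base not A/C/G/T, coverage outside the per-population bounds
(defaults GNP 24–94, NF414 19–77, NF303 18–70), or more than two alleles
with ≥ 2 reads → excluded; a minor allele with exactly one supporting read
is treated as absent (site monomorphic for the major allele); a biallelic
site whose outgroup base matches neither allele (tri-allelic across
species) → excluded.  The derived allele is the allele not carried by the
outgroup; DAF = derived reads / reads of the two alleles.  DAF > 0.95 →
fixed (counts as divergence, like a monomorphic site differing from the
outgroup); DAF < 0.05 → monomorphic (the *ancestral* allele is effectively
fixed — not divergence); otherwise polymorphic.

The external Bayesian SNP caller of the original workflow is replaced by a
documented stand-in with the same role: with equal prior odds, a site is
monomorphic (minor reads arising from sequencing error, symmetric in the
two alleles) or segregating with a uniform frequency prior, under which the
marginal likelihood of any minor count is 1/(depth+1).  Polymorphic sites
are kept when the posterior probability of segregation exceeds 0.9.

## Diversity (`diversity`)

Per-site heterozygosity is the unbiased read-pair estimate
π = M/(M−1) · (1 − Σ (c_a/M)²).  Windows are non-overlapping 50 kb,
reported only if ≥ 30% of positions pass the coverage bounds (defaults half
to twice the mean depth, overridable with the per-population values).
Watterson's θ_W = S/(a_n · covered) where S counts SNPs whose two most
frequent alleles both have ≥ `min_count` reads (default 2) and
a_n = H_{n−1} with n the *haploid pool size* (the pool bounds the number of
sampled lineages, not the read depth).  The same min-count filter gates the
sites contributing to π; the full finite-pool bias corrections of the
original windowing tool are not re-derived — at the deep coverage used in
validation the residual bias is negligible, and the mode is documented as
such.  N_e = θ/(2·ploidy·μ) with μ = 2.6321e-9 per bp per generation
(one killifish generation per year).

## Differentiation (`differentiation`)

Per-SNP F_ST is the classical π-based form (π_total − π_within)/π_total,
with π_within the mean of the two pools and π_total from the summed counts;
negative estimates are clamped to 0, undefined sites (π_total = 0) are
missing.  Window and gene values average per-SNP F_ST over qualifying SNPs
(min minor count 4, min coverage 20, per-population coverage maxima), so a
gene is exactly a window spanning the gene body.  Per pair, window F_ST is
Z-transformed and the empirical 0.5% / 99.5% type-7 quantiles flag outlier
windows.  Candidate genes under strong differentiation must meet all three
criteria: overlap a high-tail window, gene-scope F_ST above the 99.5th
percentile of genes, and ≥ 1 SNP significant by two-sided Fisher exact test
at BH-adjusted p < 0.001.  The neighbour-joining tree of genome-wide
pairwise F_ST keeps negative branch lengths as reported.

## Selection statistics and DFE (`selection`)

Per gene, Dn/Ds count fixed 0-fold/4-fold differences (DAF > 0.95 or
monomorphic-and-different), Pn/Ps count biallelic sites with
0.05 ≤ DAF ≤ 0.95, binned by DAF into 9 equal bins spanning [0.05, 0.95]
(the bin count is configurable; nothing downstream is sensitive to it).
α(x) = 1 − (Ds/Dn)(Pn(x)/Ps(x)); segregating slightly deleterious variants
depress the low-frequency bins, so the adaptive fraction is estimated as
the asymptote of a + b·exp(−c·x) at x = 1, fitted by nonlinear least
squares with a linear-extrapolation fallback (flagged) when c is not
identifiable.  Confidence intervals bootstrap over genes (200 replicates by
default).  DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps) per gene, defined only for genes
with at least one substitution and one polymorphism; population summaries
report the median and the 2.5% / 97.5% tail gene sets.

Spectra: the unfolded SFS per site class at the native pool size (derived
counts rounded from DAF) is projected to 10 chromosomes by expected
hypergeometric sampling; mass landing on the monomorphic classes leaves the
spectrum and is recorded.  The DFE fit maximises the Poisson composite
likelihood of the non-synonymous SFS under the diffusion expectation
E[F_i] = θ ∫ H(x;S) C(n,i) xⁱ(1−x)ⁿ⁻ⁱ dx with
H(x;S) = (1−e^{−S(1−x)})/(x(1−x)(1−e^{−S})) and S = 4N_e·s, written in an
expm1 form stable to S ≈ −10⁶ (domain truncated to x ≤ 200/|S| for strong
selection).  −S follows a gamma with free shape and mean; the integral over
the gamma uses 160 quantile nodes against a cached log-log interpolation of
b_i(|S|) on a 120-point grid (1e-4 to 1e6).  θ_nonsyn is profiled
analytically; θ_syn comes from the neutral fit of the synonymous SFS.
Model choice by AIC between the deleterious-only gamma and gamma plus a
neutral point mass.  This is a deliberate simplification of full DFE
tooling: no polarization-error parameter, no demographic ridge corrections,
no beneficial component — matching the final simulation analysis the
pipeline validates.  Note the well-known shape/mean likelihood ridge: the
gamma *shape* is recovered accurately (median absolute error ≈ 0.03 at
megabase scale in the tests) while the mean of 4N_e·s is only weakly
identified from a 10-chromosome SFS; results report both, but only the
shape should be interpreted quantitatively.

## Orchestration (`pipeline`, `cli`)

`RunConfig` + `run()` execute sites → diversity → fst → selection on
FASTA/GTF/sync inputs, writing per-stage TSV/BED/newick outputs (each with
a coordinate-convention header) and a `summary.json` of headline numbers
(θ_W, π, N_e per population; pairwise genome-wide F_ST and NJ tree; MK
counts, pooled and asymptotic α, median DoS; DFE parameters).  The summary
hash covers analysis parameters only, so identical configs and seeds give
byte-identical summaries regardless of paths.  The `killipool` command
exposes `simulate`, `sites`, `diversity`, `fst`, `selection`, `dfe` and
`run`; a YAML config can stand in for flags.

## Known limitations

* Pool-seq estimators use read-level frequencies without the finite-pool
  min-count bias corrections; shallow-coverage θ_W is biased downward.
* The DoS contrast between populations is measured against an outgroup at
  2% divergence because desk-scale post-split fixation counts are too
  sparse for per-gene statistics; outgroup-branch substitutions dilute the
  Dn/(Dn+Ds) term equally across populations, so the contrast is driven by
  the polymorphism term, as in the real-data design.
* The segregation filter is a stand-in posterior, not a re-implementation
  of the original Bayesian caller; only its role (a >0.9 posterior
  threshold) is preserved.
* Single chromosome only; no indels; no overlapping windows; no
  haplotype-based selection scans.
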