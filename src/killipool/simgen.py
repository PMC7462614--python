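"""Forward Wright-Fisher simulation with selection, and synthetic-data emission.

This module provides the generative machinery for the whole pipeline: a
diploid Wright-Fisher simulator with multiplicative fitness, Poisson
crossover recombination and a reflected-gamma distribution of fitness
effects (DFE) for non-synonymous-like mutations, plus emitters that turn a
simulation into the concrete inputs the analysis stages consume (reference
FASTA, CDS annotation, outgroup pseudogenome, pooled read counts) with the
underlying truth recorded for validation.

The simulated genome is a linear chromosome of ``n_cds`` coding blocks
separated by non-coding spacers.  Coding positions follow a codon-like
3-periodic structure: by default the last position of each codon is neutral
(synonymous-like, a stand-in for four-fold degenerate sites) and the first
two are under selection (non-synonymous-like, zero-fold).  Selection
coefficients of selected mutations are drawn from a reflected gamma
distribution (all deleterious); fitness is multiplicative across sites with
heterozygote effect ``1 + h*s`` and homozygote effect ``1 + s``.

Two demographic lineages ("daughter populations") may split from a common
ancestral population after a burn-in phase, with instant size changes or
exponential growth, mirroring the four canonical two-population scenarios
(models A-D) used to study relaxed purifying selection under reduced
effective population size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BASES",
    "GenomeLayout",
    "DFEParams",
    "DemographyPlan",
    "SimConfig",
    "PopulationResult",
    "SimOutput",
    "OutgroupResult",
    "SimulationError",
    "build_demography",
    "build_star_demography",
    "draw_selection_coefficient",
    "simulate_forward",
    "pool_reads",
    "mutate_outgroup",
    "population_site_frequencies",
    "sample_allele_counts",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_STR = "ACGT"

# codon prefixes whose third position is four-fold degenerate and whose
# first two positions are zero-fold degenerate (no stop-codon neighbours)
_SAFE_CODON_PREFIXES = ["GC", "GT", "CC", "AC", "TC", "CG", "GG"]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot proceed (extinction, memory guard)."""


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Geometry of the simulated chromosome.

    Parameters
    ----------
    n_cds : int
        Number of coding blocks (default 1500).
    cds_length : int
        Length of each coding block in bp (default 500).  Only complete
        codons (``3 * (cds_length // 3)`` bp) are mutable and classified.
    spacer_length : int
        Length of the non-coding spacer following each coding block.
        Spacers carry no mutations.
    neutral_fraction, deleterious_fraction : float
        Fractions of coding positions that are neutral (synonymous-like)
        versus selected (non-synonymous-like).  Must sum to 1.  Positions
        are assigned 3-periodically within each codon, neutral slots last,
        so the default 1/3 : 2/3 gives one neutral and two selected
        positions per codon.
    """

    n_cds: int = 1500
    cds_length: int = 500
    spacer_length: int = 100
    neutral_fraction: float = 1.0 / 3.0
    deleterious_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.n_cds < 1 or self.cds_length < 3:
            raise ValueError("need at least one CDS of >= 3 bp")
        if self.spacer_length < 0:
            raise ValueError("spacer_length must be >= 0")
        if not np.isclose(self.neutral_fraction + self.deleterious_fraction, 1.0):
            raise ValueError("neutral_fraction + deleterious_fraction must be 1")

    @property
    def unit_length(self) -> int:
        return self.cds_length + self.spacer_length

    @property
    def genome_length(self) -> int:
        return self.n_cds * self.unit_length

    @property
    def codons_per_cds(self) -> int:
        return self.cds_length // 3

    def cds_intervals(self) -> np.ndarray:
        """(n_cds, 2) array of 0-based half-open CDS intervals."""
        starts = np.arange(self.n_cds, dtype=np.int64) * self.unit_length
        return np.column_stack([starts, starts + self.cds_length])

    def site_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """Mutable positions and their class (0 = neutral, 1 = deleterious).

        Only complete codons are mutable; the trailing partial codon of a
        CDS whose length is not a multiple of 3 is skipped.
        """
        n_slots = int(round(3 * self.neutral_fraction))
        ncod = self.codons_per_cds
        offs = np.arange(3 * ncod, dtype=np.int64)
        cls_unit = np.where(offs % 3 >= 3 - n_slots, 0, 1).astype(np.int8)
        starts = np.arange(self.n_cds, dtype=np.int64) * self.unit_length
        pos = (starts[:, None] + offs[None, :]).ravel()
        cls = np.tile(cls_unit, self.n_cds)
        return pos, cls


@dataclass(frozen=True)
class DFEParams:
    """Reflected-gamma distribution of fitness effects for selected sites.

    ``gamma_mean`` is the mean of the (negative) selection coefficient *s*
    on the unscaled per-generation scale, ``gamma_shape`` the gamma shape,
    and ``dominance`` the dominance coefficient *h* of the heterozygote.
    Defaults follow the rescaled forward-simulation parameterisation
    (mean -2.5, shape 0.35, h = 0.1).
    """

    gamma_mean: float = -2.5
    gamma_shape: float = 0.35
    dominance: float = 0.1

    def __post_init__(self) -> None:
        if not self.gamma_mean < 0:
            raise ValueError("gamma_mean must be negative")
        if not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be positive")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must lie in [0, 1]")


def draw_selection_coefficient(
    rng: np.random.Generator, dfe: DFEParams, size: Optional[int] = None
) -> np.ndarray | float:
    """Draw selection coefficients s = -g with g ~ Gamma(shape, mean/shape).

    The reflected gamma has mean ``dfe.gamma_mean`` (negative) and variance
    ``gamma_mean**2 / gamma_shape``.
    """
    scale = abs(dfe.gamma_mean) / dfe.gamma_shape
    return -rng.gamma(dfe.gamma_shape, scale, size=size)


@dataclass(frozen=True)
class DemographyPlan:
    """Two-population demography with a common ancestor.

    Generations are counted in two phases: a burn-in of ``burn_in``
    generations at ``ancestral_size``, then ``total_generations`` further
    generations during which the population splits at ``split_generation``
    (measured from the end of the burn-in).  ``None`` for
    ``split_generation`` means a single population throughout.

    ``traj1``/``traj2`` give the diploid size of each daughter at
    post-burn-in generation t (arrays of length ``total_generations + 1``);
    before the split only lineage 1 exists, at ``ancestral_size``.
    """

    model_id: str
    ancestral_size: int
    burn_in: int
    split_generation: Optional[int]
    total_generations: int
    traj1: np.ndarray = field(repr=False)
    traj2: Optional[np.ndarray] = field(repr=False, default=None)
    extra_trajs: tuple = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.ancestral_size < 2:
            raise ValueError("ancestral_size must be >= 2")
        if self.burn_in < 0 or self.total_generations < 0:
            raise ValueError("generation counts must be >= 0")
        if self.split_generation is not None:
            if not 0 <= self.split_generation <= self.total_generations:
                raise ValueError("split_generation outside [0, total_generations]")
            if self.traj2 is None:
                raise ValueError("multi-population plan needs traj2")
        elif self.extra_trajs:
            raise ValueError("extra daughters require a split_generation")
        for traj in (self.traj1, self.traj2, *self.extra_trajs):
            if traj is not None and np.any(np.asarray(traj) < 2):
                raise ValueError("population sizes must stay >= 2")

    @property
    def n_populations(self) -> int:
        if self.split_generation is None:
            return 1
        return 2 + len(self.extra_trajs)

    @property
    def n_generations(self) -> int:
        return self.burn_in + self.total_generations

    def _trajs(self) -> list[np.ndarray]:
        trajs = [self.traj1]
        if self.traj2 is not None:
            trajs.append(self.traj2)
        trajs.extend(self.extra_trajs)
        return trajs

    def size_at(self, pop: int, t_post: int) -> int:
        """Diploid size of daughter ``pop`` at post-burn-in time t."""
        trajs = self._trajs()
        if pop >= len(trajs):
            raise ValueError(f"plan has only {len(trajs)} population(s)")
        return int(trajs[pop][t_post])

    @classmethod
    def single(
        cls, size: int, generations: int, burn_in: int = 0
    ) -> "DemographyPlan":
        traj = np.full(generations + 1, size, dtype=np.int64)
        return cls(
            model_id="custom",
            ancestral_size=size,
            burn_in=burn_in,
            split_generation=None,
            total_generations=generations,
            traj1=traj,
        )


def build_demography(
    model_id: str,
    ancestral_size: int,
    daughter_sizes: Sequence[int],
    split_generation: int,
    total_generations: int,
    burn_in: int = 50_000,
) -> DemographyPlan:
    """Construct the size trajectories of the four canonical scenarios.

    Models A and B change the daughter sizes instantly at the split and
    keep them constant; models C and D grow each daughter exponentially
    from the ancestral size so that the target is reached exactly at
    ``total_generations``.  Models B and D split immediately after the
    burn-in (``split_generation == 0`` is required); A and C may split
    later, the single ancestral lineage persisting in between.
    """
    model_id = model_id.upper()
    if model_id not in {"A", "B", "C", "D"}:
        raise ValueError(f"unknown model_id {model_id!r}")
    n1, n2 = (int(s) for s in daughter_sizes)
    if n1 < 2 or n2 < 2 or ancestral_size < 2:
        raise ValueError("population sizes must be >= 2")
    if not 0 <= split_generation <= total_generations:
        raise ValueError("split_generation outside [0, total_generations]")
    if model_id in {"B", "D"} and split_generation != 0:
        raise ValueError(f"model {model_id} requires split_generation = 0")

    t = np.arange(total_generations + 1, dtype=np.float64)
    trajs = []
    for target in (n1, n2):
        traj = np.full(total_generations + 1, ancestral_size, dtype=np.int64)
        span = total_generations - split_generation
        if model_id in {"A", "B"}:
            traj[split_generation:] = target
        else:  # exponential growth C, D
            if span == 0:
                traj[-1] = target
            else:
                rate = np.log(target / ancestral_size) / span
                grown = ancestral_size * np.exp(rate * (t[split_generation:] - split_generation))
                traj[split_generation:] = np.rint(grown).astype(np.int64)
                traj[-1] = target
        trajs.append(traj)
    return DemographyPlan(
        model_id=model_id,
        ancestral_size=ancestral_size,
        burn_in=burn_in,
        split_generation=split_generation,
        total_generations=total_generations,
        traj1=trajs[0],
        traj2=trajs[1],
    )


def build_star_demography(
    ancestral_size: int,
    daughter_sizes: Sequence[int],
    split_generation: int,
    total_generations: int,
    burn_in: int = 50_000,
) -> DemographyPlan:
    """Star split: k daughters of constant (possibly different) sizes.

    All daughters split from the ancestral population at the same
    generation and keep their target sizes afterwards — the scenario used
    for multi-population study fixtures (e.g. three populations of
    differing effective size from one common ancestor).
    """
    sizes = [int(s) for s in daughter_sizes]
    if len(sizes) < 2:
        raise ValueError("need at least two daughter populations")
    trajs = []
    for target in sizes:
        traj = np.full(total_generations + 1, ancestral_size, dtype=np.int64)
        traj[split_generation:] = target
        trajs.append(traj)
    return DemographyPlan(
        model_id="custom",
        ancestral_size=ancestral_size,
        burn_in=burn_in,
        split_generation=split_generation,
        total_generations=total_generations,
        traj1=trajs[0],
        traj2=trajs[1],
        extra_trajs=tuple(trajs[2:]),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a forward simulation.

    Default mutation and recombination rates are the rescaled values used
    with an ancestral diploid size of 10,000 (mutation 5.468928e-8 per bp
    per generation, recombination 6.604764e-6 per bp per generation).
    """

    layout: GenomeLayout
    dfe: DFEParams
    demography: DemographyPlan
    mutation_rate: float = 5.468928e-8
    recombination_rate: float = 6.604764e-6
    seed: int = 0
    sample_size: int | tuple = 30  # diploids; a tuple gives per-population sizes
    max_segregating: int = 2_000_000

    def __post_init__(self) -> None:
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        szs = self.sample_size if isinstance(self.sample_size, (tuple, list)) else (self.sample_size,)
        if any(s < 1 for s in szs):
            raise ValueError("sample_size must be >= 1")

    def sample_size_for(self, pop_index: int) -> int:
        if isinstance(self.sample_size, (tuple, list)):
            return int(self.sample_size[min(pop_index, len(self.sample_size) - 1)])
        return int(self.sample_size)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class PopulationResult:
    """Mutations and a diploid sample from one population at the end of a run.

    Segregating arrays are aligned (one entry per segregating mutation);
    ``sample_haplotypes`` is a (2 * n_sample, n_segregating) boolean matrix
    of derived-allele carriage in the sampled diploids.  Fixed arrays list
    mutations that reached frequency 1 in this lineage (including during
    the shared burn-in), with the generation at which fixation was
    observed.
    """

    name: str
    final_size: int
    seg_pos: np.ndarray
    seg_s: np.ndarray
    seg_class: np.ndarray
    seg_derived: np.ndarray
    seg_origin: np.ndarray
    seg_freq: np.ndarray
    fixed_pos: np.ndarray
    fixed_s: np.ndarray
    fixed_class: np.ndarray
    fixed_derived: np.ndarray
    fixed_origin: np.ndarray
    fixed_gen: np.ndarray
    sample_haplotypes: np.ndarray

    @property
    def n_sample(self) -> int:
        return self.sample_haplotypes.shape[0] // 2

    def sample_derived_counts(self) -> np.ndarray:
        """Derived-allele count of each segregating mutation in the sample."""
        return self.sample_haplotypes.sum(axis=0)


@dataclass
class SimOutput:
    """Reference sequence plus per-population results of one replicate."""

    config: SimConfig
    reference: np.ndarray  # int8 base codes, length = genome_length
    populations: list[PopulationResult]
    seed: int


@dataclass
class OutgroupResult:
    """An outgroup sequence plus the truth of where it was substituted."""

    sequence: np.ndarray
    substituted_positions: np.ndarray


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------


def make_reference(layout: GenomeLayout, rng: np.random.Generator) -> np.ndarray:
    """Random reference with codon structure matching the site classes.

    Coding codons are drawn from two-base prefixes whose third position is
    four-fold degenerate and whose first two positions are zero-fold
    degenerate, with no stop codon one substitution away; spacers are
    uniform random sequence.  Returned as int8 base codes (0..3 = ACGT).
    """
    seq = rng.integers(0, 4, size=layout.genome_length, dtype=np.int8)
    ncod = layout.codons_per_cds
    prefixes = np.array(
        [[_BASE_STR.index(p[0]), _BASE_STR.index(p[1])] for p in _SAFE_CODON_PREFIXES],
        dtype=np.int8,
    )
    for i in range(layout.n_cds):
        start = i * layout.unit_length
        pick = rng.integers(0, len(prefixes), size=ncod)
        codons = np.empty((ncod, 3), dtype=np.int8)
        codons[:, :2] = prefixes[pick]
        codons[:, 2] = rng.integers(0, 4, size=ncod, dtype=np.int8)
        seq[start : start + 3 * ncod] = codons.ravel()
    return seq


def sequence_to_str(seq: np.ndarray) -> str:
    return BASES[np.asarray(seq, dtype=np.int64)].tobytes().decode("ascii")


def str_to_sequence(s: str) -> np.ndarray:
    arr = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


# ---------------------------------------------------------------------------
# mutation registry and per-population state
# ---------------------------------------------------------------------------


class _Registry:
    """Append-only store of every mutation ever created in a replicate."""

    def __init__(self) -> None:
        self.pos: list[int] = []
        self.s: list[float] = []
        self.mclass: list[int] = []
        self.derived: list[int] = []
        self.origin: list[int] = []

    def add(self, pos, s, mclass, derived, origin) -> np.ndarray:
        n0 = len(self.pos)
        self.pos.extend(int(p) for p in pos)
        self.s.extend(float(v) for v in s)
        self.mclass.extend(int(c) for c in mclass)
        self.derived.extend(int(d) for d in derived)
        self.origin.extend(int(origin) for _ in pos)
        return np.arange(n0, len(self.pos), dtype=np.int64)

    def take(self, ids: np.ndarray, attr: str) -> np.ndarray:
        arr = np.asarray(getattr(self, attr))
        out = arr[ids] if len(ids) else arr[:0]
        return out


class _Pop:
    """Haplotype state of one population: a boolean carriage matrix."""

    def __init__(self, n_diploid: int, h_del: float) -> None:
        self.n = n_diploid
        self.h_del = h_del
        self.X = np.zeros((2 * n_diploid, 0), dtype=bool)
        self.ids = np.zeros(0, dtype=np.int64)
        self.pos = np.zeros(0, dtype=np.int64)
        self.s = np.zeros(0, dtype=np.float64)
        self.is_del = np.zeros(0, dtype=bool)
        self.fixed_ids: list[int] = []
        self.fixed_gen: list[int] = []

    def copy(self) -> "_Pop":
        other = _Pop.__new__(_Pop)
        other.n = self.n
        other.h_del = self.h_del
        other.X = self.X.copy()
        other.ids = self.ids.copy()
        other.pos = self.pos.copy()
        other.s = self.s.copy()
        other.is_del = self.is_del.copy()
        other.fixed_ids = list(self.fixed_ids)
        other.fixed_gen = list(self.fixed_gen)
        return other

    # -- fitness ---------------------------------------------------------
    def _fitness(self) -> Optional[np.ndarray]:
        sel = self.is_del & (self.s != 0.0)
        if not sel.any():
            return None
        Xu = self.X.view(np.uint8)[:, sel]
        G = (Xu[0::2] + Xu[1::2]).astype(np.float32)  # 0/1/2 derived copies
        s = self.s[sel]
        # fitness floor keeps log finite; exp() still underflows to 0 weight
        lhet = np.log(np.maximum(1.0 + self.h_del * s, 1e-300)).astype(np.float32)
        lhom = np.log(np.maximum(1.0 + s, 1e-300)).astype(np.float32)
        # G @ lhet covers heterozygotes; Q = G(G-1)/2 swaps in lhom for homozygotes
        logw = G @ lhet
        if np.any(G > 1.5):
            Q = 0.5 * G * (G - 1.0)
            logw += Q @ (lhom - 2.0 * lhet)
        w = np.exp((logw - logw.max()).astype(np.float64))
        return w

    # -- one generation --------------------------------------------------
    def step(
        self,
        n_next: int,
        rng: np.random.Generator,
        genome_length: int,
        rho_per_gamete: float,
        mu_per_gamete: float,
        mutable_pos: np.ndarray,
        mutable_class: np.ndarray,
        reference: np.ndarray,
        registry: _Registry,
        generation: int,
        max_segregating: int,
    ) -> None:
        if n_next < 1:
            raise SimulationError(f"population size reached 0 at generation {generation}")
        w = self._fitness()
        n_gam = 2 * n_next
        if w is None:
            parents = rng.integers(0, self.n, size=n_gam)
        else:
            cw = np.cumsum(w)
            if cw[-1] <= 0.0:
                raise SimulationError(
                    f"total fitness collapsed to 0 at generation {generation}"
                )
            parents = np.searchsorted(cw, rng.random(n_gam) * cw[-1])
        start = rng.integers(0, 2, size=n_gam)
        rows = 2 * parents + start
        K = self.X.shape[1]

        # new mutations this generation
        n_new = rng.poisson(mu_per_gamete * n_gam)
        if K + n_new > max_segregating:
            raise SimulationError("segregating-mutation cap exceeded (memory guard)")

        if n_new == 0:
            C = np.take(self.X, rows, axis=0)
        else:
            C = np.empty((n_gam, K + n_new), dtype=bool)
            if K:
                C[:, :K] = np.take(self.X, rows, axis=0)
        if n_new:
            C[:, K:] = False

        # recombination: Poisson crossovers on the linear genome; the parity
        # of crossovers left of a site decides which parental haplotype it
        # comes from (built up as an XOR over the padded crossover list)
        if rho_per_gamete > 0.0 and K:
            nx = rng.poisson(rho_per_gamete, size=n_gam)
            rec = np.nonzero(nx)[0]
            if rec.size:
                kmax = int(nx[rec].max())
                cuts = rng.uniform(0, genome_length, size=(rec.size, kmax))
                cuts[np.arange(kmax)[None, :] >= nx[rec][:, None]] = np.inf
                mask = self.pos[None, :] >= cuts[:, 0, None]
                for k in range(1, kmax):
                    np.logical_xor(mask, self.pos[None, :] >= cuts[:, k, None], out=mask)
                other = np.take(self.X, 2 * parents[rec] + 1 - start[rec], axis=0)
                C[rec, :K] = np.where(mask, other, C[rec, :K])

        # place new mutations on random gametes
        if n_new:
            mpick = rng.integers(0, mutable_pos.size, size=n_new)
            new_pos = mutable_pos[mpick]
            new_cls = mutable_class[mpick]
            new_s = np.zeros(n_new, dtype=np.float64)
            ndel = int((new_cls == 1).sum())
            if ndel:
                new_s[new_cls == 1] = self._draw_s(rng, ndel)
            new_derived = (reference[new_pos] + rng.integers(1, 4, size=n_new)) % 4
            new_ids = registry.add(new_pos, new_s, new_cls, new_derived, generation)
            carriers = rng.integers(0, n_gam, size=n_new)
            C[carriers, K + np.arange(n_new)] = True
            self.ids = np.concatenate([self.ids, new_ids])
            self.pos = np.concatenate([self.pos, new_pos])
            self.s = np.concatenate([self.s, new_s])
            self.is_del = np.concatenate([self.is_del, new_cls == 1])

        self.X = C
        self.n = n_next

    _dfe: Optional[DFEParams] = None

    def _draw_s(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return draw_selection_coefficient(rng, self._dfe, size=size)

    # -- bookkeeping -----------------------------------------------------
    def prune(self, generation: int) -> None:
        if self.X.shape[1] == 0:
            return
        counts = self.X.sum(axis=0)
        fixed = counts == self.X.shape[0]
        if fixed.any():
            self.fixed_ids.extend(int(i) for i in self.ids[fixed])
            self.fixed_gen.extend(int(generation) for _ in range(int(fixed.sum())))
        keep = (counts > 0) & ~fixed
        if not keep.all():
            self.X = np.ascontiguousarray(self.X[:, keep])
            self.ids = self.ids[keep]
            self.pos = self.pos[keep]
            self.s = self.s[keep]
            self.is_del = self.is_del[keep]


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

_PRUNE_EVERY = 4


def simulate_forward(config: SimConfig) -> SimOutput:
    """Run one replicate of the diploid Wright-Fisher simulation.

    Each generation, parents are sampled with probability proportional to
    fitness (multiplicative across sites), gametes recombine with a
    Poisson number of crossovers at the configured per-bp rate, and new
    mutations arise Poisson-distributed over coding positions: neutral
    mutations (s = 0) at neutral-class positions, selected mutations with
    a reflected-gamma s at deleterious-class positions.  After the final
    generation a sample of ``sample_size`` diploids is drawn from each
    population.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    demog = config.demography
    reference = make_reference(layout, rng)
    mutable_pos, mutable_class = layout.site_classes()
    L = layout.genome_length
    mu_per_gamete = config.mutation_rate * mutable_pos.size
    rho_per_gamete = config.recombination_rate * max(L - 1, 0)
    registry = _Registry()

    pop1 = _Pop(demog.ancestral_size, config.dfe.dominance)
    pop1._dfe = config.dfe
    pops = [pop1]

    split_at = (
        None
        if demog.split_generation is None
        else demog.burn_in + demog.split_generation
    )
    total = demog.n_generations

    for gen in range(total):
        if split_at is not None and gen == split_at:
            for _ in range(demog.n_populations - 1):
                daughter = pops[0].copy()
                daughter._dfe = config.dfe
                pops.append(daughter)
        t_next = gen + 1 - demog.burn_in
        for ipop, pop in enumerate(pops):
            if gen + 1 <= demog.burn_in or (split_at is not None and gen + 1 <= split_at):
                n_next = demog.ancestral_size
            else:
                n_next = demog.size_at(ipop, t_next)
            pop.step(
                n_next,
                rng,
                L,
                rho_per_gamete,
                mu_per_gamete,
                mutable_pos,
                mutable_class,
                reference,
                registry,
                gen + 1,
                config.max_segregating,
            )
        if (gen + 1) % _PRUNE_EVERY == 0 or gen + 1 == total:
            for pop in pops:
                pop.prune(gen + 1)

    results = []
    for ipop, pop in enumerate(pops):
        counts = pop.X.sum(axis=0) if pop.X.shape[1] else np.zeros(0, dtype=np.int64)
        freq = counts / max(pop.X.shape[0], 1)
        order = np.argsort(pop.pos, kind="stable")
        n_samp = min(config.sample_size_for(ipop), pop.n)
        chosen = rng.choice(pop.n, size=n_samp, replace=False)
        hap_rows = np.empty(2 * n_samp, dtype=np.int64)
        hap_rows[0::2] = 2 * chosen
        hap_rows[1::2] = 2 * chosen + 1
        sample = pop.X[hap_rows][:, order] if pop.X.shape[1] else pop.X[hap_rows]
        fixed_ids = np.asarray(pop.fixed_ids, dtype=np.int64)
        results.append(
            PopulationResult(
                name=f"pop{ipop + 1}",
                final_size=pop.n,
                seg_pos=pop.pos[order],
                seg_s=pop.s[order],
                seg_class=registry.take(pop.ids[order], "mclass").astype(np.int8),
                seg_derived=registry.take(pop.ids[order], "derived").astype(np.int8),
                seg_origin=registry.take(pop.ids[order], "origin"),
                seg_freq=freq[order],
                fixed_pos=registry.take(fixed_ids, "pos"),
                fixed_s=registry.take(fixed_ids, "s"),
                fixed_class=registry.take(fixed_ids, "mclass").astype(np.int8),
                fixed_derived=registry.take(fixed_ids, "derived").astype(np.int8),
                fixed_origin=registry.take(fixed_ids, "origin"),
                fixed_gen=np.asarray(pop.fixed_gen, dtype=np.int64),
                sample_haplotypes=sample,
            )
        )
    return SimOutput(
        config=config, reference=reference, populations=results, seed=config.seed
    )


# ---------------------------------------------------------------------------
# emission: outgroup, pooled reads
# ---------------------------------------------------------------------------


def mutate_outgroup(
    reference: np.ndarray | str,
    divergence: float,
    rng: np.random.Generator | int | None = None,
) -> OutgroupResult:
    """Jukes-Cantor-style outgroup: substitute each site with prob. ``divergence``.

    Every substituted site receives a uniformly random *different* base.
    The substituted positions are recorded so downstream polarisation can
    be validated against the truth.
    """
    if isinstance(reference, str):
        reference = str_to_sequence(reference)
    reference = np.asarray(reference, dtype=np.int8)
    if reference.size == 0:
        raise ValueError("empty reference")
    if not 0.0 <= divergence < 0.75:
        raise ValueError("divergence must lie in [0, 0.75)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = reference.copy()
    hit = np.nonzero(rng.random(reference.size) < divergence)[0]
    out[hit] = (reference[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return OutgroupResult(sequence=out, substituted_positions=hit)


def population_site_frequencies(
    pop: PopulationResult, reference: np.ndarray
) -> np.ndarray:
    """Dense (L, 4) base-frequency matrix of the population *sample*.

    Includes fixed differences from the reference (frequency 1 of the
    derived base) and segregating variants at their sample frequencies.
    At the rare positions hit by more than one mutation, younger mutations
    overwrite older ones on the haplotypes that carry both.
    """
    L = reference.size
    n_hap = pop.sample_haplotypes.shape[0]
    freqs = np.zeros((L, 4), dtype=np.float32)
    freqs[np.arange(L), reference] = 1.0

    # apply fixed differences (everyone carries the derived base)
    if pop.fixed_pos.size:
        order = np.argsort(pop.fixed_origin, kind="stable")
        fp = pop.fixed_pos[order]
        fd = pop.fixed_derived[order]
        freqs[fp] = 0.0
        freqs[fp, fd] = 1.0

    if pop.seg_pos.size == 0:
        return freqs

    seg_counts = pop.sample_haplotypes.sum(axis=0)
    upos, inv, cnt = np.unique(pop.seg_pos, return_inverse=True, return_counts=True)
    simple = cnt[inv] == 1
    # the common case: a single segregating mutation at the position
    sp = pop.seg_pos[simple]
    sd = pop.seg_derived[simple]
    sc = seg_counts[simple].astype(np.float32) / n_hap
    base_at = np.argmax(freqs[sp], axis=1).astype(np.int8)  # ref or fixed derived
    freqs[sp, base_at] -= sc
    freqs[sp, sd] += sc
    # multi-hit positions: resolve per haplotype in origin order
    for p in upos[cnt > 1]:
        idx = np.nonzero(pop.seg_pos == p)[0]
        idx = idx[np.argsort(pop.seg_origin[idx], kind="stable")]
        state = np.full(n_hap, int(np.argmax(freqs[p])), dtype=np.int8)
        for j in idx:
            state[pop.sample_haplotypes[:, j]] = pop.seg_derived[j]
        freqs[p] = 0.0
        for b in range(4):
            freqs[p, b] = np.mean(state == b)
    np.clip(freqs, 0.0, 1.0, out=freqs)
    return freqs


def sample_allele_counts(pop: PopulationResult, reference: np.ndarray) -> np.ndarray:
    """(L, 4) integer allele counts of the 2n sampled chromosomes."""
    n_hap = pop.sample_haplotypes.shape[0]
    freqs = population_site_frequencies(pop, reference)
    return np.rint(freqs * n_hap).astype(np.int32)


def pool_reads(
    frequencies: np.ndarray,
    depth: float,
    error_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate pooled sequencing of a population sample.

    Per site, total depth is Poisson(``depth``) and base reads are
    multinomial with the pool's base frequencies perturbed by a uniform
    sequencing-error model: a read is miscalled with probability
    ``error_rate``, to each of the three other bases with equal chance.
    Returns an (L, 4) int32 count matrix whose rows sum to the drawn depth.
    """
    freqs = np.asarray(frequencies, dtype=np.float64)
    if freqs.ndim != 2 or freqs.shape[1] != 4 or freqs.shape[0] == 0:
        raise ValueError("frequencies must be a non-empty (L, 4) array")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must lie in [0, 0.25)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = freqs * (1.0 - 4.0 * error_rate / 3.0) + error_rate / 3.0
    p /= p.sum(axis=1, keepdims=True)
    L = p.shape[0]
    total = rng.poisson(depth, size=L)
    counts = np.zeros((L, 4), dtype=np.int32)
    remaining = total.copy()
    tail = np.ones(L, dtype=np.float64)
    for b in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            pb = np.where(tail > 0, np.clip(p[:, b] / tail, 0.0, 1.0), 0.0)
        counts[:, b] = rng.binomial(remaining, pb)
        remaining -= counts[:, b]
        tail -= p[:, b]
    counts[:, 3] = remaining
    return counts
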