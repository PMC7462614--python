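"""Shared fixtures: the heavy forward-simulation runs are session-scoped so
the neutral-recovery, DoS and DFE comparisons all reuse the same replicates.
"""

from __future__ import annotations

import numpy as np
import pytest

from killipool import diversity, pipeline, simgen, sites

# Desk-scale study conditions for the paired small/large comparison:
# ancestral N = 500 for five ancestral sizes of burn-in, then a 10:1 split
# (N = 500 vs 50) evolved for 500 further generations; 150 coding blocks of
# 500 bp; per-bp mutation rate rescaled so 4*N*mu matches the canonical
# simulation, recombination at the canonical per-bp value.
PAIRED_N_LARGE = 500
PAIRED_N_SMALL = 50
PAIRED_REPLICATES = 25
PAIRED_MASTER_SEED = 1234


def _paired_replicate(seed: int) -> dict:
    layout = simgen.GenomeLayout(n_cds=150, cds_length=500, spacer_length=100)
    demog = simgen.build_demography(
        "B", PAIRED_N_LARGE, (PAIRED_N_LARGE, PAIRED_N_SMALL), 0, 500, burn_in=2500
    )
    config = simgen.SimConfig(
        layout=layout,
        dfe=simgen.DFEParams(),
        demography=demog,
        mutation_rate=1.0937856e-6,
        recombination_rate=6.604764e-6,
        seed=seed,
    )
    out = simgen.simulate_forward(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    outg = simgen.mutate_outgroup(out.reference, 0.02, rng)
    cds = pipeline._layout_cds_frame(layout)
    degmap = sites.classify_degeneracy(out.reference, cds)

    rep: dict = {}
    for label, pop in zip(("large", "small"), out.populations):
        dels = pop.seg_class == 1
        s = pop.seg_s[dels]
        scaled = np.abs(4.0 * pop.final_size * s)
        stats = pipeline.population_selection_stats(
            pop, out.reference, degmap, outg.sequence, depth=60.0, rng=rng
        )
        rep[label] = {
            "final_size": pop.final_size,
            "n_seg": int(pop.seg_pos.size),
            "n_seg_del": int(dels.sum()),
            "prop_band1": float(np.mean(scaled < 1)) if s.size else np.nan,
            "prop_band10": float(np.mean(scaled < 10)) if s.size else np.nan,
            "n_fixed_del": int((pop.fixed_class == 1).sum()),
            "dos_median": stats["dos_median"],
            "n_dos_genes": stats["n_genes"],
        }
    return rep


@pytest.fixture(scope="session")
def paired_sims() -> list[dict]:
    """25 paired small/large replicates of the desk-scale selection study."""
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in
             np.random.SeedSequence(PAIRED_MASTER_SEED).spawn(PAIRED_REPLICATES)]
    return [_paired_replicate(s) for s in seeds]


NEUTRAL_N = 1000
NEUTRAL_MU = 1e-7
NEUTRAL_SEED = 2024


@pytest.fixture(scope="session")
def neutral_sim() -> dict:
    """Neutral forward run (N = 1000, ~1 Mb, 10N generations) pooled deeply.

    Returns the window-level theta_W and pi of a 30-diploid sample pooled
    at 500x with no sequencing error, for comparison with 4*N*mu.
    """
    layout = simgen.GenomeLayout(
        n_cds=2008, cds_length=498, spacer_length=0,
        neutral_fraction=1.0, deleterious_fraction=0.0,
    )
    demog = simgen.DemographyPlan.single(NEUTRAL_N, 10 * NEUTRAL_N)
    config = simgen.SimConfig(
        layout=layout,
        dfe=simgen.DFEParams(),
        demography=demog,
        mutation_rate=NEUTRAL_MU,
        recombination_rate=5e-7,
        seed=NEUTRAL_SEED,
    )
    out = simgen.simulate_forward(config)
    pop = out.populations[0]
    rng = np.random.default_rng(np.random.SeedSequence([NEUTRAL_SEED, 99]))
    freqs = simgen.population_site_frequencies(pop, out.reference)
    counts = simgen.pool_reads(freqs, depth=500.0, error_rate=0.0, rng=rng)
    windows = diversity.window_stats(
        counts,
        haploid_pool_size=pop.sample_haplotypes.shape[0],
        window_size=50_000,
        min_count=2,
        min_depth=250,
        max_depth=1000,
    )
    return {"sim": out, "windows": windows, "expected": 4 * NEUTRAL_N * NEUTRAL_MU}
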