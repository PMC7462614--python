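"""Configuration-driven orchestration of the analysis stages.

``simulate_study`` generates a complete synthetic study (reference, CDS
annotation, outgroup pseudogenome, pooled sync counts, truth tables) from
a forward simulation of populations that diverged from a common ancestor;
``run`` executes the analysis stages (sites -> diversity -> fst ->
selection) on such inputs and writes per-stage tables plus a
machine-readable JSON summary of the headline numbers.  Identical config
and seed give a byte-identical summary.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import diversity, differentiation, io, selection, simgen, sites

__all__ = ["StudyConfig", "simulate_study", "RunConfig", "run", "PipelineError"]


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# synthetic study generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale synthetic three-population study.

    Defaults emulate the wild-population design — one strongly drifted
    population of small effective size plus two larger ones, diverged from
    a common ancestor — at a computationally convenient desk scale: the
    canonical simulation sizes are divided by 20 and the per-bp mutation
    rate multiplied by 20, preserving the population-scaled mutation
    parameter; the burn-in stays at five ancestral-population sizes.  The
    per-bp recombination rate is kept at its canonical value (about 0.6
    crossovers per gamete on the 90 kb genome) rather than rescaled, which
    only weakens linkage interference.  Pool sizes (116, 60, 60 haploid
    genomes) and mean coverages follow the pooled study design.
    """

    seed: int = 0
    ancestral_size: int = 500
    daughter_sizes: tuple = (100, 250, 500)
    pop_names: tuple = ("GNP", "NF414", "NF303")
    n_cds: int = 150
    cds_length: int = 500
    spacer_length: int = 100
    mutation_rate: float = 1.0937856e-6
    recombination_rate: float = 6.604764e-6
    dfe_mean: float = -2.5
    dfe_shape: float = 0.35
    dominance: float = 0.1
    deleterious_fraction: float = 2.0 / 3.0
    burn_in: int = 2500
    split_generation: int = 0
    total_generations: int = 500
    sample_sizes: tuple = (58, 30, 30)
    depths: tuple = (47.0, 39.0, 35.0)
    error_rate: float = 0.002
    outgroup_divergence: float = 0.02


@dataclass
class StudyData:
    """In-memory synthetic study: simulation output plus pipeline inputs."""

    config: StudyConfig
    sim: simgen.SimOutput
    reference: np.ndarray
    outgroup: simgen.OutgroupResult
    cds: pd.DataFrame
    sync: io.SyncCounts


def _layout_cds_frame(layout: simgen.GenomeLayout, chrom: str = "chr1") -> pd.DataFrame:
    iv = layout.cds_intervals()
    ncod = layout.codons_per_cds
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": iv[:, 0],
            "end": iv[:, 0] + 3 * ncod,  # complete codons only
            "strand": "+",
            "frame": 0,
            "gene_id": [f"gene{i:05d}" for i in range(len(iv))],
        }
    )


def simulate_study(config: StudyConfig, outdir: Optional[Path | str] = None) -> StudyData:
    """Simulate the populations and emit every pipeline input.

    When ``outdir`` is given, writes reference.fa, outgroup.fa, cds.gtf,
    counts.sync and truth_<pop>.tsv there.
    """
    layout = simgen.GenomeLayout(
        n_cds=config.n_cds,
        cds_length=config.cds_length,
        spacer_length=config.spacer_length,
        neutral_fraction=1.0 - config.deleterious_fraction,
        deleterious_fraction=config.deleterious_fraction,
    )
    dfe = simgen.DFEParams(
        gamma_mean=config.dfe_mean, gamma_shape=config.dfe_shape, dominance=config.dominance
    )
    demog = simgen.build_star_demography(
        config.ancestral_size,
        config.daughter_sizes,
        config.split_generation,
        config.total_generations,
        burn_in=config.burn_in,
    )
    sim_config = simgen.SimConfig(
        layout=layout,
        dfe=dfe,
        demography=demog,
        mutation_rate=config.mutation_rate,
        recombination_rate=config.recombination_rate,
        seed=config.seed,
        sample_size=config.sample_sizes,
    )
    sim = simgen.simulate_forward(sim_config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE317]))
    outg = simgen.mutate_outgroup(sim.reference, config.outgroup_divergence, rng)

    counts = []
    pool_sizes = []
    for pop, depth in zip(sim.populations, config.depths):
        freqs = simgen.population_site_frequencies(pop, sim.reference)
        counts.append(simgen.pool_reads(freqs, depth, config.error_rate, rng))
        pool_sizes.append(pop.sample_haplotypes.shape[0])
    sync = io.SyncCounts(
        chrom="chr1",
        positions=np.arange(sim.reference.size),
        ref=sim.reference,
        counts=np.stack(counts),
        pool_sizes=pool_sizes,
        pop_names=list(config.pop_names),
    )
    cds = _layout_cds_frame(layout)
    data = StudyData(
        config=config, sim=sim, reference=sim.reference, outgroup=outg, cds=cds, sync=sync
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(outdir / "reference.fa", {"chr1": sim.reference})
        io.write_fasta(outdir / "outgroup.fa", {"chr1": outg.sequence})
        io.write_gtf_cds(outdir / "cds.gtf", cds)
        io.write_sync(outdir / "counts.sync", sync)
        for name, pop in zip(config.pop_names, sim.populations):
            truth = pd.DataFrame(
                {
                    "pos": pop.seg_pos + 1,
                    "class": np.where(pop.seg_class == 1, "deleterious", "neutral"),
                    "s": pop.seg_s,
                    "derived": np.array(list("ACGT"))[pop.seg_derived],
                    "frequency": pop.seg_freq,
                }
            )
            with open(outdir / f"truth_{name}.tsv", "w") as fh:
                fh.write("##coordinates: 1-based\n")
                truth.to_csv(fh, sep="\t", index=False)
    return data


def population_selection_stats(
    pop: simgen.PopulationResult,
    reference: np.ndarray,
    degmap: "sites.DegeneracyMap",
    outgroup_seq: np.ndarray,
    depth: float = 60.0,
    error_rate: float = 0.002,
    rng: np.random.Generator | int | None = None,
    min_depth: float | None = None,
    max_depth: float | None = None,
    daf_bins: int = 9,
) -> dict:
    """Pool one simulated population and push it through the MK/DoS stage.

    Returns the per-gene MK tables, the DoS frame and its median — the
    quantities compared between small- and large-N_e populations.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    freqs = simgen.population_site_frequencies(pop, reference)
    counts = simgen.pool_reads(freqs, depth, error_rate, rng)
    lo = depth / 2.0 if min_depth is None else min_depth
    hi = depth * 2.0 if max_depth is None else max_depth
    table = sites.polarize_table(counts, outgroup_seq, degmap, min_depth=lo, max_depth=hi)
    bins = np.linspace(0.05, 0.95, daf_bins + 1)
    tables = selection.mk_counts(table, bins=bins, gene_names=degmap.genes)
    dtab = selection.dos_table(tables)
    defined = dtab["dos"].dropna()
    med = float(defined.median()) if len(defined) else float("nan")
    return {
        "mk_tables": tables,
        "dos": dtab,
        "dos_median": med,
        "n_genes": int(dtab["dos"].notna().sum()),
        "polarized": table,
    }


# ---------------------------------------------------------------------------
# analysis run
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and parameters of one analysis run."""

    reference: str
    gtf: str
    sync: str
    outgroup: str
    outdir: str
    pool_sizes: tuple = (116, 60, 60)
    pop_names: tuple = ("GNP", "NF414", "NF303")
    min_depths: tuple = (24, 19, 18)
    max_depths: tuple = (94, 77, 70)
    window_size: int = 50_000
    fst_min_count: int = 4
    fst_min_depth: float = 20.0
    diversity_min_count: int = 2
    min_covered_fraction: float = 0.3
    mu: float = 2.6321e-9
    daf_bins: int = 9
    sfs_projection: int = 10
    posterior_threshold: float = 0.9
    seg_error_rate: float = 0.01
    seed: int = 0
    stages: tuple = ("sites", "diversity", "fst", "selection")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("pool_sizes", "pop_names", "min_depths", "max_depths", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    # analysis parameters only: paths (incl. outdir) do not change results
    payload = {
        k: v
        for k, v in asdict(config).items()
        if k not in {"reference", "gtf", "sync", "outgroup", "outdir"}
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run(config: RunConfig) -> dict:
    """Execute the requested stages and write outputs plus summary.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    if "diversity" not in stages and "selection" in stages:
        pass  # selection does not need diversity
    for needy in ("diversity", "fst", "selection"):
        if needy in stages and "sites" not in stages and needy == "selection":
            raise PipelineError("stage 'selection' requires stage 'sites'")

    for path in (config.reference, config.gtf, config.sync, config.outgroup):
        if not Path(path).exists():
            raise PipelineError(f"missing input file: {path}")

    reference = io.read_fasta(config.reference)
    outgroup = io.read_fasta(config.outgroup)
    cds = io.read_gtf_cds(config.gtf)
    sync = io.read_sync(config.sync, config.pool_sizes, config.pop_names)
    chrom = sync.chrom
    ref = reference[chrom]
    out_seq = outgroup[chrom]

    summary: dict = {"config_hash": _config_hash(config), "seed": config.seed, "populations": {}}
    for name in sync.pop_names:
        summary["populations"][name] = {}

    polarized: dict[str, pd.DataFrame] = {}
    if "sites" in stages:
        degmap = sites.classify_degeneracy(ref, cds, chrom=chrom)
        for p, name in enumerate(sync.pop_names):
            table = sites.polarize_table(
                sync.counts[p],
                out_seq,
                degmap,
                min_depth=config.min_depths[p],
                max_depth=config.max_depths[p],
                positions=sync.positions,
                chrom=chrom,
            )
            table = sites.segregation_filter(
                table, config.posterior_threshold, config.seg_error_rate
            )
            polarized[name] = table
            with open(outdir / f"polarized_{name}.tsv", "w") as fh:
                fh.write("##coordinates: pos is 1-based\n")
                t = table.copy()
                t["pos"] = t["pos"] + 1
                t.to_csv(fh, sep="\t", index=False)

    if "diversity" in stages:
        rows = []
        for p, name in enumerate(sync.pop_names):
            win = diversity.window_stats(
                sync.counts[p],
                haploid_pool_size=sync.pool_sizes[p],
                positions=sync.positions,
                window_size=config.window_size,
                min_count=config.diversity_min_count,
                min_covered_fraction=config.min_covered_fraction,
                min_depth=config.min_depths[p],
                max_depth=config.max_depths[p],
                chrom=chrom,
            )
            win.insert(0, "population", name)
            rows.append(win)
            if len(win):
                w = win["covered_fraction"].to_numpy() * config.window_size
                theta = float(np.average(win["theta_w"], weights=w))
                pi = float(np.average(win["pi"], weights=w))
            else:
                theta = pi = float("nan")
            ne = diversity.estimate_ne(theta, config.mu).ne if np.isfinite(theta) else float("nan")
            summary["populations"][name].update(
                {"theta_w": theta, "pi": pi, "ne": ne, "n_windows": int(len(win))}
            )
        allwin = pd.concat(rows, ignore_index=True)
        with open(outdir / "diversity_windows.tsv", "w") as fh:
            fh.write("##coordinates: start/end are 0-based half-open\n")
            allwin.to_csv(fh, sep="\t", index=False)

    if "fst" in stages:
        pair_means = {}
        frames = []
        for a, b in combinations(range(sync.n_pops), 2):
            pair = f"{sync.pop_names[a]}:{sync.pop_names[b]}"
            win = differentiation.fst_windows(
                sync.counts[a],
                sync.counts[b],
                positions=sync.positions,
                window_size=config.window_size,
                min_count=config.fst_min_count,
                min_depth=config.fst_min_depth,
                max_depth1=config.max_depths[a],
                max_depth2=config.max_depths[b],
                pair=pair,
                chrom=chrom,
            )
            frames.append(win)
            pair_means[pair] = float(win["fst"].mean()) if len(win) else float("nan")
            if len(win) >= 200:
                outl = differentiation.zfst_outliers(win, pair=pair)
                bed = pd.concat([outl.high.assign(tail="high"), outl.low.assign(tail="low")])
                with open(outdir / f"fst_outliers_{pair.replace(':', '_')}.bed", "w") as fh:
                    fh.write("##coordinates: BED, 0-based half-open\n")
                    bed[["chrom", "start", "end", "tail", "z_fst"]].to_csv(
                        fh, sep="\t", index=False, header=False
                    )
        allfst = pd.concat(frames, ignore_index=True)
        with open(outdir / "fst_windows.tsv", "w") as fh:
            fh.write("##coordinates: start/end are 0-based half-open\n")
            allfst.to_csv(fh, sep="\t", index=False)
        summary["fst"] = pair_means
        # NJ tree from the genome-wide pairwise means
        if sync.n_pops >= 3 and all(np.isfinite(v) for v in pair_means.values()):
            d = np.zeros((sync.n_pops, sync.n_pops))
            for a, b in combinations(range(sync.n_pops), 2):
                key = f"{sync.pop_names[a]}:{sync.pop_names[b]}"
                d[a, b] = d[b, a] = pair_means[key]
            newick = differentiation.nj_tree(d, list(sync.pop_names))
            (outdir / "fst_nj.nwk").write_text(newick + "\n")
            summary["nj_tree"] = newick

    if "selection" in stages:
        if not polarized:
            raise PipelineError("stage 'selection' requires stage 'sites'")
        bins = np.linspace(0.05, 0.95, config.daf_bins + 1)
        degmap = sites.classify_degeneracy(ref, cds, chrom=chrom)
        for p, name in enumerate(sync.pop_names):
            table = polarized[name]
            tables = selection.mk_counts(table, bins=bins, gene_names=degmap.genes)
            dtab = selection.dos_table(tables)
            dtab.to_csv(outdir / f"mk_dos_{name}.tsv", sep="\t", index=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sets = selection.dos_gene_sets(dtab)
            pop_summary = summary["populations"][name]
            pop_summary["dos_median"] = sets["median"]
            pop_summary["dos_n_genes"] = sets["n_genes"]
            agg = selection.aggregate_mk(tables)
            pop_summary["mk"] = {"dn": agg.dn, "ds": agg.ds, "pn": agg.pn, "ps": agg.ps}
            try:
                x, a = selection.alpha_x(agg)
                fit = selection.fit_asymptotic_alpha(x, a)
                pop_summary["alpha_asymptotic"] = fit.alpha_asymptotic
                pop_summary["alpha_pooled"] = selection.pooled_alpha(agg)
                curve = pd.DataFrame({"x": x, "alpha": a})
                curve.to_csv(outdir / f"alpha_curve_{name}.tsv", sep="\t", index=False)
            except ValueError:
                pop_summary["alpha_asymptotic"] = float("nan")
                pop_summary["alpha_pooled"] = float("nan")
            # SFS and DFE
            n_native = sync.pool_sizes[p]
            sfs_s = selection.build_sfs(table, sites.FOUR_FOLD, n_native)
            sfs_n = selection.build_sfs(table, sites.ZERO_FOLD, n_native)
            proj_s = selection.project_sfs(sfs_s, config.sfs_projection)
            proj_n = selection.project_sfs(sfs_n, config.sfs_projection)
            sfs_frame = pd.DataFrame(
                {
                    "i": np.arange(1, config.sfs_projection),
                    "synonymous": proj_s.counts[1 : config.sfs_projection],
                    "non_synonymous": proj_n.counts[1 : config.sfs_projection],
                }
            )
            sfs_frame.to_csv(outdir / f"sfs_{name}.tsv", sep="\t", index=False)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits = [
                        selection.fit_gamma_dfe(proj_s, proj_n, model=m)
                        for m in ("gamma", "gamma_neutral")
                    ]
                best = selection.compare_models_aic(fits)
                pop_summary["dfe"] = {
                    "model": best.model,
                    "gamma_shape": best.gamma_shape,
                    "gamma_mean_scaled": best.gamma_mean,
                    "p_neutral": best.p_neutral,
                    "aic": best.aic,
                }
            except ValueError:
                pop_summary["dfe"] = None

    summary = _sanitize(summary)
    payload = json.dumps(summary, sort_keys=True, indent=2, allow_nan=False)
    (outdir / "summary.json").write_text(payload + "\n")
    return summary


def _sanitize(obj):
    """Replace non-finite floats with None for strict JSON output."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
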