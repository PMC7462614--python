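"""Forward simulator: demography plans, the DFE sampler, pooling, outgroup
generation, and Wright-Fisher invariants."""

import numpy as np
import pytest
from scipy import stats

from killipool import simgen


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------


class TestBuildDemography:
    def test_model_a_instant_change_at_split(self):
        plan = simgen.build_demography("A", 10_000, (10_000, 1000), 25_000, 50_000)
        assert plan.size_at(1, 24_999) == 10_000
        assert plan.size_at(1, 25_000) == 1000
        assert plan.size_at(1, 50_000) == 1000
        assert plan.size_at(0, 50_000) == 10_000

    def test_model_b_symmetric_null(self):
        plan = simgen.build_demography("B", 10_000, (10_000, 10_000), 0, 50_000)
        for t in (0, 1, 25_000, 50_000):
            assert plan.size_at(0, t) == 10_000
            assert plan.size_at(1, t) == 10_000

    def test_model_c_exponential_growth_closed_form(self):
        plan = simgen.build_demography("C", 10_000, (10_000, 100_000), 0, 46_050)
        rate = np.log(10.0) / 46_050
        mid = 23_000
        assert plan.size_at(1, mid) == pytest.approx(10_000 * np.exp(rate * mid), abs=1)
        assert abs(plan.size_at(1, 46_050) - 100_000) <= 1
        # daughter 1 stays at the ancestral size (zero growth rate)
        assert plan.size_at(0, 46_050) == 10_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model_id="E", ancestral_size=100, daughter_sizes=(100, 100), split_generation=0, total_generations=10),
            dict(model_id="A", ancestral_size=100, daughter_sizes=(1, 100), split_generation=0, total_generations=10),
            dict(model_id="B", ancestral_size=100, daughter_sizes=(100, 100), split_generation=5, total_generations=10),
            dict(model_id="D", ancestral_size=100, daughter_sizes=(100, 100), split_generation=3, total_generations=10),
            dict(model_id="A", ancestral_size=100, daughter_sizes=(100, 100), split_generation=20, total_generations=10),
        ],
    )
    def test_invalid_plans_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simgen.build_demography(**kwargs)

    def test_trajectories_deterministic(self):
        a = simgen.build_demography("C", 1000, (500, 5000), 100, 1000)
        b = simgen.build_demography("C", 1000, (500, 5000), 100, 1000)
        np.testing.assert_array_equal(a.traj1, b.traj1)
        np.testing.assert_array_equal(a.traj2, b.traj2)


# ---------------------------------------------------------------------------
# reflected gamma DFE
# ---------------------------------------------------------------------------


class TestSelectionCoefficients:
    def test_moments_and_support(self):
        dfe = simgen.DFEParams(gamma_mean=-2.5, gamma_shape=0.35)
        rng = np.random.default_rng(11)
        s = simgen.draw_selection_coefficient(rng, dfe, size=1_000_000)
        assert np.all(s < 0)
        assert -2.52 < s.mean() < -2.48
        expected_var = 2.5**2 / 0.35
        assert abs(s.var() - expected_var) / expected_var < 0.05

    @pytest.mark.parametrize(
        "mean,shape,h", [(0.5, 0.35, 0.1), (-2.5, -1.0, 0.1), (-2.5, 0.35, 1.5)]
    )
    def test_invalid_parameters(self, mean, shape, h):
        with pytest.raises(ValueError):
            simgen.DFEParams(gamma_mean=mean, gamma_shape=shape, dominance=h)


# ---------------------------------------------------------------------------
# pooled read sampling
# ---------------------------------------------------------------------------


class TestPoolReads:
    def test_balanced_site_deep_coverage(self):
        freqs = np.array([[0.5, 0.0, 0.0, 0.5]])
        counts = simgen.pool_reads(freqs, depth=1e6, error_rate=0.0, rng=5)
        f = counts[0, 0] / counts[0].sum()
        assert 0.498 <= f <= 0.502

    def test_monomorphic_without_error(self):
        freqs = np.tile([1.0, 0.0, 0.0, 0.0], (100, 1))
        counts = simgen.pool_reads(freqs, depth=50, error_rate=0.0, rng=0)
        assert counts[:, 1:].sum() == 0
        # row sums equal the drawn Poisson depth (they reproduce with the seed)
        rng = np.random.default_rng(0)
        assert np.array_equal(counts.sum(axis=1), rng.poisson(50, size=100))

    def test_error_rate_recovered(self):
        freqs = np.tile([1.0, 0.0, 0.0, 0.0], (1000, 1))
        counts = simgen.pool_reads(freqs, depth=100, error_rate=0.01, rng=3)
        total = counts.sum()
        frac = counts[:, 1:].sum() / total
        se = np.sqrt(0.01 * 0.99 / total)
        assert abs(frac - 0.01) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simgen.pool_reads(np.empty((0, 4)), depth=10)
        with pytest.raises(ValueError):
            simgen.pool_reads(np.array([[1.0, 0, 0, 0]]), depth=0)
        with pytest.raises(ValueError):
            simgen.pool_reads(np.array([[1.0, 0, 0, 0]]), depth=10, error_rate=0.3)


# ---------------------------------------------------------------------------
# outgroup generation
# ---------------------------------------------------------------------------


class TestMutateOutgroup:
    def test_zero_divergence_identity(self):
        ref = np.random.default_rng(0).integers(0, 4, 1000).astype(np.int8)
        out = simgen.mutate_outgroup(ref, 0.0, rng=1)
        np.testing.assert_array_equal(out.sequence, ref)
        assert out.substituted_positions.size == 0

    def test_divergence_fraction_and_truth(self):
        rng = np.random.default_rng(2)
        ref = rng.integers(0, 4, 1_000_000).astype(np.int8)
        out = simgen.mutate_outgroup(ref, 0.02, rng=rng)
        frac = out.substituted_positions.size / ref.size
        se = np.sqrt(0.02 * 0.98 / ref.size)
        assert abs(frac - 0.02) < 3 * se
        # every recorded substitution differs from the reference, and only those
        diff = np.nonzero(out.sequence != ref)[0]
        np.testing.assert_array_equal(np.sort(out.substituted_positions), diff)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simgen.mutate_outgroup(np.empty(0, dtype=np.int8), 0.1)
        with pytest.raises(ValueError):
            simgen.mutate_outgroup(np.zeros(10, dtype=np.int8), 0.8)


# ---------------------------------------------------------------------------
# forward simulation invariants
# ---------------------------------------------------------------------------


def _small_config(seed=0, **overrides):
    layout = simgen.GenomeLayout(n_cds=40, cds_length=498, spacer_length=50)
    demog = simgen.build_demography("B", 100, (100, 100), 0, 200, burn_in=300)
    defaults = dict(
        layout=layout,
        dfe=simgen.DFEParams(),
        demography=demog,
        mutation_rate=1e-6,
        recombination_rate=1e-6,
        seed=seed,
    )
    defaults.update(overrides)
    return simgen.SimConfig(**defaults)


class TestSimulateForward:
    def test_segregating_and_fixed_disjoint(self):
        out = simgen.simulate_forward(_small_config(seed=42))
        for pop in out.populations:
            seg = set(zip(pop.seg_pos.tolist(), pop.seg_origin.tolist()))
            fix = set(zip(pop.fixed_pos.tolist(), pop.fixed_origin.tolist()))
            assert not seg & fix
            assert np.all((pop.seg_freq > 0) & (pop.seg_freq < 1))

    def test_same_seed_bit_identical(self):
        a = simgen.simulate_forward(_small_config(seed=7))
        b = simgen.simulate_forward(_small_config(seed=7))
        np.testing.assert_array_equal(a.reference, b.reference)
        for pa, pb in zip(a.populations, b.populations):
            np.testing.assert_array_equal(pa.seg_pos, pb.seg_pos)
            np.testing.assert_array_equal(pa.seg_freq, pb.seg_freq)
            np.testing.assert_array_equal(pa.fixed_pos, pb.fixed_pos)
            np.testing.assert_array_equal(pa.sample_haplotypes, pb.sample_haplotypes)

    def test_neutralised_selected_class_matches_neutral_class(self):
        # with s ~ 0 and h = 0.5 the selected-class positions must behave
        # like the neutral-class ones: compare frequency spectra by KS test
        config = _small_config(
            seed=3,
            dfe=simgen.DFEParams(gamma_mean=-1e-12, gamma_shape=0.35, dominance=0.5),
            demography=simgen.DemographyPlan.single(200, 2000, burn_in=0),
            mutation_rate=2e-6,
        )
        out = simgen.simulate_forward(config)
        pop = out.populations[0]
        f_neu = pop.seg_freq[pop.seg_class == 0]
        f_del = pop.seg_freq[pop.seg_class == 1]
        assert f_neu.size > 30 and f_del.size > 30
        assert stats.ks_2samp(f_neu, f_del).pvalue > 0.01

    def test_neutral_fixation_flux_matches_mutation_rate(self):
        # neutral substitutions accrue at mu * L per generation regardless
        # of N (fixation probability 1/(2N) cancels the 2N*mu*L influx)
        layout = simgen.GenomeLayout(
            n_cds=20, cds_length=498, spacer_length=0,
            neutral_fraction=1.0, deleterious_fraction=0.0,
        )
        gens = 3000
        config = simgen.SimConfig(
            layout=layout,
            dfe=simgen.DFEParams(),
            demography=simgen.DemographyPlan.single(50, gens),
            mutation_rate=2e-6,
            recombination_rate=0.0,
            seed=9,
        )
        out = simgen.simulate_forward(config)
        n_fixed = out.populations[0].fixed_pos.size
        expected = 2e-6 * layout.genome_length * gens  # ~ 60
        # generous bound: fixation counts are overdispersed relative to Poisson
        assert 0.4 * expected < n_fixed < 1.9 * expected

    def test_memory_guard(self):
        with pytest.raises(simgen.SimulationError):
            simgen.simulate_forward(_small_config(max_segregating=10))


class TestRelaxedSelectionDirection:
    def test_small_population_holds_more_nearly_neutral_variants(self, paired_sims):
        """Smaller N_e leaves a larger share of segregating selected variants
        in the nearly-neutral |4 N s| band (one-sided Wilcoxon over pairs)."""
        small = np.array([r["small"]["prop_band10"] for r in paired_sims])
        large = np.array([r["large"]["prop_band10"] for r in paired_sims])
        ok = np.isfinite(small) & np.isfinite(large)
        res = stats.wilcoxon(small[ok], large[ok], alternative="greater")
        assert res.pvalue < 0.05

    def test_small_population_fixes_more_deleterious_mutations(self, paired_sims):
        small = np.array([r["small"]["n_fixed_del"] for r in paired_sims])
        large = np.array([r["large"]["n_fixed_del"] for r in paired_sims])
        assert np.median(small - large) > 0
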