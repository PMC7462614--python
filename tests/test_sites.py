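"""Degeneracy classification, major-allele calls, polarization and the
segregation posterior filter."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from killipool import simgen, sites
from killipool.sites import FOUR_FOLD, NONCODING, OTHER_FOLD, ZERO_FOLD


def _cds_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "frame", "gene_id"])


def _brute_force_degeneracy(codon: str, pos: int) -> int:
    """Oracle: translate the codon and all three substitutions at pos."""
    aa = str(Seq(codon).translate())
    if aa == "*":
        return NONCODING
    syn = sum(
        str(Seq(codon[:pos] + alt + codon[pos + 1 :]).translate()) == aa
        for alt in "ACGT"
        if alt != codon[pos]
    )
    return {3: FOUR_FOLD, 0: ZERO_FOLD}.get(syn, OTHER_FOLD)


class TestClassifyDegeneracy:
    @pytest.mark.parametrize(
        "codon,pos,expected",
        [
            ("GGA", 2, FOUR_FOLD),   # glycine GGN
            ("ATG", 0, ZERO_FOLD),   # unique methionine codon
            ("ATG", 1, ZERO_FOLD),
            ("ATG", 2, ZERO_FOLD),
            ("AAA", 2, OTHER_FOLD),  # AAG Lys but AAT/AAC Asn (2-fold)
        ],
    )
    def test_known_codons(self, codon, pos, expected):
        ref = simgen.str_to_sequence(codon)
        cds = _cds_frame([("chr1", 0, 3, "+", 0, "g1")])
        deg = sites.classify_degeneracy(ref, cds)
        assert deg.classes[pos] == expected
        assert _brute_force_degeneracy(codon, pos) == expected

    def test_random_cds_agrees_with_brute_force(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        ref = simgen.str_to_sequence(seq)
        cds = _cds_frame([("chr1", 0, 300, "+", 0, "g1")])
        deg = sites.classify_degeneracy(ref, cds)
        for c in range(100):
            codon = seq[3 * c : 3 * c + 3]
            for p in range(3):
                assert deg.classes[3 * c + p] == _brute_force_degeneracy(codon, p), (codon, p)

    def test_reverse_strand_by_complementation(self):
        # minus-strand gene: genomic revcomp must be read as the codons
        plus = "ATGGCTGGA"  # Met Ala Gly
        genomic = str(Seq(plus).reverse_complement())
        ref = simgen.str_to_sequence(genomic)
        cds = _cds_frame([("chr1", 0, 9, "-", 0, "g1")])
        deg = sites.classify_degeneracy(ref, cds)
        # genomic position 0 is the last base of codon GGA -> four-fold
        assert deg.classes[0] == FOUR_FOLD
        # genomic positions 6..8 are codon ATG reversed -> all zero-fold
        assert np.all(deg.classes[6:9] == ZERO_FOLD)

    def test_strand_symmetry_of_class_counts(self):
        rng = np.random.default_rng(5)
        layout = simgen.GenomeLayout(n_cds=5, cds_length=60, spacer_length=10)
        ref = simgen.make_reference(layout, rng)
        cds = _cds_frame(
            [("chr1", int(s), int(s) + 60, "+", 0, f"g{i}")
             for i, (s, _) in enumerate(layout.cds_intervals())]
        )
        fwd = sites.classify_degeneracy(ref, cds)
        L = ref.size
        ref_rc = np.array([3, 2, 1, 0], dtype=np.int8)[ref][::-1].copy()
        cds_rc = _cds_frame(
            [("chr1", L - int(r.end), L - int(r.start), "-", 0, r.gene_id)
             for r in cds.itertuples()]
        )
        rev = sites.classify_degeneracy(ref_rc, cds_rc)
        assert fwd.class_counts() == rev.class_counts()

    def test_internal_stop_codon_excluded_with_warning(self):
        ref = simgen.str_to_sequence("TAAGGA")
        cds = _cds_frame([("chr1", 0, 6, "+", 0, "g1")])
        with pytest.warns(UserWarning, match="stop codon"):
            deg = sites.classify_degeneracy(ref, cds)
        assert np.all(deg.classes[:3] == NONCODING)
        assert deg.classes[5] == FOUR_FOLD

    def test_ambiguous_base_excludes_codon(self):
        ref = simgen.str_to_sequence("GGANGA")
        cds = _cds_frame([("chr1", 0, 6, "+", 0, "g1")])
        deg = sites.classify_degeneracy(ref, cds)
        assert deg.classes[2] == FOUR_FOLD
        assert np.all(deg.classes[3:6] == NONCODING)


class TestCallMajorAllele:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([10, 0, 2, 0], 0),    # majority rule -> A
            ([0, 0, 0, 0], -1),    # uncovered -> N
            ([4, 4, 0, 0], -1),    # tie -> N (conservative masking)
            ([3, 2, 1, 0], -1),    # >2 alleles -> N
            ([0, 0, 7, 0], 2),
        ],
    )
    def test_rules(self, counts, expected):
        assert sites.call_major_allele(np.array(counts)) == expected


class TestPolarize:
    def test_biallelic_polymorphic(self):
        s = sites.polarize(np.array([18, 0, 2, 0]), outgroup_base=0, min_depth=10, max_depth=100)
        assert (s.derived_base, s.status) == (2, "polymorphic")
        assert s.daf == pytest.approx(0.10)

    def test_single_read_minor_is_monomorphic(self):
        s = sites.polarize(np.array([39, 0, 1, 0]), outgroup_base=0, min_depth=10, max_depth=100)
        assert s.status == "monomorphic"

    def test_high_daf_is_fixed(self):
        s = sites.polarize(np.array([1, 0, 39, 0]), outgroup_base=0, min_depth=24, max_depth=94)
        assert s.status == "fixed"

    def test_daf_just_above_threshold_fixed(self):
        s = sites.polarize(np.array([2, 0, 98, 0]), outgroup_base=0, min_depth=10, max_depth=200)
        assert s.daf == pytest.approx(0.98)
        assert s.status == "fixed"

    def test_outgroup_n_excluded(self):
        s = sites.polarize(np.array([18, 0, 2, 0]), outgroup_base=-1, min_depth=10, max_depth=100)
        assert s.status == "excluded"

    def test_coverage_bounds_excluded(self):
        s = sites.polarize(np.array([5, 0, 3, 0]), outgroup_base=0, min_depth=10, max_depth=100)
        assert s.status == "excluded"

    def test_triallelic_excluded(self):
        s = sites.polarize(np.array([10, 8, 6, 0]), outgroup_base=0, min_depth=10, max_depth=100)
        assert s.status == "excluded"

    def test_outgroup_matches_neither_allele_excluded(self):
        s = sites.polarize(np.array([10, 10, 0, 0]), outgroup_base=2, min_depth=10, max_depth=100)
        assert s.status == "excluded"

    def test_monomorphic_but_different_is_fixed_difference(self):
        s = sites.polarize(np.array([0, 40, 0, 0]), outgroup_base=0, min_depth=10, max_depth=100)
        assert (s.status, s.derived_base, s.daf) == ("fixed", 1, 1.0)

    def test_daf_complementarity(self):
        # daf(derived) + freq(ancestral) = 1 for biallelic sites
        s = sites.polarize(np.array([30, 0, 10, 0]), outgroup_base=0, min_depth=10, max_depth=100)
        anc = 30 / 40
        assert s.daf + anc == pytest.approx(1.0)


class TestPolarizeTableConsistency:
    def test_table_matches_scalar_rules(self):
        rng = np.random.default_rng(23)
        L = 600
        ref = rng.integers(0, 4, L).astype(np.int8)
        # random codon-structured degeneracy map over one gene
        cds = _cds_frame([("chr1", 0, L, "+", 0, "g1")])
        deg = sites.classify_degeneracy(ref, cds)
        counts = rng.integers(0, 30, size=(L, 4)).astype(np.int64)
        outg = ref.copy()
        flip = rng.random(L) < 0.1
        outg[flip] = (outg[flip] + 1) % 4
        outg[rng.random(L) < 0.05] = -1
        table = sites.polarize_table(counts, outg, deg, min_depth=20, max_depth=90)
        for row in table.sample(n=min(150, len(table)), random_state=1).itertuples():
            ps = sites.polarize(
                counts[row.pos], int(outg[row.pos]), 20, 90, degeneracy=row.degeneracy
            )
            assert ps.status == row.status, row.pos
            if ps.status in ("polymorphic", "fixed"):
                assert ps.derived_base == row.derived
                assert ps.daf == pytest.approx(row.daf, nan_ok=True)

    def test_polarization_recovers_simulated_truth(self):
        """With a non-diverged outgroup (the true ancestral sequence), deep
        error-free pooling recovers the true derived allele at >= 99% of
        single-mutation polymorphic sites."""
        layout = simgen.GenomeLayout(n_cds=120, cds_length=498, spacer_length=30)
        config = simgen.SimConfig(
            layout=layout,
            dfe=simgen.DFEParams(),
            demography=simgen.DemographyPlan.single(150, 1500),
            mutation_rate=4e-6,
            recombination_rate=1e-6,
            seed=8,
        )
        out = simgen.simulate_forward(config)
        pop = out.populations[0]
        freqs = simgen.population_site_frequencies(pop, out.reference)
        counts = simgen.pool_reads(freqs, depth=400, error_rate=0.0, rng=12)
        cds = _cds_frame(
            [("chr1", int(s), int(s) + 498, "+", 0, f"g{i}")
             for i, (s, _) in enumerate(layout.cds_intervals())]
        )
        deg = sites.classify_degeneracy(out.reference, cds)
        table = sites.polarize_table(
            counts, out.reference, deg, min_depth=200, max_depth=800
        )
        poly = table[table["status"] == "polymorphic"].set_index("pos")
        # truth: single-hit segregating mutations with sample DAF in the
        # polymorphic band
        pos_unique, cnt = np.unique(pop.seg_pos, return_counts=True)
        single = set(pos_unique[cnt == 1])
        sample_freq = pop.sample_derived_counts() / pop.sample_haplotypes.shape[0]
        hits = total = 0
        for j, p in enumerate(pop.seg_pos):
            if p not in single or not (0.1 <= sample_freq[j] <= 0.9):
                continue
            if p not in poly.index:
                continue
            total += 1
            hits += int(poly.loc[p, "derived"] == pop.seg_derived[j])
        assert total > 50
        assert hits / total >= 0.99


class TestSegregationFilter:
    def test_confident_polymorphism_kept(self):
        assert sites.segregation_posterior(10, 40) > 0.9

    def test_zero_minor_count_dropped(self):
        assert sites.segregation_posterior(0, 40) < 0.9

    def test_filter_demotes_only_polymorphic(self):
        table = pd.DataFrame(
            {
                "status": ["polymorphic", "monomorphic", "fixed", "polymorphic"],
                "derived_count": [10, 0, 39, 1],
                "total_count": [40, 40, 40, 40],
            }
        )
        out = sites.segregation_filter(table, 0.9)
        assert list(out["status"]) == ["polymorphic", "monomorphic", "fixed", "excluded"]

    @pytest.mark.parametrize("threshold", [0.0, 1.0, 1.5, -0.1])
    def test_threshold_bounds(self, threshold):
        table = pd.DataFrame({"status": [], "derived_count": [], "total_count": []})
        with pytest.raises(ValueError):
            sites.segregation_filter(table, threshold)
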