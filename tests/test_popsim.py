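"""Meiosis, crossing and phenotype simulation against genetic theory."""

import numpy as np
import pandas as pd
import pytest

from heatmaize.datatypes import CONDITIONS, SimTruth, TraitTruth
from heatmaize.genoqc import GPCutoffPolicy, gp_cutoff_filter
from heatmaize.popsim import (
    add_genotype_probabilities,
    genetic_values,
    lattice_design,
    simulate_cross,
    simulate_genome,
    simulate_phenotypes,
    simulate_study,
)


def haldane(d_cm):
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


class TestSimulateGenome:
    def test_construction_contract(self):
        gmap, haps = simulate_genome(1, [100.0], 10, 2, seed=1)
        assert gmap.n_markers == 10
        pos = gmap.table["pos_cM"].to_numpy()
        assert ((pos >= 0) & (pos <= 100)).all()
        assert (np.diff(pos) >= 0).all()
        assert haps.shape == (2, 10)
        # every marker polymorphic among the parents
        assert (haps.min(axis=0) != haps.max(axis=0)).all()

    def test_genome_at_sparse_assay_scale(self):
        lengths = np.full(10, 1823.5 / 10)
        gmap, haps = simulate_genome(10, lengths, 170, 8, seed=2)
        assert gmap.n_markers == 170
        assert len(gmap.chromosomes) == 10
        assert gmap.length_cm() <= 1823.5
        assert haps.shape == (8, 170)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_genome(1, [-5.0], 10, 2, seed=1)
        with pytest.raises(ValueError):
            simulate_genome(3, [10.0, 10.0, 10.0], 2, 2, seed=1)


class TestSimulateCross:
    def test_f1_is_fully_heterozygous(self):
        gmap, haps = simulate_genome(2, [80.0, 60.0], 40, 2, seed=5)
        f1 = simulate_cross(gmap, haps[0], haps[1], 20, 0, seed=6)
        poly = haps[0] != haps[1]
        assert (f1.genotypes[poly] == 1).all()

    def test_two_selfing_generations_give_quarter_heterozygosity(self):
        gmap, haps = simulate_genome(5, [150.0] * 5, 300, 2, seed=7)
        f3 = simulate_cross(gmap, haps[0], haps[1], 400, 2, seed=8)
        poly = haps[0] != haps[1]
        het = (f3.genotypes[poly] == 1).mean()
        assert het == pytest.approx(0.25, abs=0.02)

    def test_fully_linked_markers_stay_parental(self):
        gmap, _ = simulate_genome(1, [0.0001], 2, 2, seed=9)
        hap_a = np.array([0, 0], dtype=np.int8)
        hap_b = np.array([1, 1], dtype=np.int8)
        f2 = simulate_cross(gmap, hap_a, hap_b, 500, 1, seed=10)
        # gametes carry whole parental haplotypes: codes agree at both loci
        assert (f2.genotypes[0] == f2.genotypes[1]).all()

    def test_recombinant_fraction_matches_haldane(self):
        # two markers 100 cM apart; F2 double homozygotes reveal gametes
        table = pd.DataFrame(
            {"chrom": ["c1", "c1"], "marker": ["m1", "m2"], "pos_cM": [0.0, 100.0]}
        )
        from heatmaize.datatypes import GeneticMap

        gmap = GeneticMap(table)
        hap_a = np.array([0, 0], dtype=np.int8)
        hap_b = np.array([1, 1], dtype=np.int8)
        n = 10_000
        f2 = simulate_cross(gmap, hap_a, hap_b, n, 1, seed=11)
        g = f2.genotypes
        # each F2 is two independent gametes: E[#recombinant gametes] = 2nr
        # count via per-individual haplotype reconstruction of unambiguous cases
        r_true = haldane(100.0)
        # estimator: fraction of (0,2)/(2,0) genotypes = r^2/4 each; use
        # double heterozygote-free counts for an unbiased moment estimate
        frac_02 = np.mean((g[0] == 0) & (g[1] == 2)) + np.mean((g[0] == 2) & (g[1] == 0))
        expect = 2 * (r_true / 2) ** 2
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac_02 - expect) < 3 * se + 1e-12

    def test_alternate_allele_frequency_half(self):
        gmap, haps = simulate_genome(3, [100.0] * 3, 120, 2, seed=12)
        f3 = simulate_cross(gmap, haps[0], haps[1], 300, 2, seed=13)
        poly = haps[0] != haps[1]
        freq = f3.genotypes[poly].mean() / 2.0
        assert freq == pytest.approx(0.5, abs=0.02)

    def test_heterozygous_parent_rejected(self):
        gmap, haps = simulate_genome(1, [50.0], 10, 2, seed=14)
        het_parent = np.vstack([haps[0], haps[1]])
        with pytest.raises(ValueError, match="homozygous"):
            simulate_cross(gmap, het_parent, haps[1], 5, 1, seed=15)

    def test_seed_determinism(self):
        gmap, haps = simulate_genome(2, [90.0, 70.0], 60, 2, seed=16)
        a = simulate_cross(gmap, haps[0], haps[1], 50, 2, seed=17)
        b = simulate_cross(gmap, haps[0], haps[1], 50, 2, seed=17)
        assert np.array_equal(a.genotypes, b.genotypes)


class TestSimulatePhenotypes:
    def _noise_free_truth(self, gmap):
        rng = np.random.default_rng(0)
        qtl = list(gmap.markers[:5])
        return SimTruth(
            traits={
                "T": TraitTruth(
                    qtl_markers=qtl,
                    additive=rng.normal(0, 1, 5),
                    dominance=rng.normal(0, 0.2, 5),
                    heat_multiplier=np.full(5, 1.5),
                    mu=10.0,
                    condition_effect={"standard": 0.0, "heat": -3.0},
                    sigma2_e={"standard": 0.0, "heat": 0.0},
                    sigma2_rep=0.0,
                    sigma2_block=0.0,
                )
            },
            seed=0,
        )

    def test_noise_free_limit_reproduces_genetic_values(self):
        gmap, haps = simulate_genome(2, [50.0, 50.0], 20, 2, seed=20)
        geno = simulate_cross(gmap, haps[0], haps[1], 15, 2, seed=21)
        truth = self._noise_free_truth(gmap)
        designs = {
            c: lattice_design(list(geno.individuals), c, 3, 4, seed=22) for c in CONDITIONS
        }
        pheno = simulate_phenotypes(geno, truth, designs, seed=23)
        gv = genetic_values(geno, truth.traits["T"])
        col = {g: j for j, g in enumerate(geno.individuals)}
        for row in pheno.itertuples(index=False):
            expected = (
                10.0
                + gv[row.condition][col[row.genotype]]
                + truth.traits["T"].condition_effect[row.condition]
            )
            assert row.value == pytest.approx(expected, abs=1e-10)

    def test_null_genetics_yield_zero_genetic_variance(self):
        gmap, haps = simulate_genome(1, [60.0], 10, 2, seed=24)
        geno = simulate_cross(gmap, haps[0], haps[1], 40, 2, seed=25)
        truth = self._noise_free_truth(gmap)
        tt = truth.traits["T"]
        tt.additive = np.zeros(5)
        tt.dominance = np.zeros(5)
        tt.sigma2_e = {"standard": 1.0, "heat": 1.0}
        designs = {
            c: lattice_design(list(geno.individuals), c, 3, 4, seed=26) for c in CONDITIONS
        }
        pheno = simulate_phenotypes(geno, truth, designs, seed=27)
        from heatmaize.mixmod import genotype_variance_components, heritability

        vc = genotype_variance_components(pheno, "standard", "T")
        assert heritability(vc, 3) == pytest.approx(0.0, abs=0.15)

    def test_design_mismatch_rejected(self):
        gmap, haps = simulate_genome(1, [60.0], 10, 2, seed=28)
        geno = simulate_cross(gmap, haps[0], haps[1], 10, 2, seed=29)
        truth = self._noise_free_truth(gmap)
        designs = {
            c: lattice_design(["nope_1", "nope_2", "nope_3"], c, 3, 2, seed=30)
            for c in CONDITIONS
        }
        with pytest.raises(ValueError, match="absent"):
            simulate_phenotypes(geno, truth, designs, seed=31)


class TestGenotypeProbabilities:
    def test_error_free_probabilities_recover_truth(self, small_study):
        geno = small_study.geno_sparse
        gp = add_genotype_probabilities(geno, 0.0, 0.0, seed=1)
        assert np.allclose(gp.sum(axis=2), 1.0)
        assert (gp.argmax(axis=2) == geno.genotypes).all()
        assert (gp.max(axis=2) >= 0.98).all()

    def test_all_missing_filters_to_missing(self, small_study):
        geno = small_study.geno_sparse
        gp = add_genotype_probabilities(geno, 0.0, 1.0, seed=2)
        called = gp_cutoff_filter(gp, GPCutoffPolicy("GP098"), geno)
        assert (called.genotypes == -1).all()

    def test_error_rate_matches_direct_count(self, small_study):
        geno = small_study.geno_sparse
        gp = add_genotype_probabilities(geno, 0.05, 0.0, seed=3)
        wrong = (gp.argmax(axis=2) != geno.genotypes).mean()
        n = geno.genotypes.size
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(wrong - 0.05) < 4 * se

    def test_rate_validation(self, small_study):
        with pytest.raises(ValueError):
            add_genotype_probabilities(small_study.geno_sparse, -0.1, 0.0, seed=1)


class TestStudySimulation:
    def test_default_scheme_and_sizes(self, small_study):
        pops = small_study.geno_dense.population_ids()
        assert pops == ["P_D1D2", "P_D3D4", "P_F1F2", "P_F3F4", "P_D1F1", "P_D4F4"]
        assert small_study.geno_dense.n_individuals == 180
        assert small_study.geno_sparse.n_markers == 170
        assert set(small_study.phenotypes["condition"]) == {"standard", "heat"}
        # each genotype once per replicate per condition
        counts = small_study.phenotypes.groupby(
            ["trait", "condition", "replicate"]
        )["genotype"].nunique()
        assert (counts == 180).all()

    def test_study_seed_determinism(self):
        a = simulate_study(seed=9, n_progeny=10, n_markers_dense=120, n_traits=1, n_blocks=4)
        b = simulate_study(seed=9, n_progeny=10, n_markers_dense=120, n_traits=1, n_blocks=4)
        assert np.array_equal(a.geno_dense.genotypes, b.geno_dense.genotypes)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
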