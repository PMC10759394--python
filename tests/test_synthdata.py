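"""Synthetic peaks, alignment blocks, genotypes, effects, GWAS, and PIPs."""

import numpy as np
import pandas as pd
import pytest

from conselem.annotate import annotate_snps
from conselem.elements import conservation_fraction, intersect_peaks
from conselem.synthdata import (
    SimulationScenario,
    matched_negative,
    prior_inclusion_probability,
    simulate_alignment_blocks,
    simulate_context_peaks,
    simulate_effects,
    simulate_genotypes,
    simulate_gwas,
    simulate_pips,
    solve_theta0,
)

GENOME = {"chr1": 1_000_000, "chr2": 600_000}


class TestContextPeaks:
    def test_zero_overlap_gives_empty_intersection(self):
        h3k, acc = simulate_context_peaks(GENOME, 200, overlap_frac=0.0, seed=1)
        assert len(intersect_peaks(h3k, acc)) == 0

    def test_full_overlap_gives_identical_sets(self):
        h3k, acc = simulate_context_peaks(GENOME, 200, overlap_frac=1.0, seed=1)
        pd.testing.assert_frame_equal(h3k.intervals, acc.intervals)
        inter = intersect_peaks(h3k, acc)
        assert inter.total_bases == h3k.total_bases

    def test_seeded_determinism(self):
        a = simulate_context_peaks(GENOME, 500, overlap_frac=0.4, seed=9)
        b = simulate_context_peaks(GENOME, 500, overlap_frac=0.4, seed=9)
        pd.testing.assert_frame_equal(a[0].intervals, b[0].intervals)
        pd.testing.assert_frame_equal(a[1].intervals, b[1].intervals)

    def test_expected_overlap_fraction(self):
        h3k, acc = simulate_context_peaks(GENOME, 800, overlap_frac=0.6, seed=3)
        inter = intersect_peaks(h3k, acc)
        frac = inter.total_bases / h3k.total_bases
        assert frac == pytest.approx(0.6, abs=0.06)

    def test_sorted_and_in_bounds(self):
        h3k, acc = simulate_context_peaks(GENOME, 300, overlap_frac=0.5, seed=5)
        for es in (h3k, acc):
            for chrom, grp in es.intervals.groupby("chrom"):
                assert grp["start"].is_monotonic_increasing
                assert (grp["end"] <= GENOME[chrom]).all()

    def test_empty_genome_raises(self):
        with pytest.raises(ValueError, match="chromosome"):
            simulate_context_peaks({}, 10)


class TestAlignmentBlocks:
    def test_full_coverage_scores_one(self):
        blocks = simulate_alignment_blocks(GENOME, 1.0, seed=1)
        from conselem.elements import GenomicInterval

        assert conservation_fraction(GenomicInterval("chr1", 100, 5000), blocks) == 1.0

    def test_zero_coverage_empty(self):
        blocks = simulate_alignment_blocks(GENOME, 0.0, seed=1)
        assert len(blocks) == 0

    @pytest.mark.parametrize("coverage", [0.1, 0.5, 0.9])
    def test_realized_coverage_within_two_percent(self, coverage):
        blocks = simulate_alignment_blocks(GENOME, coverage, seed=2)
        for chrom, size in GENOME.items():
            sub = blocks.blocks[blocks.blocks["chrom"] == chrom]
            realized = (sub["end"] - sub["start"]).sum() / size
            assert realized == pytest.approx(coverage, abs=0.02)

    def test_source_blocks_non_overlapping(self):
        blocks = simulate_alignment_blocks(GENOME, 0.5, seed=4).blocks
        for _, grp in blocks.groupby("chrom"):
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()


class TestGenotypes:
    def test_rho_zero_uncorrelated(self):
        scen = SimulationScenario(n_snps=200, n_individuals=5000, seed=1)
        geno = simulate_genotypes(scen, rho=0.0, block_size=20)
        x = geno.values.astype(float)
        xs = (x - x.mean(0)) / x.std(0)
        corr = xs.T @ xs / len(x)
        off = np.abs(corr[np.triu_indices(200, 1)])
        assert off.mean() < 0.02

    def test_rho_one_identical_standardized_columns(self):
        scen = SimulationScenario(n_snps=50, n_individuals=400, seed=2)
        geno = simulate_genotypes(scen, maf_dist=(0.3, 0.3 + 1e-9), rho=1.0, block_size=10, maf_floor=0.05)
        x = geno.values.astype(float)
        xs = (x - x.mean(0)) / x.std(0)
        for b in range(5):
            cols = xs[:, geno.block_assignment == b]
            assert np.allclose(cols, cols[:, [0]][:, np.zeros(cols.shape[1], int)])

    def test_realized_maf_floor(self):
        scen = SimulationScenario(n_snps=500, n_individuals=300, seed=3)
        geno = simulate_genotypes(scen, maf_dist=(0.05, 0.5), rho=0.4)
        freq = geno.values.mean(axis=0) / 2
        maf = np.minimum(freq, 1 - freq)
        assert (maf >= 0.05 - 1e-12).all()

    def test_maf_floor_above_half_raises(self):
        scen = SimulationScenario(n_snps=10, n_individuals=10, seed=0)
        with pytest.raises(ValueError, match="floor"):
            simulate_genotypes(scen, maf_dist=(0.5, 0.6))

    def test_blockwise_ar1_correlation(self):
        scen = SimulationScenario(n_snps=100, n_individuals=8000, seed=5)
        geno = simulate_genotypes(scen, maf_dist=(0.45, 0.5), rho=0.8, block_size=50)
        x = geno.values.astype(float)
        xs = (x - x.mean(0)) / x.std(0)
        # latent AR(1) at lag 1 implies strong positive genotype correlation
        r01 = float(xs[:, 0] @ xs[:, 1] / len(x))
        assert 0.5 < r01 < 0.9
        # across blocks: independent
        r_cross = float(xs[:, 49] @ xs[:, 50] / len(x))
        assert abs(r_cross) < 0.05


class TestEffects:
    def test_pi_closed_forms(self):
        a = np.array([0, 1])
        pi = prior_inclusion_probability(a, theta0=-2.0, theta=0.0)
        assert pi[0] == pytest.approx(1 / 101)
        pi = prior_inclusion_probability(a, theta0=-2.0, theta=1.0)
        assert pi[1] == pytest.approx(1 / 11)

    def test_slab_variance_closed_form(self):
        a = np.ones(4000, dtype=int)
        beta = simulate_effects(a, theta0=2.0, theta=0.0, sigma0_sq=0.1, sigma_sq=0.2, seed=1)
        nz = beta[beta != 0]
        assert nz.var() == pytest.approx(0.3, rel=0.1)

    def test_causal_fraction_law_of_large_numbers(self):
        a = (np.arange(100_000) % 10 == 0).astype(int)
        theta0, theta = -2.0, 1.0
        beta = simulate_effects(a, theta0, theta, 1.0, 0.5, seed=7)
        pi = prior_inclusion_probability(a, theta0, theta)
        expected = pi.mean()
        mc_sd = np.sqrt((pi * (1 - pi)).sum()) / len(a)
        assert abs((beta != 0).mean() - expected) < 3 * mc_sd

    def test_invalid_sigma0_raises(self):
        with pytest.raises(ValueError, match="sigma0_sq"):
            simulate_effects(np.zeros(5, int), -2, 0, 0.0, 0.0)


class TestGwas:
    @pytest.fixture(scope="class")
    def geno(self):
        scen = SimulationScenario(n_snps=2000, n_individuals=800, seed=11)
        return simulate_genotypes(scen, rho=0.3)

    def test_null_z_scores_standard_normal(self, geno):
        gwas = simulate_gwas(geno, np.zeros(geno.n_snps), pve=0.0, seed=1)
        z = gwas["z"].to_numpy()
        assert abs(z.mean()) < 0.05
        assert 0.9 < z.var() < 1.1

    def test_pve_controls_signal(self, geno):
        rng = np.random.default_rng(0)
        beta = np.zeros(geno.n_snps)
        beta[rng.choice(geno.n_snps, 20, replace=False)] = rng.standard_normal(20)
        z_lo = simulate_gwas(geno, beta, pve=0.1, seed=2)["z"].to_numpy()
        z_hi = simulate_gwas(geno, beta, pve=0.6, seed=2)["z"].to_numpy()
        assert (z_hi**2).mean() > (z_lo**2).mean()

    def test_single_causal_snp_attains_max_z(self):
        # no LD so the causal SNP should dominate
        scen = SimulationScenario(n_snps=200, n_individuals=1000, seed=3)
        geno = simulate_genotypes(scen, rho=0.0, block_size=1)
        beta = np.zeros(200)
        beta[77] = 1.0
        wins = 0
        for s in range(100):
            gwas = simulate_gwas(geno, beta, pve=0.3, seed=1000 + s)
            wins += int(np.argmax(np.abs(gwas["z"])) == 77)
        assert wins >= 95

    def test_seeded_determinism(self, geno):
        beta = np.zeros(geno.n_snps)
        beta[5] = 0.5
        a = simulate_gwas(geno, beta, pve=0.2, seed=9)
        b = simulate_gwas(geno, beta, pve=0.2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_beta_with_positive_pve_raises(self, geno):
        with pytest.raises(ValueError, match="zero"):
            simulate_gwas(geno, np.zeros(geno.n_snps), pve=0.2, seed=0)


class TestPips:
    @pytest.fixture(scope="class")
    def snps(self):
        return pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(10_000)],
                "chrom": "chr1",
                "pos": np.arange(10_000) * 100,
                "a1": "A",
                "a2": "G",
                "maf": 0.2,
            }
        )

    def test_bounds(self, snps):
        a = (np.arange(len(snps)) % 7 == 0).astype(int)
        pips = simulate_pips(snps, a, enrich_ratio=4.0, seed=1)["pip"].to_numpy()
        assert ((pips >= 0) & (pips <= 1)).all()

    def test_no_enrichment_equal_means(self, snps):
        a = (np.arange(len(snps)) % 2 == 0).astype(int)
        pips = simulate_pips(snps, a, enrich_ratio=1.0, seed=2)["pip"].to_numpy()
        assert abs(pips[a == 1].mean() - pips[a == 0].mean()) < 0.02

    def test_enrichment_ratio_of_means(self, snps):
        a = (np.arange(len(snps)) % 3 == 0).astype(int)
        pips = simulate_pips(snps, a, enrich_ratio=3.0, seed=3)["pip"].to_numpy()
        ratio = pips[a == 1].mean() / pips[a == 0].mean()
        assert ratio == pytest.approx(3.0, rel=0.25)

    def test_invalid_ratio_raises(self, snps):
        with pytest.raises(ValueError, match="enrich_ratio"):
            simulate_pips(snps, np.zeros(len(snps), int), enrich_ratio=0.5)


class TestScenarios:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationScenario(prop_causal=0.0)
        with pytest.raises(ValueError):
            SimulationScenario(pve=1.0)
        with pytest.raises(ValueError):
            SimulationScenario(theta=-1.0)

    def test_matched_negative_preserves_causal_fraction_and_pve(self):
        pos = SimulationScenario(
            prop_causal=0.01,
            pve=0.4,
            theta0=solve_theta0(0.01, 2.0, 0.1),
            theta=2.0,
            sigma_sq=1.0,
        )
        neg = matched_negative(pos)
        assert neg.is_negative
        assert neg.pve == pos.pve
        a = (np.arange(10) < 1).astype(int)  # 10% annotated
        pi_pos = prior_inclusion_probability(a, pos.theta0, pos.theta).mean()
        pi_neg = prior_inclusion_probability(a, neg.theta0, neg.theta).mean()
        assert pi_pos == pytest.approx(0.01, abs=1e-9)
        assert pi_neg == pytest.approx(0.01, abs=1e-9)
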