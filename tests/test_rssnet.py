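"""Harmonization, variational inference, Bayes factors, and element P1."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conselem.elements import GenomicInterval
from conselem.rssnet import (
    EffectPrior,
    GridConfig,
    LdStructure,
    bayes_factor,
    element_p1,
    fit_model,
    harmonize_gwas,
    regularize_ld,
    variational_fit,
)
from conselem.synthdata import (
    SimulationScenario,
    simulate_effects,
    simulate_genotypes,
    simulate_gwas,
)


def _gwas_frame(betahat, se, pos=None):
    p = len(betahat)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(p)],
            "chrom": "chr1",
            "pos": np.arange(p) * 10 if pos is None else pos,
            "a1": "A",
            "a2": "G",
            "beta": betahat,
            "se": se,
            "n": 1000,
            "z": np.asarray(betahat) / np.asarray(se),
        }
    )


def _exact_pips(betahat, se, R, pi, sigma2):
    """Exhaustive enumeration of all sparsity patterns under the summary-stat
    likelihood; the independent oracle for the variational fit."""
    p = len(betahat)
    S = np.diag(se)
    cov0 = S @ R @ S
    Sinv = np.linalg.inv(S)
    M = S @ R @ Sinv
    logps = []
    for cfg in product([0, 1], repeat=p):
        g = np.array(cfg, dtype=float)
        D = np.diag(g * sigma2)
        cov = cov0 + M @ D @ M.T
        lp = stats.multivariate_normal.logpdf(betahat, np.zeros(p), cov)
        lp += float(np.sum(g * np.log(pi) + (1 - g) * np.log(1 - pi)))
        logps.append((g, lp))
    mx = max(lp for _, lp in logps)
    w = np.array([np.exp(lp - mx) for _, lp in logps])
    w /= w.sum()
    pips = np.zeros(p)
    for (g, _), wi in zip(logps, w):
        pips += g * wi
    return pips


class TestHarmonize:
    def _ref(self):
        return pd.DataFrame(
            {
                "snp": ["rs1", "rs2", "rs3"],
                "chrom": "chr1",
                "pos": [10, 20, 30],
                "a1": ["T", "A", "C"],
                "a2": ["G", "G", "A"],
                "maf": 0.2,
            }
        )

    def test_allele_swap_flips_sign(self):
        gwas = _gwas_frame([0.1], [0.05])
        gwas["snp"] = ["rs1"]
        gwas["a1"], gwas["a2"] = ["G"], ["T"]
        aligned, report = harmonize_gwas(gwas, self._ref())
        assert aligned.loc[0, "beta"] == pytest.approx(-0.1)
        assert report["sign_flipped"] == 1

    def test_strand_ambiguous_dropped(self):
        gwas = _gwas_frame([0.1, 0.2], [0.05, 0.05])
        gwas["snp"] = ["rs2", "rs3"]
        gwas.loc[0, ["a1", "a2"]] = ["A", "T"]
        gwas.loc[1, ["a1", "a2"]] = ["C", "G"]
        with pytest.raises(ValueError):
            harmonize_gwas(gwas, self._ref())

    def test_identity_passthrough(self):
        ref = self._ref()
        gwas = _gwas_frame([0.1, 0.2, 0.3], [0.05, 0.05, 0.05])
        gwas["snp"] = ref["snp"]
        gwas["a1"], gwas["a2"] = ref["a1"], ref["a2"]
        aligned, report = harmonize_gwas(gwas, ref)
        assert report["matched"] == 3
        assert sum(v for k, v in report.items() if k != "matched") == 0
        np.testing.assert_allclose(aligned["beta"], gwas["beta"])

    def test_strand_complement_resolved(self):
        gwas = _gwas_frame([0.1], [0.05])
        gwas["snp"] = ["rs1"]
        gwas["a1"], gwas["a2"] = ["A"], ["C"]  # complement of T/G
        aligned, report = harmonize_gwas(gwas, self._ref())
        assert report["strand_flipped"] == 1
        assert aligned.loc[0, "beta"] == pytest.approx(0.1)


class TestVariationalFit:
    def test_single_snp_matches_exact_posterior(self):
        betahat, se, s2, pi = 0.27, 0.08, 0.05, 1 / 31
        gwas = _gwas_frame([betahat], [se])
        ld = LdStructure([np.eye(1)], np.zeros(1, dtype=int))
        prior = EffectPrior(np.log10(pi / (1 - pi)), 0.0, s2, 0.0)
        sol = variational_fit(gwas, ld, prior, annotation=np.zeros(1), tol=1e-12)
        bf = np.sqrt(se**2 / (se**2 + s2)) * np.exp(
            betahat**2 * s2 / (2 * se**2 * (se**2 + s2))
        )
        exact = pi * bf / (pi * bf + 1 - pi)
        assert sol.alpha[0] == pytest.approx(exact, abs=1e-6)

    def test_elbo_monotone_every_iteration(self):
        rng = np.random.default_rng(3)
        p = 30
        R = regularize_ld(np.linalg.matrix_power(np.eye(p) * 0 + 0.6, 1) ** np.abs(
            np.subtract.outer(np.arange(p), np.arange(p))
        ), shrinkage=0.0)
        se = np.full(p, 0.05)
        betahat = rng.normal(0, 0.1, p)
        gwas = _gwas_frame(betahat, se)
        ld = LdStructure([R], np.zeros(p, dtype=int))
        prior = EffectPrior(-1.5, 0.0, 0.02, 0.0)
        sol = variational_fit(gwas, ld, prior, annotation=np.zeros(p), tol=1e-12, max_iter=100)
        assert np.all(np.diff(sol.elbo_trace) >= -1e-9 * (1 + np.abs(sol.elbo_trace[:-1])))

    def test_three_snp_ld_close_to_enumeration(self):
        rng = np.random.default_rng(1)
        R = regularize_ld(
            np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1.0]]), shrinkage=0.0
        )
        se = np.array([0.1, 0.12, 0.09])
        S = np.diag(se)
        true_beta = np.array([0.4, 0.0, 0.0])
        bh = rng.multivariate_normal(S @ R @ np.linalg.solve(S, true_beta), S @ R @ S)
        gwas = _gwas_frame(bh, se)
        ld = LdStructure([R], np.zeros(3, dtype=int))
        pi, s2 = 1 / 11, 0.05
        prior = EffectPrior(np.log10(pi / (1 - pi)), 0.0, s2, 0.0)
        sol = variational_fit(gwas, ld, prior, annotation=np.zeros(3), tol=1e-12)
        exact = _exact_pips(bh, se, R, np.full(3, pi), s2)
        assert np.max(np.abs(sol.alpha - exact)) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_correlation_with_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(5, 11))
        base = rng.uniform(0.2, 0.7)
        R = regularize_ld(base ** np.abs(np.subtract.outer(np.arange(p), np.arange(p))),
                          shrinkage=0.0)
        se = rng.uniform(0.05, 0.15, p)
        S = np.diag(se)
        true_beta = np.zeros(p)
        true_beta[rng.integers(p)] = rng.normal(0, 0.3)
        bh = rng.multivariate_normal(S @ R @ np.linalg.solve(S, true_beta), S @ R @ S)
        gwas = _gwas_frame(bh, se)
        ld = LdStructure([R], np.zeros(p, dtype=int))
        pi, s2 = 0.1, 0.09
        prior = EffectPrior(np.log10(pi / (1 - pi)), 0.0, s2, 0.0)
        sol = variational_fit(gwas, ld, prior, annotation=np.zeros(p), tol=1e-12)
        exact = _exact_pips(bh, se, R, np.full(p, pi), s2)
        rho = stats.spearmanr(sol.alpha, exact).statistic
        assert rho >= 0.9 or np.max(np.abs(sol.alpha - exact)) < 0.05


@pytest.fixture(scope="module")
def small_dataset():
    scen = SimulationScenario(n_snps=300, n_individuals=1458, seed=31)
    geno = simulate_genotypes(scen, rho=0.5, block_size=30)
    ld = LdStructure.from_genotypes(geno)
    annotation = (np.arange(300) % 10 == 0).astype(np.int8)
    return geno, ld, annotation


class TestFitModel:
    def test_mode_b_equals_mode_h_with_zero_annotation(self, small_dataset):
        geno, ld, annotation = small_dataset
        beta = simulate_effects(annotation, -1.8, 1.0, 1.0, 1.0, seed=2)
        gwas = simulate_gwas(geno, beta, pve=0.3, seed=2)
        grid = GridConfig(
            theta0=(-2.5, -1.5), theta=(0.0, 2.0),
            sigma0_sq=(0.005,), sigma_sq=(0.0, 0.005),
        )
        fit_b = fit_model(gwas, ld, None, grid=grid, mode="B", n_restarts=1)
        with pytest.warns(UserWarning, match="a_j = 1"):
            fit_h0 = fit_model(gwas, ld, np.zeros(300, dtype=np.int8), grid=grid,
                               mode="H", n_restarts=1)
        np.testing.assert_allclose(fit_b.alpha, fit_h0.alpha, atol=1e-12)
        assert [p for p in fit_b.priors] == [p for p in fit_h0.priors]

    def test_deterministic_given_config(self, small_dataset):
        geno, ld, annotation = small_dataset
        beta = simulate_effects(annotation, -1.8, 1.5, 1.0, 1.0, seed=5)
        gwas = simulate_gwas(geno, beta, pve=0.3, seed=5)
        grid = GridConfig(theta0=(-2.0,), theta=(0.0, 1.5),
                          sigma0_sq=(0.005,), sigma_sq=(0.0,))
        a = fit_model(gwas, ld, annotation, grid=grid, mode="H")
        b = fit_model(gwas, ld, annotation, grid=grid, mode="H")
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.elbos, b.elbos)

    def test_enriched_simulation_favors_enrichment_points(self, small_dataset):
        geno, ld, annotation = small_dataset
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            beta = simulate_effects(annotation, -2.0, 2.0, 4.0, 4.0, seed=100 + s)
            if not beta.any():
                beta[0] = 1.0
            gwas = simulate_gwas(geno, beta, pve=0.4, seed=100 + s)
            unit = float(np.median(gwas["se"] ** 2))
            grid = GridConfig(theta0=(-2.5, -1.5), theta=(0.0, 2.0),
                              sigma0_sq=(unit * 32,), sigma_sq=(0.0,))
            fit = fit_model(gwas, ld, annotation, grid=grid, mode="H", n_restarts=1)
            mass_enriched = fit.weights[[not p.is_null for p in fit.priors]].sum()
            hits += int(mass_enriched > 0.5)
        assert hits >= int(0.8 * n_seeds)


class TestBayesFactor:
    def test_degenerate_grid_gives_bf_one(self, small_dataset):
        geno, ld, annotation = small_dataset
        beta = simulate_effects(annotation, -1.8, 0.0, 1.0, 0.0, seed=9)
        if not beta.any():
            beta[3] = 1.0
        gwas = simulate_gwas(geno, beta, pve=0.2, seed=9)
        grid = GridConfig(theta0=(-2.5, -1.5), theta=(0.0,),
                          sigma0_sq=(0.004,), sigma_sq=(0.0,))
        fit_enr = fit_model(gwas, ld, annotation, grid=grid, mode="H", n_restarts=1)
        fit_null = fit_model(gwas, ld, None, grid=grid, mode="B", n_restarts=1)
        assert bayes_factor(fit_enr, fit_null) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_data_raises(self, small_dataset):
        geno, ld, annotation = small_dataset
        beta = simulate_effects(annotation, -1.8, 0.0, 1.0, 0.0, seed=4)
        if not beta.any():
            beta[0] = 1.0
        g1 = simulate_gwas(geno, beta, pve=0.2, seed=4)
        g2 = simulate_gwas(geno, beta, pve=0.2, seed=5)
        grid = GridConfig(theta0=(-2.0,), theta=(0.0,), sigma0_sq=(0.004,), sigma_sq=(0.0,))
        f1 = fit_model(g1, ld, None, grid=grid, mode="B", n_restarts=1)
        f2 = fit_model(g2, ld, None, grid=grid, mode="B", n_restarts=1)
        with pytest.raises(ValueError, match="identical data"):
            bayes_factor(f1, f2)

    def test_power_and_null_behaviour(self, small_dataset):
        geno, ld, annotation = small_dataset
        n_seeds = 8
        log_bf_null, log_bf_enr = [], []
        for s in range(n_seeds):
            for enriched in (False, True):
                theta = 2.0 if enriched else 0.0
                sig = 4.0 if enriched else 0.0
                theta0 = -2.0
                beta = simulate_effects(annotation, theta0, theta, 4.0, sig, seed=200 + s)
                if not beta.any():
                    beta[7] = 2.0
                gwas = simulate_gwas(geno, beta, pve=0.4, seed=200 + s)
                unit = float(np.median(gwas["se"] ** 2))
                grid = GridConfig(theta0=(-2.5, -1.5), theta=(1.0, 2.5),
                                  sigma0_sq=(unit * 32,), sigma_sq=(0.0, unit * 32))
                fit_enr = fit_model(gwas, ld, annotation, grid=grid, mode="H", n_restarts=1)
                fit_null = fit_model(gwas, ld, None, grid=grid, mode="B", n_restarts=1)
                lb = np.log(bayes_factor(fit_enr, fit_null))
                (log_bf_enr if enriched else log_bf_null).append(lb)
        assert np.mean(np.array(log_bf_enr) > 0) >= 0.75
        assert np.median(np.abs(log_bf_null)) < np.median(np.abs(log_bf_enr))


class TestElementP1:
    def _fit_with_alpha(self, small_dataset, alphas):
        geno, ld, annotation = small_dataset
        beta = np.zeros(300)
        beta[0] = 1.0
        gwas = simulate_gwas(geno, beta, pve=0.2, seed=1)
        grid = GridConfig(theta0=(-2.0,), theta=(0.0,), sigma0_sq=(0.004,), sigma_sq=(0.0,))
        fit = fit_model(gwas, ld, None, grid=grid, mode="B", n_restarts=1)
        fit.solutions[0].alpha[:] = 0.0
        for j, a in alphas.items():
            fit.solutions[0].alpha[j] = a
        return fit, geno.snp_table()

    def test_single_snp_element(self, small_dataset):
        fit, snps = self._fit_with_alpha(small_dataset, {5: 0.37})
        pos = int(snps.loc[5, "pos"])
        el = GenomicInterval("chr1", pos, pos + 1)
        assert element_p1(fit, el, snps) == pytest.approx(0.37)

    def test_all_zero_alpha_gives_zero(self, small_dataset):
        fit, snps = self._fit_with_alpha(small_dataset, {})
        el = GenomicInterval("chr1", 0, int(snps["pos"].max()) + 1)
        assert element_p1(fit, el, snps) == 0.0

    def test_two_half_alphas_give_three_quarters(self, small_dataset):
        fit, snps = self._fit_with_alpha(small_dataset, {2: 0.5, 3: 0.5})
        p2, p3 = int(snps.loc[2, "pos"]), int(snps.loc[3, "pos"])
        el = GenomicInterval("chr1", min(p2, p3), max(p2, p3) + 1)
        assert element_p1(fit, el, snps) == pytest.approx(0.75)

    def test_element_without_snps_raises(self, small_dataset):
        fit, snps = self._fit_with_alpha(small_dataset, {})
        with pytest.raises(ValueError, match="no SNPs"):
            element_p1(fit, GenomicInterval("chr9", 0, 100), snps)
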