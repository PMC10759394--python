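"""Synthetic inputs with the statistical structure the pipeline assumes.

This module generates every input the analysis consumes: context-matched peak
tracks, gapless cross-genome alignment blocks, block-structured genotypes,
sparse SNP effects drawn from the spike-and-slab prior, single-SNP GWAS
summary statistics from an additive phenotype model, and fine-mapping PIP
tables with controllable annotation enrichment.  Every generator is
deterministic given its seed.

Genotypes use a latent-Gaussian construction: within an LD block the latent
variables follow an AR(1) process with parameter ``rho`` (independent across
blocks), and two latent haplotypes per individual are thresholded at the
Hardy–Weinberg quantile of the sampled allele frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .elements import AlignmentBlockSet, ElementSet, intervals_frame

__all__ = [
    "SimulationScenario",
    "GenotypeMatrix",
    "simulate_context_peaks",
    "simulate_alignment_blocks",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_gwas",
    "simulate_pips",
    "prior_inclusion_probability",
    "solve_theta0",
    "matched_negative",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design.

    ``theta0``/``theta`` are the baseline and enrichment log10-odds of a SNP
    being trait-associated; ``sigma0_sq``/``sigma_sq`` the baseline and
    enrichment components of the causal effect variance.  A negative scenario
    has ``theta == 0`` and ``sigma_sq == 0``.
    """

    n_snps: int = 2000
    n_individuals: int = 1458
    frac_annotated: float = 0.10
    prop_causal: float = 0.005
    pve: float = 0.2
    theta0: float = -2.3
    theta: float = 0.0
    sigma0_sq: float = 1.0
    sigma_sq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prop_causal < 1:
            raise ValueError("prop_causal must lie in (0, 1)")
        if not 0 <= self.pve < 1:
            raise ValueError("pve must lie in [0, 1)")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.sigma_sq < 0:
            raise ValueError("sigma_sq must be >= 0")
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be > 0")

    @property
    def is_negative(self) -> bool:
        return self.theta == 0 and self.sigma_sq == 0


@dataclass
class GenotypeMatrix:
    """0/1/2 allele counts for individuals x SNPs, with LD-block structure."""

    values: np.ndarray
    snp_ids: list[str]
    block_assignment: np.ndarray
    positions: np.ndarray | None = None
    chrom: str = "chr1"
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1, or 2")
        self.block_assignment = np.asarray(self.block_assignment)
        if self.values.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids must match the number of SNP columns")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def snp_table(self) -> pd.DataFrame:
        freq = self.values.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        pos = self.positions if self.positions is not None else np.arange(self.n_snps)
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "chrom": self.chrom,
                "pos": np.asarray(pos, dtype=np.int64),
                "a1": "A",
                "a2": "G",
                "maf": maf,
            }
        )


# ---------------------------------------------------------------------------
# prior helpers
# ---------------------------------------------------------------------------


def prior_inclusion_probability(
    annotation: np.ndarray, theta0: float, theta: float
) -> np.ndarray:
    """pi_j = (1 + 10^-(theta0 + a_j * theta))^-1."""
    a = np.asarray(annotation, dtype=float)
    return 1.0 / (1.0 + 10.0 ** -(theta0 + a * theta))


def solve_theta0(prop_causal: float, theta: float, frac_annotated: float) -> float:
    """Baseline log10-odds giving an expected causal fraction of ``prop_causal``.

    With a fraction ``frac_annotated`` of SNPs annotated and enrichment
    ``theta``, the mean of pi_j over the genome is matched to ``prop_causal``.
    This is how positive and negative scenarios are matched on the proportion
    of trait-associated SNPs.
    """
    fa = frac_annotated

    def mean_pi(theta0: float) -> float:
        p0 = 1.0 / (1.0 + 10.0 ** -theta0)
        p1 = 1.0 / (1.0 + 10.0 ** -(theta0 + theta))
        return (1 - fa) * p0 + fa * p1

    lo, hi = -12.0, 4.0
    return float(optimize.brentq(lambda t: mean_pi(t) - prop_causal, lo, hi, xtol=1e-12))


def matched_negative(scenario: SimulationScenario) -> SimulationScenario:
    """The matched no-enrichment scenario: theta = sigma_sq = 0, same
    proportion of trait-associated SNPs and the same PVE."""
    theta0 = solve_theta0(scenario.prop_causal, 0.0, scenario.frac_annotated)
    return replace(scenario, theta=0.0, sigma_sq=0.0, theta0=theta0)


# ---------------------------------------------------------------------------
# peak and alignment-block generators
# ---------------------------------------------------------------------------


def _draw_lengths(rng: np.random.Generator, dist: tuple[int, int], size: int) -> np.ndarray:
    lo, hi = dist
    return rng.integers(lo, hi + 1, size=size)


def simulate_context_peaks(
    genome_spec: Mapping[str, int],
    n_peaks: int,
    length_dist: tuple[int, int] = (200, 1000),
    overlap_frac: float = 0.5,
    seed: int = 0,
) -> tuple[ElementSet, ElementSet]:
    """Simulate paired H3K27ac and accessible-chromatin peak tracks.

    With probability ``overlap_frac`` an accessibility peak coincides exactly
    with an H3K27ac peak; otherwise it is placed in the gap after it, disjoint
    from all H3K27ac peaks.  The expected fraction of H3K27ac bases covered by
    accessibility peaks therefore equals ``overlap_frac``.
    """
    if not genome_spec:
        raise ValueError("genome must contain at least one chromosome")
    if any(length <= 0 for length in genome_spec.values()):
        raise ValueError("chromosome lengths must be positive")
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome_spec)
    sizes = np.array([genome_spec[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n_peaks, sizes / sizes.sum())
    h3k_rows, acc_rows = [], []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        length = genome_spec[chrom]
        peak_len = _draw_lengths(rng, length_dist, k)
        matched = rng.random(k) < overlap_frac
        acc_len = peak_len.copy()  # identical length_dist draw when matched
        spacer = rng.integers(1, 51, size=k)
        unit = peak_len + np.where(matched, 0, spacer + acc_len) + 1
        required = int(unit.sum())
        if required >= length:
            raise ValueError(
                f"cannot fit {k} peaks of the requested lengths on {chrom} ({length} bp)"
            )
        free = length - required
        gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        cursor = 0
        for i in range(k):
            cursor += gaps[i]
            start = cursor
            end = start + int(peak_len[i])
            h3k_rows.append((chrom, start, end))
            cursor = end
            if matched[i]:
                acc_rows.append((chrom, start, end))
            else:
                a_start = cursor + int(spacer[i])
                a_end = a_start + int(acc_len[i])
                acc_rows.append((chrom, a_start, a_end))
                cursor = a_end
            cursor += 1  # guard base so consecutive peaks never touch
        # trailing gap gaps[k] is implicit
    h3k = ElementSet(intervals_frame(h3k_rows), context="h3k27ac")
    acc = ElementSet(intervals_frame(acc_rows), context="accessible")
    return h3k, acc


def simulate_alignment_blocks(
    genome_spec: Mapping[str, int],
    target_coverage: float,
    block_length_dist: tuple[int, int] = (50, 500),
    seed: int = 0,
    target_prefix: str = "m_",
) -> AlignmentBlockSet:
    """Simulate gapless alignment blocks covering ``target_coverage`` of the
    source genome, paired with equal-length target-genome intervals."""
    if not genome_spec:
        raise ValueError("genome must contain at least one chromosome")
    if not 0 <= target_coverage <= 1:
        raise ValueError("target_coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in sorted(genome_spec):
        length = genome_spec[chrom]
        want = int(round(target_coverage * length))
        if want == 0:
            continue
        lengths = []
        total = 0
        while total < want:
            ln = int(_draw_lengths(rng, block_length_dist, 1)[0])
            ln = min(ln, want - total)
            lengths.append(ln)
            total += ln
        k = len(lengths)
        free = length - total
        src_gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        tgt_gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        s_cursor = t_cursor = 0
        for i, ln in enumerate(lengths):
            s_cursor += src_gaps[i]
            t_cursor += tgt_gaps[i]
            rows.append(
                (chrom, s_cursor, s_cursor + ln, target_prefix + chrom, t_cursor, t_cursor + ln)
            )
            s_cursor += ln
            t_cursor += ln
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "target_chrom", "target_start", "target_end"],
    )
    return AlignmentBlockSet(df, source_assembly="source", target_assembly="target")


# ---------------------------------------------------------------------------
# genotypes, effects, GWAS
# ---------------------------------------------------------------------------


def _ar1_latent(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """n x p latent Gaussian with AR(1) column correlation rho."""
    x = np.empty((n, p))
    x[:, 0] = rng.standard_normal(n)
    if p > 1:
        innov = rng.standard_normal((n, p - 1))
        scale = math.sqrt(max(0.0, 1.0 - rho * rho))
        for j in range(1, p):
            x[:, j] = rho * x[:, j - 1] + scale * innov[:, j - 1]
    return x


def simulate_genotypes(
    scenario: SimulationScenario,
    maf_dist: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.5,
    block_size: int = 100,
    spacing: int = 1000,
    maf_floor: float | None = None,
) -> GenotypeMatrix:
    """Simulate block-structured genotypes by thresholded latent Gaussians.

    Two latent haplotypes per individual share the AR(1) correlation within a
    block; blocks are independent.  Sampled allele frequencies come from a
    uniform ``maf_dist``; ``maf_floor`` (default: the distribution's lower
    bound) is also enforced on the realized frequencies — single alleles are
    toggled at random individuals for the rare boundary SNPs that drift below
    it.
    """
    lo, hi = maf_dist
    if maf_floor is None:
        maf_floor = lo
    if maf_floor >= 0.5:
        raise ValueError("MAF floor must be below 0.5")
    if not (abs(rho) < 1 or rho == 1):
        raise ValueError("rho must satisfy |rho| < 1 (or the degenerate rho == 1)")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n_individuals, scenario.n_snps
    maf = rng.uniform(lo, min(hi, 0.5), size=p)
    geno = np.empty((n, p), dtype=np.int8)
    n_blocks = math.ceil(p / block_size)
    blocks = np.repeat(np.arange(n_blocks), block_size)[:p]
    thresh = stats.norm.ppf(1.0 - maf)
    for b in range(n_blocks):
        cols = np.flatnonzero(blocks == b)
        hap1 = _ar1_latent(rng, n, len(cols), rho)
        hap2 = _ar1_latent(rng, n, len(cols), rho)
        geno[:, cols] = (hap1 > thresh[cols]).astype(np.int8) + (
            hap2 > thresh[cols]
        ).astype(np.int8)
    # enforce the realized MAF floor
    floor = maf_floor
    counts = geno.sum(axis=0, dtype=np.int64)
    for j in range(p):
        target_min = int(math.ceil(floor * 2 * n))
        target_max = 2 * n - target_min
        while counts[j] < target_min:
            i = int(rng.integers(n))
            if geno[i, j] < 2:
                geno[i, j] += 1
                counts[j] += 1
        while counts[j] > target_max:
            i = int(rng.integers(n))
            if geno[i, j] > 0:
                geno[i, j] -= 1
                counts[j] -= 1
    snp_ids = [f"snp{j:05d}" for j in range(p)]
    positions = np.arange(p, dtype=np.int64) * spacing + spacing // 2
    return GenotypeMatrix(
        geno, snp_ids, blocks, positions=positions, maf=np.minimum(maf, 1 - maf)
    )


def simulate_effects(
    annotation: np.ndarray,
    theta0: float,
    theta: float,
    sigma0_sq: float,
    sigma_sq: float,
    seed: int = 0,
) -> np.ndarray:
    """Draw sparse SNP effects from the annotation-informed spike-and-slab prior.

    beta_j is zero with probability 1 - pi_j and otherwise
    N(0, sigma0_sq + a_j * sigma_sq), with
    pi_j = (1 + 10^-(theta0 + a_j*theta))^-1.
    """
    if sigma0_sq <= 0:
        raise ValueError("sigma0_sq must be > 0")
    a = np.asarray(annotation)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("annotation must be binary")
    rng = np.random.default_rng(seed)
    pi = prior_inclusion_probability(a, theta0, theta)
    sigma2 = sigma0_sq + a * sigma_sq
    causal = rng.random(len(a)) < pi
    beta = np.zeros(len(a))
    beta[causal] = rng.standard_normal(causal.sum()) * np.sqrt(sigma2[causal])
    return beta


def marginal_summary_stats(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-SNP least-squares slope, SE, and z from single-SNP regressions."""
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    if (sxx == 0).any():
        raise ValueError("monomorphic SNP in genotype matrix")
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / ((n - 2) * sxx))
    return pd.DataFrame({"beta": beta, "se": se, "z": beta / se, "n": n})


def simulate_gwas(
    genotypes: GenotypeMatrix, beta: np.ndarray, pve: float, seed: int = 0
) -> pd.DataFrame:
    """Simulate a phenotype from the additive model and return single-SNP
    GWAS summary statistics.

    The Gaussian noise variance is scaled so the SNP-explained fraction of
    phenotypic variance equals ``pve``; ``pve == 0`` means pure unit-variance
    noise.  Columns: snp, chrom, pos, a1, a2, beta, se, n, z.
    """
    if not 0 <= pve < 1:
        raise ValueError("pve must lie in [0, 1)")
    beta = np.asarray(beta, dtype=float)
    if len(beta) != genotypes.n_snps:
        raise ValueError("beta length must equal the number of SNPs")
    rng = np.random.default_rng(seed)
    x = genotypes.values.astype(float)
    genetic = x @ beta
    var_g = float(genetic.var())
    if pve > 0:
        if var_g == 0:
            raise ValueError("cannot scale noise: genetic variance is zero (all-zero beta?)")
        noise_var = var_g * (1.0 - pve) / pve
    else:
        genetic = np.zeros_like(genetic)
        noise_var = 1.0
    y = genetic + rng.standard_normal(genotypes.n_individuals) * math.sqrt(noise_var)
    stats_df = marginal_summary_stats(x, y)
    table = genotypes.snp_table()
    out = pd.DataFrame(
        {
            "snp": table["snp"],
            "chrom": table["chrom"],
            "pos": table["pos"],
            "a1": table["a1"],
            "a2": table["a2"],
            "beta": stats_df["beta"].to_numpy(),
            "se": stats_df["se"].to_numpy(),
            "n": genotypes.n_individuals,
            "z": stats_df["z"].to_numpy(),
        }
    )
    return out


def simulate_pips(
    snp_table: pd.DataFrame,
    annotation,
    enrich_ratio: float = 1.0,
    seed: int = 0,
    base_mean: float = 0.05,
    concentration: float = 0.3,
    trait: str = "trait1",
    method: str = "synthetic",
) -> pd.DataFrame:
    """Simulate a fine-mapping PIP table with controllable enrichment.

    PIPs are Beta-distributed with fixed concentration; the mean for annotated
    SNPs is ``enrich_ratio`` times the mean for unannotated SNPs, capped at 1.
    """
    if enrich_ratio < 1:
        raise ValueError("enrich_ratio must be >= 1")
    a = np.asarray(getattr(annotation, "values", annotation))
    if len(a) != len(snp_table):
        raise ValueError("annotation length must match the SNP table")
    rng = np.random.default_rng(seed)
    mean = np.where(a == 1, min(enrich_ratio * base_mean, 1.0), base_mean)
    k = concentration
    pip = np.empty(len(a))
    degenerate = mean >= 1.0
    pip[degenerate] = 1.0
    m = mean[~degenerate]
    pip[~degenerate] = rng.beta(m * k, (1.0 - m) * k)
    return pd.DataFrame(
        {"snp": snp_table["snp"], "trait": trait, "method": method, "pip": pip}
    )
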