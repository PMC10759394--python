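"""Stratified heritability regression on GWAS summary statistics.

The per-SNP effect-size variance is modeled as a linear function of binary
annotations,

    Var(beta_j) = tau_0 + sum_d tau_d * a_d(j),

which implies E[chi2_j] ~ 1 + n * sum_d tau_d * l(j, d) where
l(j, d) = sum_k r^2(j, k) a_d(k) is the stratified LD score of SNP j.
Regressing observed chi2 statistics on LD scores with a free intercept gives
the tau estimates; block-jackknife resampling over contiguous SNP blocks
gives their standard errors and propagates into the two derived summaries:

* enrichment  = (h2_a / h2) / (|a| / p)
* tau*        = (p * SD_a / h2) * tau_a      (standardized effect size)

Random-effects meta-analysis (DerSimonian–Laird) pools estimates across
studies, and a generalized Deming regression assesses concordance between two
sets of estimates that both carry sampling error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats import meta_analysis as sm_meta

from .annotate import Annotation
from .synthdata import GenotypeMatrix


@dataclass
class LdScores:
    """Stratified LD scores: one column per annotation, rows aligned to SNPs."""

    values: np.ndarray  # p x A
    labels: list[str]
    snp_ids: list[str]
    window_bases: int | None = None
    reference: str = ""

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


@dataclass
class SldscFit:
    """Coefficients and jackknife replicates of a stratified heritability fit.

    ``tau`` holds one coefficient per annotation column (the first annotation
    is conventionally the all-SNPs base, whose coefficient is the background
    per-SNP contribution tau_0); ``intercept`` is the free regression
    intercept.  ``tau_jack`` holds delete-one-block pseudo-estimates with the
    intercept in the last column.
    """

    labels: list[str]
    tau: np.ndarray
    intercept: float
    tau_jack: np.ndarray  # B x (A + 1)
    annotations: np.ndarray  # p x A binary values
    n: float
    p: int

    @property
    def n_blocks(self) -> int:
        return self.tau_jack.shape[0]

    def tau_se(self) -> np.ndarray:
        """Jackknife SEs of the annotation coefficients (intercept excluded)."""
        b = self.n_blocks
        dev = self.tau_jack[:, :-1] - self.tau_jack[:, :-1].mean(axis=0)
        return np.sqrt((b - 1) / b * (dev**2).sum(axis=0))

    def intercept_se(self) -> float:
        b = self.n_blocks
        dev = self.tau_jack[:, -1] - self.tau_jack[:, -1].mean()
        return float(np.sqrt((b - 1) / b * (dev**2).sum()))

    def per_snp_variance(self, tau: np.ndarray | None = None) -> np.ndarray:
        """Var(beta_j) evaluated at the (given) coefficient vector."""
        t = self.tau if tau is None else tau
        return self.annotations @ t

    def h2(self, tau: np.ndarray | None = None) -> float:
        return float(self.per_snp_variance(tau).sum())

    def h2_annotation(self, label: str, tau: np.ndarray | None = None) -> float:
        mask = self.annotations[:, self.labels.index(label)] > 0
        return float(self.per_snp_variance(tau)[mask].sum())


@dataclass
class EnrichmentSummary:
    label: str
    enrichment: float
    enrichment_se: float
    enrichment_p: float
    tau_star: float
    tau_star_se: float
    tau_star_p: float
    diff: float  # per-SNP heritability difference contrast
    diff_se: float


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------


def compute_ld_scores(
    ref_genotypes: GenotypeMatrix,
    annotations: dict[str, np.ndarray] | list[Annotation],
    window_bases: int | None = None,
) -> LdScores:
    """Stratified LD scores from a reference genotype matrix.

    r^2 is the plain squared sample correlation of genotype columns.  SNP
    pairs beyond ``window_bases`` (or outside the same LD block when no window
    is given) contribute nothing.  Monomorphic reference SNPs are excluded
    from the reference sums with a warning.
    """
    if isinstance(annotations, list):
        annotations = {a.label or f"annot{i}": a.values for i, a in enumerate(annotations)}
    x = ref_genotypes.values.astype(float)
    p = x.shape[1]
    sd = x.std(axis=0)
    poly = sd > 0
    if not poly.all():
        warnings.warn(f"excluding {np.count_nonzero(~poly)} monomorphic reference SNPs")
    xs = np.zeros_like(x)
    xs[:, poly] = (x[:, poly] - x[:, poly].mean(axis=0)) / sd[poly]
    labels = list(annotations)
    amat = np.column_stack([np.asarray(annotations[k], dtype=float) for k in labels])
    amat[~poly, :] = 0.0
    values = np.zeros((p, len(labels)))
    if window_bases is not None:
        if ref_genotypes.positions is None:
            raise ValueError("window_bases requires SNP positions")
        pos = np.asarray(ref_genotypes.positions)
        order = np.argsort(pos)
        # contiguous windows over position-sorted SNPs
        lo = np.searchsorted(pos[order], pos[order] - window_bases, side="left")
        hi = np.searchsorted(pos[order], pos[order] + window_bases, side="right")
        n = x.shape[0]
        for rank, j in enumerate(order):
            cols = order[lo[rank] : hi[rank]]
            r = xs[:, cols].T @ xs[:, j] / n
            values[j] = (r**2) @ amat[cols]
    else:
        blocks = ref_genotypes.block_assignment
        n = x.shape[0]
        for b in np.unique(blocks):
            cols = np.flatnonzero(blocks == b)
            r = xs[:, cols].T @ xs[:, cols] / n
            values[cols] = (r**2) @ amat[cols]
    return LdScores(values, labels, list(ref_genotypes.snp_ids), window_bases)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


def _check_design_rank(design: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(design.T)
        bad = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    bad.append((labels[i], labels[j]))
        detail = f"; collinear pairs: {bad}" if bad else ""
        raise ValueError(f"rank-deficient annotation design{detail}")


def fit_sldsc(
    gwas: pd.DataFrame,
    ld: LdScores,
    annotations: dict[str, np.ndarray] | list[Annotation],
    n: float | None = None,
    n_jackknife_blocks: int = 200,
    min_maf: float | None = None,
    maf: np.ndarray | None = None,
) -> SldscFit:
    """Weighted chi2-on-LD-score regression with block-jackknife SEs.

    The design has a free intercept plus one column ``n * l(j, d)`` per
    annotation; weights follow the usual heteroskedasticity/overcounting
    style, ``1 / (l_tot * 2 * (1 + n * l_tot * h2 / p)^2)``, with h2 from a
    first unweighted pass.  Jackknife blocks are contiguous in SNP order.
    """
    if isinstance(annotations, list):
        annotations = {a.label or f"annot{i}": a.values for i, a in enumerate(annotations)}
    labels = list(annotations)
    if list(ld.labels) != labels:
        raise ValueError("LD score columns must match the annotation labels")
    z = gwas["z"].to_numpy(float)
    if n is None:
        n = float(np.median(gwas["n"]))
    keep = np.ones(len(z), dtype=bool)
    if min_maf is not None:
        maf_values = maf if maf is not None else gwas.get("maf")
        if maf_values is None:
            raise ValueError("min_maf filter requires MAF values")
        keep &= np.asarray(maf_values, float) >= min_maf
    y = (z**2)[keep]
    lmat = ld.values[keep]
    p_total = ld.values.shape[0]
    if len(y) < 2 * (len(labels) + 1):
        raise ValueError("need at least 2x more SNPs than annotations")
    amat = np.column_stack([np.asarray(annotations[k], float) for k in labels])
    design = np.column_stack([n * lmat, np.ones(len(y))])
    _check_design_rank(design[:, :-1], labels)
    l_tot = np.maximum(lmat.max(axis=1), 1.0)  # base column is the largest for nested sets
    # pass 1: crude h2 for the weights
    coef0, *_ = np.linalg.lstsq(design, y, rcond=None)
    h2_guess = float(np.clip((amat @ coef0[:-1]).sum(), 1e-6, None))
    mean_chi2 = np.maximum(1.0 + n * l_tot * h2_guess / p_total, 1.0)
    w = 1.0 / (l_tot * 2.0 * mean_chi2**2)
    # pass 2: weighted fit
    sw = np.sqrt(w)
    dw = design * sw[:, None]
    yw = y * sw
    coef, *_ = np.linalg.lstsq(dw, yw, rcond=None)
    # block jackknife over contiguous SNP blocks
    n_blocks = int(min(n_jackknife_blocks, max(2, len(y) // 10)))
    edges = np.linspace(0, len(y), n_blocks + 1).astype(int)
    k = design.shape[1]
    xtx_total = dw.T @ dw
    xty_total = dw.T @ yw
    tau_jack = np.empty((n_blocks, k))
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        xtx_b = dw[sl].T @ dw[sl]
        xty_b = dw[sl].T @ yw[sl]
        tau_jack[b] = np.linalg.solve(xtx_total - xtx_b, xty_total - xty_b)
    return SldscFit(
        labels=labels,
        tau=coef[:-1].copy(),
        intercept=float(coef[-1]),
        tau_jack=tau_jack,
        annotations=amat,
        n=n,
        p=p_total,
    )


def _summaries_at(fit: SldscFit, tau: np.ndarray, idx: int) -> tuple[float, float, float]:
    """(enrichment, tau_star, per-SNP difference) at a coefficient vector."""
    a = fit.annotations[:, idx]
    count = float(a.sum())
    var = fit.annotations @ tau
    h2 = float(var.sum())
    h2_a = float(var[a > 0].sum())
    p = fit.p
    enrich = (h2_a / h2) / (count / p)
    q = count / p
    sd_a = np.sqrt(q * (1 - q))
    tau_star = p * sd_a / h2 * tau[idx]
    diff = h2_a / count - (h2 - h2_a) / (p - count)
    return enrich, tau_star, diff


def summarize_fit(fit: SldscFit, label: str) -> EnrichmentSummary:
    """Enrichment and standardized effect size with jackknife-propagated SEs.

    The one-sided enrichment P-value tests whether the per-SNP heritability
    difference ``h2_a/|a| - (h2 - h2_a)/(p - |a|)`` exceeds zero; the tau*
    P-value is the one-sided Z test for tau* > 0.  The all-SNPs annotation has
    enrichment exactly 1 with a zero-width difference contrast.
    """
    if label not in fit.labels:
        raise ValueError(f"annotation {label!r} not in fit")
    idx = fit.labels.index(label)
    count = float(fit.annotations[:, idx].sum())
    if count == 0:
        raise ValueError("enrichment undefined for an empty annotation")
    if count == fit.p:
        tau_star, tau_star_se, tau_star_p = _tau_star_stats(fit, idx)
        return EnrichmentSummary(label, 1.0, 0.0, 1.0, tau_star, tau_star_se, tau_star_p, 0.0, 0.0)
    enrich, tau_star, diff = _summaries_at(fit, fit.tau, idx)
    reps = np.array(
        [_summaries_at(fit, fit.tau_jack[b, :-1], idx) for b in range(fit.n_blocks)]
    )
    b = fit.n_blocks
    dev = reps - reps.mean(axis=0)
    ses = np.sqrt((b - 1) / b * (dev**2).sum(axis=0))
    enrich_se, tau_star_se, diff_se = ses
    diff_p = float(stats.norm.sf(diff / diff_se)) if diff_se > 0 else float(diff <= 0)
    tau_star_p = float(stats.norm.sf(tau_star / tau_star_se)) if tau_star_se > 0 else 1.0
    return EnrichmentSummary(
        label, enrich, enrich_se, diff_p, tau_star, tau_star_se, tau_star_p, diff, diff_se
    )


def _tau_star_stats(fit: SldscFit, idx: int) -> tuple[float, float, float]:
    a = fit.annotations[:, idx]
    q = float(a.mean())
    sd_a = np.sqrt(q * (1 - q))
    h2 = fit.h2()
    tau_star = fit.p * sd_a / h2 * fit.tau[idx]
    reps = []
    for b in range(fit.n_blocks):
        tau_b = fit.tau_jack[b, :-1]
        h2_b = float((fit.annotations @ tau_b).sum())
        reps.append(fit.p * sd_a / h2_b * tau_b[idx])
    reps = np.asarray(reps)
    nb = fit.n_blocks
    se = float(np.sqrt((nb - 1) / nb * ((reps - reps.mean()) ** 2).sum()))
    p = float(stats.norm.sf(tau_star / se)) if se > 0 else 1.0
    return tau_star, se, p


# ---------------------------------------------------------------------------
# meta-analysis and concordance
# ---------------------------------------------------------------------------


def meta_random_effects(
    estimates: np.ndarray, ses: np.ndarray
) -> tuple[float, float, float]:
    """DerSimonian–Laird random-effects pooling with a one-sided P for > 0.

    A single study is returned unchanged (no heterogeneity is estimable).
    """
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if est.shape != se.shape:
        raise ValueError("estimates and SEs must have equal length")
    if (se <= 0).any():
        raise ValueError("SEs must be positive")
    if len(est) == 1:
        e, s = float(est[0]), float(se[0])
        return e, s, float(stats.norm.sf(e / s))
    with warnings.catch_warnings():
        # a negative moment estimate of tau2 makes statsmodels' internal
        # random-effects weights degenerate before we truncate below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm_meta.combine_effects(est, se**2, method_re="dl")
    if res.tau2 > 0:
        pooled = float(res.mean_effect_re)
        pooled_se = float(res.sd_eff_w_re)
    else:
        # homogeneous case: the DL moment estimate is truncated at tau2 = 0,
        # where random- and fixed-effect pooling coincide
        pooled = float(res.mean_effect_fe)
        pooled_se = float(res.sd_eff_w_fe)
    p = float(stats.norm.sf(pooled / pooled_se))
    return pooled, pooled_se, p


def _deming_objective(slope: float, x, y, vx, vy) -> tuple[float, float]:
    w = 1.0 / (vy + slope**2 * vx)
    intercept = float(np.sum(w * (y - slope * x)) / np.sum(w))
    obj = float(np.sum(w * (y - intercept - slope * x) ** 2))
    return obj, intercept


def deming_fit(
    x: np.ndarray,
    y: np.ndarray,
    se_x: np.ndarray,
    se_y: np.ndarray,
) -> tuple[float, float, float, float]:
    """Generalized Deming (errors-in-variables) regression of y on x.

    Minimizes the SE-weighted orthogonal residual sum
    ``sum (y - a - b x)^2 / (se_y^2 + b^2 se_x^2)``; with constant SEs this is
    the classic Deming estimator.  Returns (slope, intercept, slope SE,
    intercept SE) with delete-one jackknife SEs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx = np.asarray(se_x, float) ** 2
    vy = np.asarray(se_y, float) ** 2
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if (vx <= 0).any() or (vy <= 0).any():
        raise ValueError("SEs must be positive")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")

    def fit_one(xi, yi, vxi, vyi) -> tuple[float, float]:
        b0 = np.polyfit(xi, yi, 1)[0]
        res = optimize.minimize_scalar(
            lambda b: _deming_objective(b, xi, yi, vxi, vyi)[0],
            bracket=(b0 - 1.0, b0 + 1.0),
            method="brent",
            options={"xtol": 1e-12},
        )
        slope = float(res.x)
        return slope, _deming_objective(slope, xi, yi, vxi, vyi)[1]

    slope, intercept = fit_one(x, y, vx, vy)
    n = len(x)
    reps = np.empty((n, 2))
    for i in range(n):
        m = np.arange(n) != i
        reps[i] = fit_one(x[m], y[m], vx[m], vy[m])
    dev = reps - reps.mean(axis=0)
    ses = np.sqrt((n - 1) / n * (dev**2).sum(axis=0))
    return slope, intercept, float(ses[0]), float(ses[1])
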