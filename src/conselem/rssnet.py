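"""Annotation-informed spike-and-slab Bayesian model on GWAS summary statistics.

The marginal effect estimates are modeled with a summary-statistic likelihood:
given true effects beta, the estimates betahat are jointly normal with mean
``S R S^-1 beta`` and covariance ``S R S``, where S is the diagonal matrix of
standard errors and R the (block-diagonal) reference LD correlation matrix.
Each effect has the spike-and-slab prior

    beta_j ~ pi_j N(0, sigma_j^2) + (1 - pi_j) delta_0,
    pi_j = (1 + 10^-(theta0 + a_j theta))^-1,
    sigma_j^2 = sigma0^2 + a_j sigma^2,

so a binary annotation a_j raises both the association probability (through
theta) and the effect size (through sigma^2) of SNPs inside elements.
Posteriors are approximated with a fully factorized variational family fit by
coordinate ascent; hyper-parameters (theta0, theta, sigma0^2, sigma^2) are
handled by averaging over a grid with weights proportional to the
exponentiated evidence lower bounds (ELBOs).

Two read-outs summarize a fit: the enrichment Bayes factor comparing the
hyper-parameter grid with enrichment (theta > 0 or sigma^2 > 0) against the
no-enrichment baseline (theta = sigma^2 = 0), and the per-element association
probability P1 = 1 - prod_j (1 - alpha_j) that at least one SNP inside an
element is trait-associated (the product form follows from the factorized
posterior).
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from itertools import product


import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._vb import coordinate_ascent
from .annotate import Annotation
from .elements import GenomicInterval

LN10 = math.log(10.0)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# GWAS / reference harmonization
# ---------------------------------------------------------------------------


def harmonize_gwas(
    gwas: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Align GWAS summary statistics to a reference SNP table.

    Matching is by SNP id.  Alleles equal to the reference are kept; swapped
    a1/a2 flip the effect sign; strand-complement matches are resolved by
    complementing; strand-ambiguous (A/T, C/G) SNPs and SNPs whose alleles
    cannot be reconciled are dropped.  Returns the aligned table (in reference
    order) and a per-reason exclusion report.
    """
    report = {
        "matched": 0,
        "sign_flipped": 0,
        "strand_flipped": 0,
        "strand_ambiguous": 0,
        "allele_mismatch": 0,
        "not_in_reference": 0,
    }
    ref = reference.set_index("snp")
    rows = []
    for rec in gwas.itertuples(index=False):
        if rec.snp not in ref.index:
            report["not_in_reference"] += 1
            continue
        a1, a2 = str(rec.a1).upper(), str(rec.a2).upper()
        if {a1, a2} in ({"A", "T"}, {"C", "G"}):
            report["strand_ambiguous"] += 1
            continue
        r = ref.loc[rec.snp]
        r1, r2 = str(r["a1"]).upper(), str(r["a2"]).upper()
        c1, c2 = _COMPLEMENT.get(a1, "?"), _COMPLEMENT.get(a2, "?")
        if (a1, a2) == (r1, r2):
            sign, reason = 1.0, "matched"
        elif (a1, a2) == (r2, r1):
            sign, reason = -1.0, "sign_flipped"
        elif (c1, c2) == (r1, r2):
            sign, reason = 1.0, "strand_flipped"
        elif (c1, c2) == (r2, r1):
            sign, reason = -1.0, "strand_flipped"
        else:
            report["allele_mismatch"] += 1
            continue
        report[reason] += 1
        d = rec._asdict()
        d["a1"], d["a2"] = r1, r2
        d["beta"] = sign * rec.beta
        d["z"] = sign * rec.z
        rows.append(d)
    if not rows:
        raise ValueError("no GWAS SNPs could be matched to the reference")
    aligned = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(reference["snp"])}
    aligned = aligned.sort_values("snp", key=lambda s: s.map(order)).reset_index(drop=True)
    return aligned, report


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectPrior:
    """Hyper-parameters of the annotation-informed spike-and-slab prior."""

    theta0: float
    theta: float
    sigma0_sq: float
    sigma_sq: float

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be > 0")
        if self.sigma_sq < 0 or self.theta < 0:
            raise ValueError("enrichment parameters must be >= 0")

    def pi(self, a: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + 10.0 ** -(self.theta0 + np.asarray(a, float) * self.theta))

    def log_odds(self, a: np.ndarray) -> np.ndarray:
        """Natural-log prior odds of association."""
        return LN10 * (self.theta0 + np.asarray(a, float) * self.theta)

    def slab_variance(self, a: np.ndarray) -> np.ndarray:
        return self.sigma0_sq + np.asarray(a, float) * self.sigma_sq

    @property
    def is_null(self) -> bool:
        return self.theta == 0.0 and self.sigma_sq == 0.0


@dataclass
class LdStructure:
    """Block-diagonal reference LD with PSD regularization.

    Each block matrix is symmetrized, optionally shrunk toward the identity,
    and floored at a small positive eigenvalue.
    """

    matrices: list[np.ndarray]
    block_assignment: np.ndarray

    def __post_init__(self) -> None:
        self.block_assignment = np.asarray(self.block_assignment)
        sizes = [len(m) for m in self.matrices]
        counts = [np.count_nonzero(self.block_assignment == b) for b in range(len(sizes))]
        if sizes != counts:
            raise ValueError("block matrices do not match the block assignment")
        for m in self.matrices:
            if not np.allclose(np.diag(m), 1.0, atol=1e-6):
                raise ValueError("LD matrices must have unit diagonal")

    @classmethod
    def from_genotypes(
        cls, genotypes, shrinkage: float = 0.1, eig_floor: float = 1e-8
    ) -> "LdStructure":
        x = genotypes.values.astype(float)
        blocks = np.asarray(genotypes.block_assignment)
        mats = []
        for b in np.unique(blocks):
            cols = np.flatnonzero(blocks == b)
            sub = x[:, cols]
            sd = sub.std(axis=0)
            if (sd == 0).any():
                raise ValueError("monomorphic SNP in LD reference")
            r = np.corrcoef(sub, rowvar=False)
            if r.ndim == 0:
                r = np.array([[1.0]])
            mats.append(regularize_ld(r, shrinkage, eig_floor))
        return cls(mats, blocks)

    @property
    def n_snps(self) -> int:
        return len(self.block_assignment)


def regularize_ld(r: np.ndarray, shrinkage: float = 0.1, eig_floor: float = 1e-8) -> np.ndarray:
    """Symmetrize, shrink toward identity, and floor eigenvalues."""
    r = 0.5 * (r + r.T)
    if shrinkage > 0:
        r = (1.0 - shrinkage) * r + shrinkage * np.eye(len(r))
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValueError("LD matrix is not PSD after regularization")
    if w.min() < eig_floor:
        w = np.maximum(w, eig_floor)
        r = (v * w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


@dataclass
class VariationalSolution:
    alpha: np.ndarray
    mu: np.ndarray  # conditional (slab) posterior means
    elbo: float
    elbo_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class GridConfig:
    """Hyper-parameter grid with uniform hyper-prior weights."""

    theta0: tuple[float, ...] = (-4.0, -3.25, -2.5, -1.75, -1.0)
    theta: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    sigma0_sq: tuple[float, ...] = ()
    sigma_sq: tuple[float, ...] = ()

    def points(self) -> list[EffectPrior]:
        return [
            EffectPrior(t0, t, s0, s)
            for t0, t, s0, s in product(self.theta0, self.theta, self.sigma0_sq, self.sigma_sq)
        ]

    def null_grid(self) -> "GridConfig":
        """The theta = sigma^2 = 0 sub-grid (the no-enrichment baseline)."""
        return GridConfig(self.theta0, (0.0,), self.sigma0_sq, (0.0,))

    @classmethod
    def default(cls, se: np.ndarray, n_sigma0: int = 4, n_sigma: int = 4) -> "GridConfig":
        """Slab variances scaled to the per-SNP sampling variance.

        A causal SNP with slab variance k * median(se^2) boosts its expected
        chi-square by about k, so the geometric ladder below spans weak to
        strong per-SNP signals.
        """
        unit = float(np.median(np.asarray(se) ** 2))
        s0 = tuple(unit * 4.0**i for i in range(1, n_sigma0 + 1))
        s = (0.0,) + tuple(unit * 4.0**i for i in range(1, n_sigma))
        return cls(sigma0_sq=s0, sigma_sq=s)


@dataclass
class RssNetFit:
    """Grid of variational solutions with ELBO-based model averaging."""

    mode: str
    priors: list[EffectPrior]
    solutions: list[VariationalSolution]
    annotation: np.ndarray
    snp_ids: list[str]
    data_digest: str

    def __post_init__(self) -> None:
        elbos = np.array([s.elbo for s in self.solutions])
        w = np.exp(elbos - elbos.max())
        self.weights = w / w.sum()
        self.elbos = elbos

    @property
    def alpha(self) -> np.ndarray:
        """Grid-averaged per-SNP inclusion probabilities."""
        stacked = np.stack([s.alpha for s in self.solutions])
        return self.weights @ stacked

    def log_marginal(self, subset: str = "all") -> float:
        """Hyper-prior-averaged ELBO approximation to the log marginal likelihood.

        ``subset`` selects "all", "enriched" (theta > 0 or sigma^2 > 0) or
        "null" grid points.
        """
        mask = np.ones(len(self.priors), dtype=bool)
        if subset == "enriched":
            mask = np.array([not p.is_null for p in self.priors])
        elif subset == "null":
            mask = np.array([p.is_null for p in self.priors])
        if not mask.any():
            raise ValueError(f"no {subset} grid points in this fit")
        sel = self.elbos[mask]
        return float(logsumexp(sel) - math.log(len(sel)))


# ---------------------------------------------------------------------------
# variational inference
# ---------------------------------------------------------------------------


def _flatten_blocks(ld: LdStructure, se: np.ndarray):
    blocks = ld.block_assignment
    order_blocks = np.unique(blocks)
    s_off = np.zeros(len(order_blocks) + 1, dtype=np.int64)
    perm = []
    flat_parts = []
    a_off = np.zeros(len(order_blocks), dtype=np.int64)
    pos = 0
    for k, b in enumerate(order_blocks):
        cols = np.flatnonzero(blocks == b)
        perm.append(cols)
        s_off[k + 1] = s_off[k] + len(cols)
        a_off[k] = pos
        sub_se = se[cols]
        a = ld.matrices[k] / np.outer(sub_se, sub_se)
        flat_parts.append(a.ravel())
        pos += len(cols) ** 2
    perm = np.concatenate(perm)
    a_flat = np.concatenate(flat_parts)
    return a_flat, a_off, s_off, perm


def variational_fit(
    gwas: pd.DataFrame,
    ld: LdStructure,
    prior: EffectPrior,
    annotation: np.ndarray | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    _prepared=None,
) -> VariationalSolution:
    """Coordinate-ascent fit of the factorized spike-and-slab family.

    Deterministic given the initialization; SNPs are updated in order of
    decreasing |z| within each LD block.  The returned ELBO omits additive
    constants that do not depend on the hyper-parameters, so ELBOs are
    comparable across grid points and models on identical data.
    Non-convergence within ``max_iter`` sweeps is flagged, not raised.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    betahat = gwas["beta"].to_numpy(float)
    se = gwas["se"].to_numpy(float)
    if len(betahat) != ld.n_snps:
        raise ValueError("GWAS SNPs must match the LD structure")
    if _prepared is None:
        _prepared = _flatten_blocks(ld, se)
    a_flat, a_off, s_off, perm = _prepared
    b = (betahat / se**2)[perm]
    d = a_flat[
        np.concatenate(
            [a_off[k] + np.arange(s_off[k + 1] - s_off[k]) * ((s_off[k + 1] - s_off[k]) + 1)
             for k in range(len(a_off))]
        )
    ]  # diagonal of D^-1 R D^-1 in permuted order
    z = np.abs(gwas["z"].to_numpy(float))[perm]
    if annotation is None:
        if "_annotation" in gwas:
            annotation = gwas["_annotation"].to_numpy(float)
        else:
            annotation = np.zeros(len(b))
    else:
        annotation = np.asarray(getattr(annotation, "values", annotation), float)
    logodds = prior.log_odds(annotation)[perm]
    s2 = prior.slab_variance(annotation)[perm]
    p = len(b)
    # within-block update order: descending |z|
    order = np.empty(p, dtype=np.int64)
    for k in range(len(s_off) - 1):
        sl = slice(s_off[k], s_off[k + 1])
        local = np.argsort(-z[sl], kind="mergesort") + s_off[k]
        order[sl] = local
    if init is None:
        alpha = 1.0 / (1.0 + np.exp(-logodds))
        mu = np.zeros(p)
    else:
        alpha = init[0][perm].astype(float).copy()
        mu = init[1][perm].astype(float).copy()
    trace, n_iter = coordinate_ascent(
        a_flat, a_off, s_off, b, d, logodds, s2, order, alpha, mu, tol, max_iter
    )
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    converged = n_iter < max_iter or (
        len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-1]))
    )
    if not converged:
        warnings.warn("variational fit did not converge within max_iter")
    return VariationalSolution(
        alpha=alpha[inv],
        mu=mu[inv],
        elbo=float(trace[-1]),
        elbo_trace=trace.copy(),
        n_iter=int(n_iter),
        converged=bool(converged),
    )


_INIT_STRATEGIES = ("prior", "marginal", "half")


def _initializations(gwas, prior, annotation, n_restarts):
    betahat = gwas["beta"].to_numpy(float)
    se = gwas["se"].to_numpy(float)
    p = len(betahat)
    s2 = prior.slab_variance(annotation)
    inits: list[tuple[np.ndarray, np.ndarray] | None] = [None]  # prior init
    if n_restarts >= 2:
        # marginal single-SNP posteriors ignoring LD
        v = 1.0 / (1.0 / se**2 + 1.0 / s2)
        mu = v * betahat / se**2
        lo = prior.log_odds(annotation) + 0.5 * np.log(v / s2) + 0.5 * mu**2 / v
        alpha = 1.0 / (1.0 + np.exp(-np.clip(lo, -500, 500)))
        inits.append((alpha, mu))
    if n_restarts >= 3:
        inits.append((np.full(p, 0.5), np.zeros(p)))
    return inits[:n_restarts]


def fit_model(
    gwas: pd.DataFrame,
    ld: LdStructure,
    annotation: Annotation | np.ndarray | None,
    grid: GridConfig | None = None,
    mode: str = "H",
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 3,
    warm_start: bool = True,
) -> RssNetFit:
    """Fit the model over a hyper-parameter grid and average by ELBO weight.

    ``mode`` records which annotation definition is in use: "H" (conserved
    elements), "N" (all elements), or "B" (baseline; the annotation is forced
    to zero and the grid collapses to theta = sigma^2 = 0).  An all-zero
    annotation in modes N/H triggers a warning and behaves exactly like B.
    """
    if mode not in ("B", "N", "H"):
        raise ValueError("mode must be one of 'B', 'N', 'H'")
    p = len(gwas)
    if mode == "B" or annotation is None:
        a = np.zeros(p)
        mode_grid_null = True
    else:
        a = np.asarray(getattr(annotation, "values", annotation), float)
        if len(a) != p:
            raise ValueError("annotation length must match the GWAS table")
        mode_grid_null = False
        if a.sum() == 0:
            warnings.warn(
                "annotation has no SNPs with a_j = 1; enrichment parameters are "
                "unidentifiable and the fit collapses to the baseline model"
            )
            mode_grid_null = True
    if grid is None:
        grid = GridConfig.default(gwas["se"].to_numpy(float))
    if mode_grid_null:
        grid = grid.null_grid()
    priors = grid.points()
    work = gwas.copy()
    work["_annotation"] = a
    se = work["se"].to_numpy(float)
    prepared = _flatten_blocks(ld, se)
    solutions: list[VariationalSolution] = []
    prev: tuple[np.ndarray, np.ndarray] | None = None
    for prior in priors:
        cands: list[VariationalSolution] = []
        inits = _initializations(work, prior, a, n_restarts)
        if warm_start and prev is not None:
            inits = [prev] + inits
        for init in inits:
            sol = variational_fit(
                work, ld, prior, init=init, tol=tol, max_iter=max_iter, _prepared=prepared
            )
            cands.append(sol)
        best = max(cands, key=lambda s: s.elbo)
        solutions.append(best)
        prev = (best.alpha, best.mu)
    digest = hashlib.sha256(
        np.ascontiguousarray(work[["beta", "se"]].to_numpy(float)).tobytes()
    ).hexdigest()
    return RssNetFit(
        mode=mode,
        priors=priors,
        solutions=solutions,
        annotation=a,
        snp_ids=list(gwas["snp"]),
        data_digest=digest,
    )


def bayes_factor(fit_enriched: RssNetFit, fit_baseline: RssNetFit) -> float:
    """Enrichment Bayes factor from ELBO-approximated marginal likelihoods.

    Ratio of the hyper-prior-averaged evidence of the enrichment fit's grid to
    the theta = sigma^2 = 0 baseline fit.  Both fits must be on identical
    harmonized data.  When the enrichment grid degenerates to the null point
    the ratio is exactly 1.
    """
    if fit_enriched.data_digest != fit_baseline.data_digest:
        raise ValueError("Bayes factor requires fits on identical data")
    log_num = fit_enriched.log_marginal("all")
    log_den = fit_baseline.log_marginal("all")
    return float(np.exp(log_num - log_den))


def element_p1(
    fit: RssNetFit, element: GenomicInterval, snps: pd.DataFrame
) -> float:
    """P1: posterior probability that >= 1 SNP in the element is associated.

    Computed per grid point from the factorized posterior as
    ``1 - prod_j (1 - alpha_j)`` over the element's SNPs, then averaged with
    the fit's ELBO weights.
    """
    mask = (
        (snps["chrom"].to_numpy() == element.chrom)
        & (snps["pos"].to_numpy() >= element.start)
        & (snps["pos"].to_numpy() < element.end)
    )
    if not mask.any():
        raise ValueError("element contains no SNPs present in the fit")
    return float(_p1_for_mask(fit, mask))


def _p1_for_mask(fit: RssNetFit, mask: np.ndarray) -> float:
    p1s = np.array(
        [1.0 - np.prod(1.0 - s.alpha[mask]) for s in fit.solutions]
    )
    return float(fit.weights @ p1s)


def elements_p1(
    fit: RssNetFit, elements: pd.DataFrame, snps: pd.DataFrame
) -> np.ndarray:
    """Vectorized P1 for a frame of elements; NaN where an element has no SNPs."""
    chroms = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    out = np.full(len(elements), np.nan)
    for i, rec in enumerate(elements.itertuples(index=False)):
        mask = (chroms == rec.chrom) & (pos >= rec.start) & (pos < rec.end)
        if mask.any():
            out[i] = _p1_for_mask(fit, mask)
    return out
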