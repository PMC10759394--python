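"""Desk-scale simulation harness validating element-level association calls.

The harness mirrors the model-validation design: matched "positive" datasets
(SNP effects drawn from the spike-and-slab prior WITH enrichment of annotated
SNPs) and "negative" datasets (same prior with theta = sigma^2 = 0), matched
on the proportion of trait-associated SNPs and on the phenotypic variance
explained.  Elements are called trait-associated at ``P1_H >= 0.9`` and each
call is labelled true/false by whether the element contains a SNP with a
nonzero simulated effect; the harness reports the empirical per-element false
positive rate on negative datasets and the empirical false discovery rate
across all calls.

Default sizes are desk-scale: 2,000 SNPs in 20 AR(1) LD blocks, 1,458
individuals (the reference-panel size the real analysis emulates), 100
two-SNP elements (10% of SNPs annotated), and 4 scenarios crossing the
proportion of trait-associated SNPs {0.005, 0.02} with the SNP-explained
variance fraction {0.2, 0.5}; positives use theta = 2 (log10-odds) together
with a doubled slab variance for annotated SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elements import intervals_frame
from .rssnet import GridConfig, LdStructure, fit_model, elements_p1
from .synthdata import (
    GenotypeMatrix,
    SimulationScenario,
    matched_negative,
    simulate_effects,
    simulate_genotypes,
    simulate_gwas,
    solve_theta0,
)


def default_scenarios(seed: int = 0) -> list[SimulationScenario]:
    """The 4 positive scenarios: prop_causal x pve grid with enrichment."""
    out = []
    for prop_causal in (0.005, 0.02):
        for pve in (0.2, 0.5):
            theta = 2.0
            out.append(
                SimulationScenario(
                    n_snps=2000,
                    n_individuals=1458,
                    frac_annotated=0.10,
                    prop_causal=prop_causal,
                    pve=pve,
                    theta0=solve_theta0(prop_causal, theta, 0.10),
                    theta=theta,
                    sigma0_sq=1.0,
                    sigma_sq=1.0,
                    seed=seed,
                )
            )
    return out


def harness_grid(se: np.ndarray) -> GridConfig:
    """Reduced hyper-parameter grid used by the desk-scale harness.

    3 x 3 x 3 x 2 = 54 points spanning baseline log10-odds around the
    simulated causal fractions, enrichments up to theta = 3, and slab
    variances from weak to strong per-SNP signals (in units of the median
    squared SE).
    """
    unit = float(np.median(np.asarray(se) ** 2))
    return GridConfig(
        theta0=(-3.0, -2.25, -1.5),
        theta=(0.0, 1.5, 3.0),
        sigma0_sq=tuple(unit * k for k in (8.0, 32.0, 128.0)),
        sigma_sq=(0.0, unit * 32.0),
    )


@dataclass
class HarnessConfig:
    n_datasets: int = 50  # positive datasets per scenario (matched negatives added)
    n_elements: int = 100
    snps_per_element: int = 2
    rho: float = 0.5
    block_size: int = 100
    p1_cutoff: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    tol: float = 1e-6
    max_iter: int = 200
    scenarios: list[SimulationScenario] = field(default_factory=default_scenarios)


@dataclass
class HarnessResult:
    calls: pd.DataFrame  # one row per called element
    n_null_negative_elements: int
    n_false_on_negative: int
    per_scenario: pd.DataFrame

    @property
    def fpr(self) -> float:
        """False positive rate: called null elements / null elements, on
        negative datasets only."""
        if self.n_null_negative_elements == 0:
            return float("nan")
        return self.n_false_on_negative / self.n_null_negative_elements

    @property
    def fdr(self) -> float:
        """False fraction among all calls across positive and negative data."""
        if len(self.calls) == 0:
            return 0.0
        return float((~self.calls["true_call"]).mean())


def build_elements(
    genotypes: GenotypeMatrix, n_elements: int, snps_per_element: int, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Place disjoint elements over runs of consecutive SNPs.

    Returns the element frame and the element index (-1 outside) per SNP.
    """
    rng = np.random.default_rng(seed)
    p = genotypes.n_snps
    run = snps_per_element
    n_slots = p // run
    if n_elements > n_slots:
        raise ValueError("too many elements for the SNP count")
    slots = np.sort(rng.choice(n_slots, size=n_elements, replace=False))
    pos = np.asarray(genotypes.positions)
    element_of = np.full(p, -1, dtype=np.int64)
    rows = []
    for e, s in enumerate(slots):
        j0, j1 = s * run, s * run + run - 1
        element_of[j0 : j1 + 1] = e
        rows.append((genotypes.chrom, int(pos[j0]) - 1, int(pos[j1]) + 1))
    elements = intervals_frame(rows)
    return elements, element_of


def run_harness(
    config: HarnessConfig | None = None, seed: int = 0, grid: GridConfig | None = None
) -> HarnessResult:
    """Run the full positive/negative validation harness.

    One genotype matrix (and hence one LD structure) is shared by all
    datasets, as in reference-panel-based designs; effects, phenotypes, and
    summary statistics are redrawn per dataset from per-dataset seeds.
    """
    if config is None:
        config = HarnessConfig()
    root = np.random.SeedSequence(seed)
    base = config.scenarios[0]
    geno = simulate_genotypes(
        SimulationScenario(
            n_snps=base.n_snps,
            n_individuals=base.n_individuals,
            frac_annotated=base.frac_annotated,
            prop_causal=base.prop_causal,
            pve=base.pve,
            theta0=base.theta0,
            theta=base.theta,
            sigma0_sq=base.sigma0_sq,
            sigma_sq=base.sigma_sq,
            seed=int(root.generate_state(1)[0] % (2**31)),
        ),
        maf_dist=config.maf_range,
        rho=config.rho,
        block_size=config.block_size,
    )
    ld = LdStructure.from_genotypes(geno)
    elements, element_of = build_elements(
        geno,
        config.n_elements,
        config.snps_per_element,
        int(root.generate_state(2)[1] % (2**31)),
    )
    annotation = (element_of >= 0).astype(np.int8)
    snps = geno.snp_table()
    records = []
    scen_rows = []
    n_null_neg = 0
    n_false_neg = 0
    for si, scenario in enumerate(config.scenarios):
        for kind in ("positive", "negative"):
            scen = scenario if kind == "positive" else matched_negative(scenario)
            n_calls = n_true = 0
            for d in range(config.n_datasets):
                sub_seed = int(
                    np.random.SeedSequence([seed, si, d, 0 if kind == "positive" else 1])
                    .generate_state(1)[0]
                    % (2**31)
                )
                beta = simulate_effects(
                    annotation, scen.theta0, scen.theta, scen.sigma0_sq, scen.sigma_sq, sub_seed
                )
                attempt = 1
                while not beta.any():  # pve cannot be scaled on an all-null draw
                    beta = simulate_effects(
                        annotation,
                        scen.theta0,
                        scen.theta,
                        scen.sigma0_sq,
                        scen.sigma_sq,
                        sub_seed + 10_000_019 * attempt,
                    )
                    attempt += 1
                gwas = simulate_gwas(geno, beta, scen.pve, seed=sub_seed)
                use_grid = grid if grid is not None else harness_grid(gwas["se"].to_numpy())
                fit = fit_model(
                    gwas,
                    ld,
                    annotation,
                    grid=use_grid,
                    mode="H",
                    tol=config.tol,
                    max_iter=config.max_iter,
                    n_restarts=1,
                    warm_start=True,
                )
                p1 = elements_p1(fit, elements, snps)
                causal_elem = np.zeros(len(elements), dtype=bool)
                hit = element_of[(beta != 0) & (element_of >= 0)]
                causal_elem[np.unique(hit)] = True
                called = p1 >= config.p1_cutoff
                if kind == "negative":
                    n_null_neg += int((~causal_elem).sum())
                    n_false_neg += int((called & ~causal_elem).sum())
                for e in np.flatnonzero(called):
                    records.append(
                        {
                            "scenario": si,
                            "kind": kind,
                            "dataset": d,
                            "element": int(e),
                            "p1": float(p1[e]),
                            "true_call": bool(causal_elem[e]),
                        }
                    )
                n_calls += int(called.sum())
                n_true += int((called & causal_elem).sum())
            scen_rows.append(
                {
                    "scenario": si,
                    "kind": kind,
                    "prop_causal": scen.prop_causal,
                    "pve": scen.pve,
                    "theta": scen.theta,
                    "sigma_sq": scen.sigma_sq,
                    "n_datasets": config.n_datasets,
                    "n_calls": n_calls,
                    "n_true_calls": n_true,
                }
            )
    calls = pd.DataFrame(
        records,
        columns=["scenario", "kind", "dataset", "element", "p1", "true_call"],
    )
    return HarnessResult(
        calls=calls,
        n_null_negative_elements=n_null_neg,
        n_false_on_negative=n_false_neg,
        per_scenario=pd.DataFrame(scen_rows),
    )
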