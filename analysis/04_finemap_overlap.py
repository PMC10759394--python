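"""Overlap of fine-mapped variants with conserved elements across PIP cutoffs.

Simulates PIP tables for two fine-mapping methods with threefold enrichment
of high-PIP variants inside the conserved-element annotation, computes the
per-threshold fractions and enrichments, and tests each with the one-sided
exact binomial test.

Writes results/finemap_overlap.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from conselem.finemap import pip_overlap_by_method
from conselem.synthdata import simulate_pips

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(17)
    n = 20_000
    snps = pd.DataFrame(
        {"snp": [f"rs{i}" for i in range(n)], "chrom": "chr1",
         "pos": np.arange(n) * 150, "a1": "A", "a2": "G",
         "maf": rng.uniform(0.05, 0.5, n)}
    )
    annotation = (rng.random(n) < 0.08).astype(np.int8)
    tables = [
        simulate_pips(snps, annotation, enrich_ratio=3.0, seed=21, method="susie"),
        simulate_pips(snps, annotation, enrich_ratio=3.0, seed=22, method="finemap"),
    ]
    table = pd.concat(tables, ignore_index=True)
    ann2 = np.concatenate([annotation, annotation])
    res = pip_overlap_by_method(table, ann2, thresholds=(0.0, 0.1, 0.25, 0.5))
    res.to_csv(RESULTS / "finemap_overlap.tsv", sep="\t", index=False)
    print(res.to_string(index=False))
    t01 = res[res["threshold"] == 0.1]
    print(
        "\nat PIP >= 0.1 the annotated fraction exceeds the genome-wide fraction "
        f"by {t01['diff'].mean():.3f} on average (both methods, one-sided binomial "
        f"P <= {t01['p'].max():.2e})"
    )


if __name__ == "__main__":
    main()
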