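"""Build per-SNP annotations from omnibus elements and quantify correlations.

Reads the omnibus BED files produced by 01_build_elements.py, annotates a
simulated common-SNP table against each conservation class, verifies the
omnibus/max identity on the per-context sets, and reports pairwise Cramér's V
between the class annotations.

Writes results/snp_annotations.tsv and results/annotation_correlations.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from conselem import annotate_snps, combine_max, correlate_annotations, intersect_peaks
from conselem.io import read_bed, write_annotation_tsv
from conselem.synthdata import simulate_context_peaks

RESULTS = Path(__file__).resolve().parents[1] / "results"
GENOME = {"chr1": 2_000_000, "chr2": 1_500_000}


def main() -> None:
    rng = np.random.default_rng(7)
    snps = []
    for chrom, size in GENOME.items():
        pos = np.sort(rng.choice(size, size=size // 400, replace=False))
        snps.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    snps = pd.concat(snps, ignore_index=True)
    snps.insert(0, "snp", [f"rs{i}" for i in range(len(snps))])
    snps["a1"], snps["a2"] = "A", "G"
    snps["maf"] = rng.uniform(0.05, 0.5, len(snps))

    annotations = {}
    for name in ("NC", "LC", "MC", "HC"):
        elements = read_bed(RESULTS / f"omnibus_{name}.bed")
        annotations[name] = annotate_snps(snps, elements)
        print(
            f"{name}: |a| = {annotations[name].n_annotated} SNPs "
            f"({100 * annotations[name].proportion:.1f}%), SD_a = {annotations[name].sd:.3f}"
        )
    write_annotation_tsv(snps, {k: a.values for k, a in annotations.items()},
                         RESULTS / "snp_annotations.tsv")

    # omnibus identity on freshly simulated per-context element sets
    contexts = []
    for i in range(3):
        h3k, acc = simulate_context_peaks(GENOME, 800, overlap_frac=0.5, seed=300 + i)
        contexts.append(intersect_peaks(h3k, acc, context=f"ctx{i}"))
    from conselem import merge_omnibus

    direct = annotate_snps(snps, merge_omnibus(contexts))
    combined = combine_max([annotate_snps(snps, c) for c in contexts])
    assert np.array_equal(direct.values, combined.values)
    print("omnibus annotation equals the elementwise max over contexts (exact)")

    rows = []
    names = list(annotations)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            v = correlate_annotations(annotations[x], annotations[y])
            rows.append({"a": x, "b": y, "cramers_v": v.value})
    corr = pd.DataFrame(rows)
    corr.to_csv(RESULTS / "annotation_correlations.tsv", sep="\t", index=False)
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main()
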