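"""Per-SNP binary annotations from element sets, and annotation correlations.

A SNP annotation is the indicator ``a(j) = 1{SNP j falls inside at least one
element of the set}``.  Because an omnibus element set is the merged union of
context-specific sets, its annotation equals the elementwise maximum of the
per-context annotations — a structural identity the test suite checks exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .elements import ElementSet, merge_intervals, _as_interval_frame


@dataclass
class Annotation:
    """A 0/1 vector aligned to a SNP table, with its summary statistics."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("annotation values must be binary (0/1)")
        self.values = v.astype(np.int8)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_annotated(self) -> int:
        """|a|: number of SNPs inside the element set."""
        return int(self.values.sum())

    @property
    def proportion(self) -> float:
        return self.n_annotated / len(self.values)

    @property
    def sd(self) -> float:
        """Population standard deviation, sqrt(q(1-q)) with q = |a|/p."""
        q = self.proportion
        return float(np.sqrt(q * (1.0 - q)))


class CorrelationResult(NamedTuple):
    value: float
    kind: str  # "cramers_v" or "pearson_r"


def annotate_snps(snps: pd.DataFrame, elements) -> Annotation:
    """Mark SNPs falling inside at least one element (half-open intervals).

    A SNP exactly at an element's ``end`` coordinate is outside.
    """
    merged = merge_intervals(_as_interval_frame(elements))
    values = np.zeros(len(snps), dtype=np.int8)
    by_chrom = dict(tuple(merged.groupby("chrom", sort=False)))
    positions = snps["pos"].to_numpy(np.int64)
    chroms = snps["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        mask = chroms == chrom
        pos = positions[mask]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        values[np.flatnonzero(mask)[inside]] = 1
    label = elements.context if isinstance(elements, ElementSet) else ""
    if isinstance(elements, ElementSet):
        label = f"{elements.context}:{elements.conservation_class}" if label else elements.conservation_class
    return Annotation(values, label=label)


def combine_max(annotations: list[Annotation], label: str = "omnibus") -> Annotation:
    """Elementwise maximum over per-context annotations (the omnibus identity)."""
    if not annotations:
        raise ValueError("need at least one annotation")
    stacked = np.stack([a.values for a in annotations])
    return Annotation(stacked.max(axis=0), label=label)


def correlate_annotations(x: Annotation, y) -> CorrelationResult:
    """Correlate a binary annotation with a binary or quantitative covariate.

    Binary–binary pairs give Cramér's V computed as sqrt(chi2 / n) from the
    2x2 contingency table without bias correction; binary–quantitative pairs
    give Pearson's R.  Constant vectors have no defined correlation.
    """
    xv = np.asarray(x.values if isinstance(x, Annotation) else x)
    yv = np.asarray(y.values if isinstance(y, Annotation) else y)
    if len(xv) != len(yv):
        raise ValueError("annotations must have equal length")
    if not np.isin(xv, (0, 1)).all():
        raise ValueError("x must be binary")
    if xv.min() == xv.max():
        raise ValueError("undefined correlation: x is constant")
    y_binary = np.isin(yv, (0, 1)).all()
    if y_binary:
        if yv.min() == yv.max():
            raise ValueError("undefined correlation: y is constant")
        table = np.zeros((2, 2))
        for i in (0, 1):
            for j in (0, 1):
                table[i, j] = np.count_nonzero((xv == i) & (yv == j))
        chi2 = stats.chi2_contingency(table, correction=False).statistic
        return CorrelationResult(float(np.sqrt(chi2 / len(xv))), "cramers_v")
    if np.std(yv) == 0:
        raise ValueError("undefined correlation: y is constant")
    r = stats.pearsonr(xv.astype(float), yv.astype(float)).statistic
    return CorrelationResult(float(r), "pearson_r")
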