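"""Overlap of fine-mapped variants with element annotations.

For a table of per-variant posterior inclusion probabilities (PIPs) and a
binary annotation, computes — per PIP threshold — the fraction of annotated
variants passing the threshold, the genome-wide fraction, and their
difference/ratio, with a one-sided exact binomial test for enrichment.
Thresholds are inclusive (``PIP >= t``).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import Annotation


def binomial_enrichment_test(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float(stats.binom.sf(k - 1, n, p0))


def pip_overlap_fractions(
    table: pd.DataFrame,
    annotation: Annotation | np.ndarray,
    thresholds: Sequence[float] = (0.0, 0.1, 0.25, 0.5),
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-threshold overlap fractions and enrichment of fine-mapped variants.

    Rows of ``table`` must align with ``annotation``; when several fine-mapping
    methods are present the table should be filtered to one method first (the
    caller-facing wrapper below keeps methods separate).  Returns one row per
    threshold with columns ``threshold, f_in, f_all, diff, ratio, p``.
    """
    a = np.asarray(getattr(annotation, "values", annotation)).astype(bool)
    if len(a) != len(table):
        raise ValueError("annotation length must match the PIP table")
    if a.sum() == 0:
        raise ValueError("undefined fractions: zero annotated variants")
    pip = table["pip"].to_numpy(float)
    if ((pip < 0) | (pip > 1)).any():
        raise ValueError("PIPs must lie in [0, 1]")
    thresholds = np.asarray(thresholds, float)
    if ((thresholds < 0) | (thresholds > 1)).any():
        raise ValueError("thresholds must lie in [0, 1]")
    rows = []
    n_ann = int(a.sum())
    n_all = len(pip)
    for t in thresholds:
        passing = pip >= t if inclusive else pip > t
        k = int((passing & a).sum())
        f_in = k / n_ann
        f_all = int(passing.sum()) / n_all
        if 0 < f_all < 1:
            p = binomial_enrichment_test(k, n_ann, f_all)
        else:
            p = np.nan
        rows.append(
            {
                "threshold": float(t),
                "f_in": f_in,
                "f_all": f_all,
                "diff": f_in - f_all,
                "ratio": f_in / f_all if f_all > 0 else np.inf,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def pip_overlap_by_method(
    table: pd.DataFrame,
    annotation: Annotation | np.ndarray,
    thresholds: Sequence[float] = (0.0, 0.1, 0.25, 0.5),
    qc_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Overlap statistics computed separately per fine-mapping method.

    ``qc_columns`` name boolean columns of precomputed quality-control flags
    (credible-set membership and LD-based exclusions); rows where any flag is
    False are dropped before the overlap computation.
    """
    a = np.asarray(getattr(annotation, "values", annotation))
    df = table.reset_index(drop=True)
    keep = np.ones(len(df), dtype=bool)
    for col in qc_columns:
        keep &= df[col].to_numpy(bool)
    out = []
    for method, grp in df[keep].groupby("method", sort=True):
        res = pip_overlap_fractions(grp, a[grp.index.to_numpy()], thresholds)
        res.insert(0, "method", method)
        out.append(res)
    return pd.concat(out, ignore_index=True)
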