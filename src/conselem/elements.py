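"""Enhancer-like elements (ELEs) and cross-species sequence conservation.

An enhancer-like element is a genomic interval carrying both an H3K27ac peak
and an accessible-chromatin peak in the same tissue/cell context.  Elements
are classified by how much of their sequence lies inside gapless alignment
blocks of a second genome: the minimum covered fraction ("minMatch") defines
nested conservation classes

    NC (all elements)  ⊇  LC (≥ 0.1)  ⊇  MC (≥ 0.5)  ⊇  HC (≥ 0.9).

All coordinates are 0-based, half-open (BED convention).  Interval sets are
stored as sorted ``pandas.DataFrame`` objects with columns
``chrom, start, end`` (plus optional extras such as ``conservation_fraction``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

CONSERVATION_CLASSES = ("NC", "LC", "MC", "HC")
DEFAULT_CONSERVATION_LEVELS = {"LC": 0.1, "MC": 0.5, "HC": 0.9}

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class GenomicInterval(NamedTuple):
    """A half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int


def intervals_frame(records: Iterable[tuple[str, int, int]] | pd.DataFrame) -> pd.DataFrame:
    """Build a validated, sorted interval frame from (chrom, start, end) records."""
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, INTERVAL_COLUMNS].copy()
    else:
        df = pd.DataFrame(list(records), columns=INTERVAL_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if len(df):
        if (df["start"] < 0).any():
            raise ValueError("interval start must be >= 0")
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        if (df["chrom"].astype(str).str.len() == 0).any():
            raise ValueError("chromosome names must be non-empty")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


@dataclass
class ElementSet:
    """A sorted set of elements from one context at one conservation class.

    ``intervals`` may carry a ``conservation_fraction`` column once the set has
    been scored against alignment blocks.
    """

    intervals: pd.DataFrame
    context: str = ""
    conservation_class: str = "NC"
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.conservation_class not in CONSERVATION_CLASSES:
            raise ValueError(f"unknown conservation class {self.conservation_class!r}")
        extras = [c for c in self.intervals.columns if c not in INTERVAL_COLUMNS]
        base = intervals_frame(self.intervals)
        if extras:
            srt = self.intervals.sort_values(
                ["chrom", "start", "end"], kind="mergesort"
            ).reset_index(drop=True)
            for c in extras:
                base[c] = srt[c].to_numpy()
        self.intervals = base

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_bases(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


@dataclass
class AlignmentBlockSet:
    """Gapless alignment blocks between a source and a target assembly.

    Each block pairs a source interval with a target interval of identical
    length; source blocks are pairwise non-overlapping.
    """

    blocks: pd.DataFrame  # chrom, start, end, target_chrom, target_start, target_end
    source_assembly: str = ""
    target_assembly: str = ""

    def __post_init__(self) -> None:
        df = self.blocks.copy()
        for c in ("start", "end", "target_start", "target_end"):
            df[c] = df[c].astype(np.int64)
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if len(df):
            src_len = df["end"] - df["start"]
            tgt_len = df["target_end"] - df["target_start"]
            if (src_len <= 0).any():
                raise ValueError("blocks must have positive length")
            if not (src_len == tgt_len).all():
                raise ValueError("gapless blocks require equal source/target lengths")
            overlap = (
                df.groupby("chrom")["start"].shift(-1) < df["end"]
            ) & df["chrom"].eq(df.groupby("chrom")["chrom"].shift(-1))
            if overlap.fillna(False).any():
                raise ValueError("source blocks must be pairwise non-overlapping")
        self.blocks = df

    def __len__(self) -> int:
        return len(self.blocks)

    def source_intervals(self) -> pd.DataFrame:
        return self.blocks.loc[:, INTERVAL_COLUMNS].copy()


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------


def merge_intervals(df: pd.DataFrame, merge_bookended: bool = True) -> pd.DataFrame:
    """Merge overlapping (and, by default, bookended) intervals per chromosome."""
    df = intervals_frame(df)
    if not len(df):
        return df
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cummax_end = np.maximum.accumulate(ends)
        prev_end = np.empty_like(cummax_end)
        prev_end[0] = np.iinfo(np.int64).min
        prev_end[1:] = cummax_end[:-1]
        if merge_bookended:
            new_run = starts > prev_end
        else:
            new_run = starts >= prev_end
        run_id = np.cumsum(new_run) - 1
        n_runs = run_id[-1] + 1
        run_start = np.full(n_runs, np.iinfo(np.int64).max)
        run_end = np.zeros(n_runs, dtype=np.int64)
        np.minimum.at(run_start, run_id, starts)
        np.maximum.at(run_end, run_id, ends)
        out.append(pd.DataFrame({"chrom": chrom, "start": run_start, "end": run_end}))
    return pd.concat(out, ignore_index=True)


def _intersect_merged(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Base-level intersection of two already-merged interval frames."""
    pieces = []
    b_by_chrom = dict(tuple(b.groupby("chrom", sort=False)))
    for chrom, ga in a.groupby("chrom", sort=True):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        a_start = ga["start"].to_numpy()
        a_end = ga["end"].to_numpy()
        b_start = gb["start"].to_numpy()
        b_end = gb["end"].to_numpy()
        lo = np.searchsorted(b_end, a_start, side="right")
        hi = np.searchsorted(b_start, a_end, side="left")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            continue
        a_idx = np.repeat(np.flatnonzero(keep), counts[keep])
        b_idx = np.concatenate([np.arange(l, h) for l, h in zip(lo[keep], hi[keep])])
        starts = np.maximum(a_start[a_idx], b_start[b_idx])
        ends = np.minimum(a_end[a_idx], b_end[b_idx])
        ok = starts < ends
        pieces.append(pd.DataFrame({"chrom": chrom, "start": starts[ok], "end": ends[ok]}))
    if not pieces:
        return pd.DataFrame(columns=INTERVAL_COLUMNS).pipe(intervals_frame)
    return pd.concat(pieces, ignore_index=True)


def _as_interval_frame(obj) -> pd.DataFrame:
    if isinstance(obj, ElementSet):
        return obj.intervals.loc[:, INTERVAL_COLUMNS]
    return intervals_frame(obj)


# ---------------------------------------------------------------------------
# element identification and classification
# ---------------------------------------------------------------------------


def intersect_peaks(h3k27ac, accessible, context: str = "", assembly: str = "") -> ElementSet:
    """Identify enhancer-like elements as the base-level peak intersection.

    Overlapping bases of the two peak sets are merged into maximal intervals;
    every output base lies in both inputs.
    """
    a_asm = getattr(h3k27ac, "assembly", "") or assembly
    b_asm = getattr(accessible, "assembly", "") or assembly
    if a_asm and b_asm and a_asm != b_asm:
        raise ValueError(f"assembly mismatch: {a_asm!r} vs {b_asm!r}")
    a = merge_intervals(_as_interval_frame(h3k27ac))
    b = merge_intervals(_as_interval_frame(accessible))
    out = _intersect_merged(a, b)
    return ElementSet(out, context=context, conservation_class="NC", assembly=a_asm or b_asm)


def _coverage_per_interval(df: pd.DataFrame, blocks: pd.DataFrame) -> np.ndarray:
    """Bases of each interval of ``df`` covered by the merged ``blocks``."""
    covered = np.zeros(len(df), dtype=np.int64)
    blocks = merge_intervals(blocks)
    b_by_chrom = dict(tuple(blocks.groupby("chrom", sort=False)))
    for chrom, grp in df.groupby("chrom", sort=False):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        b_start = gb["start"].to_numpy()
        b_end = gb["end"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(b_end - b_start)])

        def cov_before(x: np.ndarray) -> np.ndarray:
            i = np.searchsorted(b_start, x, side="right")
            c = cum[i].astype(np.int64)
            has = i > 0
            trim = np.zeros_like(c)
            trim[has] = np.maximum(0, b_end[i[has] - 1] - x[has])
            return c - trim

        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        covered[grp.index.to_numpy()] = cov_before(e) - cov_before(s)
    return covered


def conservation_fraction(element, blocks: AlignmentBlockSet) -> float | np.ndarray:
    """Fraction of element bases lying inside gapless source alignment blocks.

    Accepts a single :class:`GenomicInterval` (returns a float) or an interval
    frame / :class:`ElementSet` (returns an array aligned to its rows).
    """
    if isinstance(element, GenomicInterval):
        df = intervals_frame([element])
        scalar = True
    else:
        df = _as_interval_frame(element)
        scalar = False
    if not len(df):
        return np.zeros(0)
    cov = _coverage_per_interval(df, blocks.source_intervals())
    frac = cov / (df["end"] - df["start"]).to_numpy()
    return float(frac[0]) if scalar else frac


def classify_conservation(
    nc: ElementSet,
    blocks: AlignmentBlockSet,
    levels: Mapping[str, float] | Sequence[float] = (0.1, 0.5, 0.9),
) -> dict[str, ElementSet]:
    """Split NC elements into conservation classes by minMatch thresholds.

    An element joins the level-``m`` class iff its conservation fraction is
    ``>= m``; the retained record is the original (source-genome) interval, so
    the classes nest by construction.  ``levels`` must be strictly increasing.
    """
    if isinstance(levels, Mapping):
        names = list(levels.keys())
        cuts = [float(levels[k]) for k in names]
    else:
        cuts = [float(v) for v in levels]
        if len(cuts) != 3:
            raise ValueError("positional levels must give the LC, MC, HC thresholds")
        names = ["LC", "MC", "HC"]
    if any(b <= a for a, b in zip(cuts, cuts[1:])) or not all(0 < c <= 1 for c in cuts):
        raise ValueError("conservation levels must be strictly increasing in (0, 1]")
    frac = conservation_fraction(nc, blocks)
    scored = nc.intervals.copy()
    scored["conservation_fraction"] = frac
    out: dict[str, ElementSet] = {}
    for name, cut in zip(names, cuts):
        sub = scored.loc[scored["conservation_fraction"] >= cut].reset_index(drop=True)
        out[name] = ElementSet(
            sub, context=nc.context, conservation_class=name, assembly=nc.assembly
        )
    return out


def merge_omnibus(element_sets: Sequence[ElementSet]) -> ElementSet:
    """Aggregate context-specific elements and merge them into disjoint intervals.

    All inputs must share assembly and conservation class; the result is the
    union with overlapping or bookended segments merged (idempotent).
    """
    if not element_sets:
        raise ValueError("need at least one element set")
    classes = {es.conservation_class for es in element_sets}
    if len(classes) != 1:
        raise ValueError(f"mixed conservation classes: {sorted(classes)}")
    assemblies = {es.assembly for es in element_sets if es.assembly}
    if len(assemblies) > 1:
        raise ValueError(f"mixed assemblies: {sorted(assemblies)}")
    merged = merge_intervals(
        pd.concat([es.intervals.loc[:, INTERVAL_COLUMNS] for es in element_sets], ignore_index=True)
    )
    return ElementSet(
        merged,
        context="omnibus",
        conservation_class=classes.pop(),
        assembly=assemblies.pop() if assemblies else "",
    )


def tss_proximity_class(
    elements: ElementSet | pd.DataFrame,
    tss_positions: Mapping[str, Sequence[int]],
    proximal: int = 200,
    near: int = 2000,
) -> pd.Series:
    """Classify elements by distance to the nearest transcription start site.

    Distance is measured from the closest element base to the closest TSS;
    boundaries are inclusive: ``<= 200`` bp -> ``proximal200``, ``<= 2000`` bp
    -> ``proximal2k``, otherwise ``distal``.
    """
    tss = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tss_positions.items()}
    if not tss or all(len(v) == 0 for v in tss.values()):
        raise ValueError("TSS list must be non-empty")
    df = _as_interval_frame(elements)
    dist = np.full(len(df), np.iinfo(np.int64).max, dtype=np.int64)
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = tss.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        s = grp["start"].to_numpy()
        last = grp["end"].to_numpy() - 1  # last base of the element
        # candidate TSSs flanking the interval
        i = np.searchsorted(pos, s)
        j = np.searchsorted(pos, last, side="right")
        d = np.full(len(grp), np.iinfo(np.int64).max, dtype=np.int64)
        inside = j > i  # at least one TSS within [start, end)
        d[inside] = 0
        left_ok = i > 0
        d[left_ok] = np.minimum(d[left_ok], s[left_ok] - pos[i[left_ok] - 1])
        right_ok = j < len(pos)
        d[right_ok] = np.minimum(d[right_ok], pos[j[right_ok]] - last[right_ok])
        dist[grp.index.to_numpy()] = d
    labels = np.where(dist <= proximal, "proximal200", np.where(dist <= near, "proximal2k", "distal"))
    return pd.Series(labels, index=df.index, name="tss_class")
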