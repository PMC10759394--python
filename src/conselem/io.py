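"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything here is tab-separated text: BED3+ for peaks and elements, UCSC
chain files or a simplified two-sided block TSV for alignment blocks, and
TSV tables for SNPs, GWAS summary statistics, LD scores, and fine-mapping
posterior inclusion probabilities (PIPs).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .elements import AlignmentBlockSet, ElementSet, intervals_frame

GWAS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "n", "z"]
PIP_COLUMNS = ["snp", "trait", "method", "pip"]
SNP_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf"]

BLOCK_COLUMNS = ["chrom", "start", "end", "target_chrom", "target_start", "target_end"]


# -- BED ---------------------------------------------------------------------


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED3+ file into a sorted interval frame (extra columns kept)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    extras = {i: f"field{i}" for i in df.columns if isinstance(i, int)}
    df = df.rename(columns=extras)
    base = intervals_frame(df)
    for c in df.columns:
        if c not in ("chrom", "start", "end"):
            srt = df.sort_values(["chrom", "start", "end"], kind="mergesort")
            base[c] = srt[c].to_numpy()
    return base


def write_bed(obj, path: str | os.PathLike) -> None:
    """Write intervals (or an :class:`ElementSet`) as BED.

    Element sets scored for conservation carry two extra columns,
    ``conservation_fraction`` and ``conservation_class``.
    """
    if isinstance(obj, ElementSet):
        df = obj.intervals.copy()
        if "conservation_fraction" in df.columns:
            df["conservation_class"] = obj.conservation_class
    else:
        df = pd.DataFrame(obj)
    df.to_csv(path, sep="\t", header=False, index=False)


# -- alignment blocks --------------------------------------------------------


def read_blocks_tsv(
    path: str | os.PathLike, source_assembly: str = "", target_assembly: str = ""
) -> AlignmentBlockSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"block TSV missing columns: {missing}")
    return AlignmentBlockSet(df[BLOCK_COLUMNS], source_assembly, target_assembly)


def write_blocks_tsv(blocks: AlignmentBlockSet, path: str | os.PathLike) -> None:
    blocks.blocks[BLOCK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chain(path: str | os.PathLike) -> AlignmentBlockSet:
    """Decompose a UCSC chain file into gapless alignment blocks.

    The chain "target" (t) side is taken as the source genome and the "query"
    (q) side as the other genome.  Negative query strands are converted to
    forward-strand coordinates; the source strand of a chain is always '+'.
    """
    records = []
    src_asm = tgt_asm = ""
    with open(path) as fh:
        header = None
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                parts = line.split()
                header = {
                    "t_name": parts[2],
                    "t_size": int(parts[3]),
                    "t_start": int(parts[5]),
                    "q_name": parts[7],
                    "q_size": int(parts[8]),
                    "q_strand": parts[9],
                    "q_start": int(parts[10]),
                }
                t_pos = header["t_start"]
                q_pos = header["q_start"]
                continue
            if header is None:
                raise ValueError("alignment data line before chain header")
            parts = [int(x) for x in line.split()]
            size = parts[0]
            dt = parts[1] if len(parts) > 1 else 0
            dq = parts[2] if len(parts) > 2 else 0
            q0, q1 = q_pos, q_pos + size
            if header["q_strand"] == "-":
                q0, q1 = header["q_size"] - q1, header["q_size"] - q0
            records.append(
                (header["t_name"], t_pos, t_pos + size, header["q_name"], q0, q1)
            )
            t_pos += size + dt
            q_pos += size + dq
            if len(parts) == 1:
                header = None
    df = pd.DataFrame(records, columns=BLOCK_COLUMNS)
    return AlignmentBlockSet(df, src_asm, tgt_asm)


# -- tabular inputs ----------------------------------------------------------


def read_snp_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a SNP table from TSV, or from a VCF (sites only, MAF from AF tag)."""
    path = os.fspath(path)
    if path.endswith(".vcf"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                info = dict(
                    kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
                ) if len(f) > 7 else {}
                af = float(info.get("AF", "nan"))
                maf = min(af, 1 - af) if np.isfinite(af) else np.nan
                rows.append((f[2], f[0], int(f[1]) - 1, f[3], f[4], maf))
        df = pd.DataFrame(rows, columns=SNP_COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t")
    return validate_snp_table(df)


def validate_snp_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    df = df[SNP_COLUMNS + [c for c in df.columns if c not in SNP_COLUMNS]].copy()
    if df["snp"].duplicated().any():
        raise ValueError("SNP ids must be unique")
    maf = df["maf"].to_numpy(float)
    if np.isfinite(maf).all() and ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    return df


def read_gwas_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS summary TSV missing columns: {missing}")
    return df


def write_gwas_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pip_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PIP TSV missing columns: {missing}")
    if ((df["pip"] < 0) | (df["pip"] > 1)).any():
        raise ValueError("PIPs must lie in [0, 1]")
    return df


def write_pip_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = PIP_COLUMNS + [c for c in df.columns if c not in PIP_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def write_annotation_tsv(
    snps: pd.DataFrame, annotations: Mapping[str, np.ndarray], path: str | os.PathLike
) -> None:
    """Thin-annot style layout: snp, chrom, pos plus one 0/1 column per label."""
    out = snps[["snp", "chrom", "pos"]].copy()
    for label, values in annotations.items():
        out[label] = np.asarray(values, dtype=int)
    out.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotype_matrix(values: np.ndarray, snp_ids, path: str | os.PathLike) -> None:
    pd.DataFrame(values, columns=list(snp_ids)).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=np.int8), list(df.columns)
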