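"""Readers and writers for the tabular dialects used across the pipeline.

All files are plain text.  Genotype tables are tab-separated with columns
``sample_id  locus  allele1  allele2  tool  platform``; missing calls are
``NA``.  Reference allele frequencies are ``locus  allele  frequency``.
Population panels are CSV with columns
``population,region,sample_n,standard,locus,allele,frequency`` (an
AFND-export-like layout).  ROH summaries are ``sample_id  total_roh_bp
n_segments  platform``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .nomenclature import GGroupTable, load_g_groups

PathLike = Union[str, Path]

GENOTYPE_COLUMNS = ["sample_id", "locus", "allele1", "allele2", "tool", "platform"]


def read_genotypes(path: PathLike) -> pd.DataFrame:
    """Read a genotype TSV; absent ``tool``/``platform`` columns become ``NA``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in GENOTYPE_COLUMNS:
        if col not in df.columns:
            df[col] = "NA"
    return df[GENOTYPE_COLUMNS]


def write_genotypes(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_reference_af(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "allele": str})
    df["frequency"] = df["frequency"].astype(float)
    return df


def write_reference_af(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_panel_rows(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["frequency"] = df["frequency"].astype(float)
    df["sample_n"] = df["sample_n"].astype(int)
    return df


def read_roh(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "platform": str})
    df["total_roh_bp"] = df["total_roh_bp"].astype(float)
    df["n_segments"] = df["n_segments"].astype(int)
    return df


def write_roh(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_g_groups(path: PathLike) -> GGroupTable:
    with open(path) as fh:
        return load_g_groups(fh)


def aggregate_roh_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-segment ROH caller output into per-sample summaries.

    Expects columns ``sample_id``, ``length`` (bp) and optionally ``platform``;
    returns the summary dialect (total_roh_bp, n_segments).
    """
    has_platform = "platform" in segments.columns
    grouped = segments.groupby("sample_id")
    out = grouped.agg(
        total_roh_bp=("length", "sum"), n_segments=("length", "size")
    ).reset_index()
    if has_platform:
        out = out.merge(
            grouped["platform"].first().reset_index(), on="sample_id"
        )
    else:
        out["platform"] = "NA"
    return out
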