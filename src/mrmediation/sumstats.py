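"""GWAS summary-statistics tables: reading, validation, writing.

The canonical dialect is a delimited text table with one row per variant and
columns ``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
For binary traits ``beta`` is a log odds ratio; for continuous traits it is in
SD (or trait) units. Missing effect-allele frequency is written as ``NA``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: accepted header spellings for each canonical column (lower-cased)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "rsid", "rs_id", "markername", "variant_id", "id"),
    "chr": ("chr", "chrom", "chromosome", "#chrom"),
    "pos": ("pos", "bp", "base_pair_location", "position"),
    "effect_allele": ("effect_allele", "a1", "ea", "allele1", "alt"),
    "other_allele": ("other_allele", "a2", "oa", "nea", "allele2", "ref"),
    "eaf": ("eaf", "freq", "af", "effect_allele_frequency", "maf", "frq"),
    "beta": ("beta", "b", "effect", "effect_size", "logor"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "pval": ("pval", "p", "p_value", "pvalue", "p_bolt_lmm"),
    "n": ("n", "samplesize", "sample_size", "n_total"),
}

VALID_BASES = frozenset("ACGT")
NA_SENTINEL = "NA"

#: smallest positive double; p = 0 inputs are clamped here, not dropped
MIN_PVAL = np.nextafter(0.0, 1.0)


@dataclass
class SumStatsTable:
    """One trait's per-variant GWAS summary records.

    ``df`` holds the canonical columns in canonical order; ``snp`` values are
    unique. For ``trait_type == "binary"`` the betas are log odds ratios
    throughout the pipeline.
    """

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    df: pd.DataFrame
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SchemaError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        if self.df["snp"].duplicated().any():
            raise SchemaError(f"duplicate snp ids in table {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, snp_ids) -> "SumStatsTable":
        """Restrict to the given variants, preserving current row order."""
        keep = self.df[self.df["snp"].isin(set(snp_ids))].reset_index(drop=True)
        return SumStatsTable(self.trait_name, self.trait_type, keep, self.provenance)


def _resolve_columns(header: list[str], column_map: dict[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual header names; eaf may be absent."""
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon in CANONICAL_COLUMNS:
        if canon in column_map:
            if column_map[canon] not in header:
                raise SchemaError(
                    f"column {column_map[canon]!r} (mapped to {canon!r}) not in header"
                )
            resolved[canon] = column_map[canon]
            continue
        for alias in DEFAULT_ALIASES[canon]:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
        else:
            if canon == "eaf":
                continue  # optional
            raise SchemaError(f"mandatory column {canon!r} not found in header {header}")
    return resolved


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_sumstats(
    path,
    trait_name: str,
    trait_type: str,
    column_map: dict[str, str] | None = None,
) -> SumStatsTable:
    """Read and validate a summary-statistics table.

    Rows violating per-variant invariants (se <= 0, p outside (0,1], identical
    or non-ACGT alleles, eaf outside (0,1), pos < 1) are dropped with a logged
    count; p = 0 is clamped to the smallest positive double with a warning
    rather than dropped. Duplicate snp ids keep the smallest p-value.

    Raises :class:`SchemaError` for a missing mandatory column and
    :class:`EmptyInputError` when no valid rows remain.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=[NA_SENTINEL], keep_default_na=False)
    resolved = _resolve_columns(list(raw.columns), column_map)

    df = pd.DataFrame({canon: raw[src] for canon, src in resolved.items()})
    if "eaf" not in df.columns:
        df["eaf"] = np.nan

    warnings: list[str] = []
    n_in = len(df)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["snp"] = df["snp"].astype(str)
    df["chr"] = df["chr"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    n_zero_p = int((df["pval"] == 0).sum())
    if n_zero_p:
        msg = f"{trait_name}: clamped {n_zero_p} zero p-values to {MIN_PVAL:g}"
        warnings.append(msg)
        logger.warning(msg)
        df.loc[df["pval"] == 0, "pval"] = MIN_PVAL

    single_base = df["effect_allele"].isin(VALID_BASES) & df["other_allele"].isin(VALID_BASES)
    valid = (
        single_base
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["pos"] >= 1)
        & (df["beta"].notna())
        & (df["n"].notna())
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        msg = f"{trait_name}: dropped {n_dropped} invalid rows of {n_in}"
        warnings.append(msg)
        logger.info(msg)
    df = df[valid]

    # duplicate ids: keep the most significant record (stated tie rule)
    df = df.sort_values(["pval", "snp"], kind="mergesort")
    n_dup = int(df["snp"].duplicated().sum())
    if n_dup:
        msg = f"{trait_name}: removed {n_dup} duplicate snp ids (kept smallest pval)"
        warnings.append(msg)
        logger.info(msg)
    df = df.drop_duplicates("snp", keep="first")
    # restore input order for the retained rows
    df = df.sort_index().reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df = df[CANONICAL_COLUMNS]

    if len(df) == 0:
        raise EmptyInputError(f"no valid rows in {path} for trait {trait_name!r}")
    return SumStatsTable(trait_name, trait_type, df, provenance=str(path), warnings=warnings)


def write_sumstats(table: SumStatsTable, path) -> Path:
    """Write a table in the canonical tab-separated dialect.

    ``read_sumstats(write_sumstats(t)) == t`` on records; missing eaf is
    emitted as the ``NA`` sentinel.
    """
    path = Path(path)
    df = table.df.copy()
    df.to_csv(path, sep="\t", index=False, na_rep=NA_SENTINEL)
    return path
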