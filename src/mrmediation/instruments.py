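"""Instrumental-variable selection: p-value screening and greedy LD clumping.

Defaults follow common two-sample MR practice: genome-wide significance
(p < 5e-8) for primary exposures, a relaxed p < 1e-5 screen for traits with
few genome-wide hits (e.g. microbial abundances), and clumping that removes
any variant within 10,000 kb of a more significant retained variant when
their LD r-squared is at or above 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
RELAXED_P = 1e-5


@dataclass
class ClumpConfig:
    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not 0 <= self.r2_threshold <= 1:
            raise ConfigError(f"r2_threshold must be in [0,1], got {self.r2_threshold}")
        if self.window_kb <= 0:
            raise ConfigError(f"window_kb must be > 0, got {self.window_kb}")


class LDReference:
    """Pairwise LD correlations (r) for a panel of variants.

    Stored as a square symmetric matrix with unit diagonal. Variants absent
    from the panel are treated as uncorrelated with everything (r = 0), with
    a warning logged once per lookup batch.
    """

    def __init__(self, snp_ids: list[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.shape != (len(snp_ids), len(snp_ids)):
            raise ConfigError(
                f"LD matrix shape {r.shape} does not match {len(snp_ids)} snp ids"
            )
        self.snp_ids = list(snp_ids)
        self.r = r
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants; 0 if either is unknown."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def write(self, path) -> None:
        df = pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids)
        df.to_csv(path, sep="\t", index_label="snp")

    @classmethod
    def read(cls, path) -> "LDReference":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LDReference":
        return cls(list(snp_ids), np.eye(len(snp_ids)))


def filter_by_p(table: SumStatsTable, p_threshold: float = GENOME_WIDE_P) -> SumStatsTable:
    """Retain rows with pval strictly below the threshold, most significant first.

    An empty result is allowed; it is flagged with a logged warning so the
    caller can skip the trait.
    """
    if not 0 < p_threshold <= 1:
        raise ConfigError(f"p_threshold must be in (0,1], got {p_threshold}")
    df = table.df[table.df["pval"] < p_threshold]
    df = df.sort_values(["pval", "chr", "pos"], kind="mergesort").reset_index(drop=True)
    if len(df) == 0:
        logger.warning(
            "%s: no variants pass p < %.3g", table.trait_name, p_threshold
        )
    return SumStatsTable(table.trait_name, table.trait_type, df, table.provenance)


def clump(
    table: SumStatsTable,
    ld: LDReference | None,
    cfg: ClumpConfig | None = None,
) -> SumStatsTable:
    """Greedy LD clumping.

    Repeatedly keep the remaining variant with the smallest p-value and
    discard every remaining variant on the same chromosome within
    ``window_kb`` of it whose r-squared with it is at or above
    ``r2_threshold``. Ties in p are broken by (chrom, pos). The most
    significant variant overall is therefore always retained, and every
    retained pair within the window has r-squared below the threshold.
    """
    cfg = cfg or ClumpConfig()
    if ld is None:
        ld = LDReference.identity([])
    df = table.df
    missing = [s for s in df["snp"] if s not in ld]
    if missing and ld.snp_ids:
        logger.warning(
            "%s: %d variants absent from LD reference treated as independent",
            table.trait_name, len(missing),
        )

    order = df.sort_values(["pval", "chr", "pos"], kind="mergesort").index.to_list()
    window_bp = cfg.window_kb * 1000.0
    alive = set(order)
    kept: list[int] = []
    snp = df["snp"]
    chrom = df["chr"]
    pos = df["pos"]
    for idx in order:
        if idx not in alive:
            continue
        kept.append(idx)
        alive.discard(idx)
        for other in list(alive):
            if chrom[other] != chrom[idx]:
                continue
            if abs(float(pos[other]) - float(pos[idx])) > window_bp:
                continue
            if ld.r2(snp[idx], snp[other]) >= cfg.r2_threshold:
                alive.discard(other)
    out = df.loc[kept].reset_index(drop=True)
    return SumStatsTable(table.trait_name, table.trait_type, out, table.provenance)


def select_instruments(
    table: SumStatsTable,
    ld: LDReference | None = None,
    cfg: ClumpConfig | None = None,
) -> SumStatsTable:
    """p-value screen followed by clumping — the standard IV selection step."""
    cfg = cfg or ClumpConfig()
    return clump(filter_by_p(table, cfg.p_threshold), ld, cfg)


def instrument_strength(table: SumStatsTable) -> pd.DataFrame:
    """Diagnostic per-variant F statistics, F = (beta/se)^2.

    Reported for transparency only; no weak-instrument filter is applied.
    """
    f = (table.df["beta"] / table.df["se"]) ** 2
    return pd.DataFrame({"snp": table.df["snp"], "f_stat": f})
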