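"""Allele harmonization between two summary-statistics tables.

Two GWAS report each variant's effect relative to a chosen effect allele; MR
needs both effects to refer to the *same* allele. For each shared variant:

* identical allele pairs are kept as-is;
* swapped pairs (effect/other exchanged) have the outcome beta negated and
  the outcome frequency reflected (status ``sign_flipped``);
* pairs that match only after complementing both alleles were typed on
  opposite strands and are aligned by complementing (``strand_flipped``),
  with an additional sign flip if also swapped;
* palindromic variants (A/T or C/G) cannot be resolved from alleles alone:
  under the default ``infer`` policy the effect-allele frequencies decide the
  alignment when both are outside an ambiguity band around 0.5, otherwise the
  variant is dropped (``dropped_palindromic``);
* anything irreconcilable is ``dropped_mismatch``.

The audit counts over all statuses always sum to the size of the snp-id
intersection of the two tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, HarmonizationError
from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

STATUSES = ("kept", "sign_flipped", "strand_flipped",
            "dropped_palindromic", "dropped_mismatch")

DEFAULT_EAF_BAND = 0.08

HARMONIZED_COLUMNS = [
    "snp", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "status",
]


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure-outcome instrument table — the unit of MR.

    ``df`` holds only usable (non-dropped) records with exposure and outcome
    effects expressed for the same effect allele; ``audit`` counts every
    shared variant by harmonization status.
    """

    exposure_name: str
    outcome_name: str
    df: pd.DataFrame
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def snp_ids(self) -> list[str]:
        return list(self.df["snp"])

    def drop(self, snp_ids) -> "HarmonizedSet":
        """Harmonized set without the given variants (audit unchanged)."""
        keep = ~self.df["snp"].isin(set(snp_ids))
        return HarmonizedSet(self.exposure_name, self.outcome_name,
                             self.df[keep].reset_index(drop=True), dict(self.audit))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path, exposure_name: str = "exposure",
             outcome_name: str = "outcome") -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(exposure_name, outcome_name, df)


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in PALINDROMIC_PAIRS


def _eaf_side(eaf: float, band: float) -> int:
    """-1 below the ambiguity band, +1 above, 0 inside (unresolvable)."""
    if np.isnan(eaf):
        return 0
    if eaf < 0.5 - band:
        return -1
    if eaf > 0.5 + band:
        return 1
    return 0


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_policy: str = "infer",
    eaf_ambiguity_band: float = DEFAULT_EAF_BAND,
) -> HarmonizedSet:
    """Align the outcome table's effects to the exposure's effect alleles.

    ``palindrome_policy``: ``infer`` (default) resolves palindromic variants
    by frequency when possible and drops the ambiguous ones; ``drop``
    discards all palindromic variants; ``keep`` assumes both tables are on
    the same strand and applies the plain allele rules.

    Raises :class:`HarmonizationError` when the tables share no variants.
    """
    if palindrome_policy not in ("infer", "drop", "keep"):
        raise ConfigError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not 0 <= eaf_ambiguity_band < 0.5:
        raise ConfigError(f"eaf_ambiguity_band must be in [0, 0.5), got {eaf_ambiguity_band}")

    exp = exposure.df.set_index("snp")
    out = outcome.df.set_index("snp")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise HarmonizationError(
            f"no shared variants between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )
    # deterministic order: exposure table order
    shared = [s for s in exposure.df["snp"] if s in set(out.index)]

    rows = []
    audit = {s: 0 for s in STATUSES}
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        palindromic = _is_palindromic(ea_e, oa_e)

        status = None
        if palindromic:
            if palindrome_policy == "drop":
                status = "dropped_palindromic"
            elif {ea_o, oa_o} != {ea_e, oa_e}:
                status = "dropped_mismatch"
            else:
                # For a palindromic pair a swap and a strand flip are
                # indistinguishable from the allele strings alone.
                swapped = ea_o == oa_e  # apparent orientation from the strings
                negate = swapped
                if palindrome_policy == "infer":
                    side_e = _eaf_side(float(e["eaf"]), eaf_ambiguity_band)
                    cand_eaf = 1.0 - eaf_out if negate else eaf_out
                    side_o = _eaf_side(cand_eaf, eaf_ambiguity_band)
                    if side_e == 0 or side_o == 0:
                        status = "dropped_palindromic"
                    elif side_e != side_o:
                        # the frequencies contradict the apparent alignment:
                        # the variant was typed on the opposite strand
                        negate = not negate
                if status is None:
                    if negate:
                        beta_out = -beta_out
                        eaf_out = 1.0 - eaf_out
                        status = "sign_flipped"
                    else:
                        status = "kept"
        elif (ea_o, oa_o) == (ea_e, oa_e):
            status = "kept"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            status = "sign_flipped"
        else:
            cea, coa = COMPLEMENT.get(ea_o, "?"), COMPLEMENT.get(oa_o, "?")
            if (cea, coa) == (ea_e, oa_e):
                status = "strand_flipped"
            elif (cea, coa) == (oa_e, ea_e):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                status = "strand_flipped"
            else:
                status = "dropped_mismatch"

        audit[status] += 1
        if status.startswith("dropped"):
            continue
        rows.append({
            "snp": snp, "effect_allele": ea_e, "other_allele": oa_e,
            "beta_exp": float(e["beta"]), "se_exp": float(e["se"]),
            "beta_out": beta_out, "se_out": float(o["se"]),
            "eaf_exp": float(e["eaf"]), "eaf_out": eaf_out,
            "status": status,
        })

    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    n_dropped = audit["dropped_palindromic"] + audit["dropped_mismatch"]
    if n_dropped:
        logger.info(
            "%s vs %s: dropped %d of %d shared variants at harmonization",
            exposure.trait_name, outcome.trait_name, n_dropped, len(shared),
        )
    return HarmonizedSet(exposure.trait_name, outcome.trait_name, df, audit)
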