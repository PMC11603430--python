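"""Two-step MR mediation: product of coefficients with delta-method SEs.

Step 1 estimates the exposure's effect on a candidate mediator (beta1) using
the exposure's instruments; step 2 estimates the mediator's effect on the
outcome (beta2) using the mediator's own instruments. The indirect effect is
the coefficient product ``beta1 * beta2`` and the proportion mediated is
``beta1 * beta2 / alpha`` where alpha is the total effect of the exposure on
the outcome. First-order delta-method standard errors treat the three
estimates as independent (they come from separate two-sample fits); a
parametric-bootstrap alternative for the proportion's CI is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedProportionError
from .harmonize import harmonize
from .instruments import ClumpConfig, LDReference, RELAXED_P, select_instruments
from .mr import MREstimate, ivw
from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition of a total effect.

    ``indirect = beta1 * beta2`` and ``proportion * alpha = indirect`` hold
    exactly. ``inconsistent`` flags |proportion| > 1 (opposing direct and
    indirect paths, or a near-null total effect).
    """

    alpha: MREstimate
    beta1: MREstimate
    beta2: MREstimate
    indirect: float = field(init=False)
    se_indirect: float = field(init=False)
    proportion: float = field(init=False)
    se_proportion: float = field(init=False)
    z_indirect: float = field(init=False)
    p_indirect: float = field(init=False)
    inconsistent: bool = field(init=False)
    boot_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        a, b1, b2 = self.alpha.beta, self.beta1.beta, self.beta2.beta
        if a == 0.0:
            raise UndefinedProportionError("proportion mediated undefined for alpha = 0")
        se1, se2, se_a = self.beta1.se, self.beta2.se, self.alpha.se
        self.indirect = b1 * b2
        self.se_indirect = math.sqrt(b1 ** 2 * se2 ** 2 + b2 ** 2 * se1 ** 2)
        self.proportion = self.indirect / a
        if self.indirect != 0.0:
            self.se_proportion = abs(self.proportion) * math.sqrt(
                (self.se_indirect / self.indirect) ** 2 + (se_a / a) ** 2
            )
        else:
            self.se_proportion = self.se_indirect / abs(a)
        self.z_indirect = self.indirect / self.se_indirect if self.se_indirect > 0 else 0.0
        self.p_indirect = float(2.0 * stats.norm.sf(abs(self.z_indirect)))
        self.inconsistent = abs(self.proportion) > 1.0
        if self.inconsistent:
            logger.warning(
                "proportion mediated %.3f outside [-1, 1]: direct and indirect "
                "paths oppose or the total effect is near zero", self.proportion,
            )

    @property
    def proportion_pct(self) -> float:
        """Proportion mediated as a percentage at one decimal."""
        return round(100.0 * self.proportion, 1)


def two_step_mediation(
    alpha: MREstimate,
    beta1: MREstimate,
    beta2: MREstimate,
    bootstrap: bool = False,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MediationResult:
    """Combine total, step-1 and step-2 effects into a mediation result.

    With ``bootstrap=True`` the proportion's 95% CI is additionally obtained
    by resampling the three coefficients from their normal sampling
    distributions (percentile interval), which avoids the delta method's
    independence and linearity approximations.
    """
    result = MediationResult(alpha=alpha, beta1=beta1, beta2=beta2)
    if bootstrap:
        rng = np.random.default_rng(seed)
        a = rng.normal(alpha.beta, alpha.se, n_boot)
        b1 = rng.normal(beta1.beta, beta1.se, n_boot)
        b2 = rng.normal(beta2.beta, beta2.se, n_boot)
        with np.errstate(divide="ignore", invalid="ignore"):
            props = b1 * b2 / a
        lo, hi = np.percentile(props, [2.5, 97.5])
        result.boot_ci = (float(lo), float(hi))
    return result


@dataclass
class MediationScanRow:
    mediator_name: str
    result: MediationResult
    qualifies: bool
    n_snp_step1: int
    n_snp_step2: int


def run_mediation_scan(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    mediator_tables: list[SumStatsTable],
    ld: LDReference | None = None,
    exposure_clump: ClumpConfig | None = None,
    mediator_clump: ClumpConfig | None = None,
    ivw_model: str = "mre",
    palindrome_policy: str = "infer",
    significance: float = 0.05,
) -> list[MediationScanRow]:
    """Screen candidate mediators of an exposure-outcome effect.

    The total effect alpha is computed once from the exposure's instruments
    on the outcome. For each mediator, beta1 comes from the exposure's
    instruments on the mediator and beta2 from the mediator's own
    instruments (relaxed p-threshold by default) on the outcome. A mediator
    qualifies for reporting only when both step IVW p-values are below the
    significance level. Results are sorted by |proportion| descending;
    mediators without instruments are skipped with a log entry.
    """
    exposure_clump = exposure_clump or ClumpConfig()
    mediator_clump = mediator_clump or ClumpConfig(p_threshold=RELAXED_P)

    exp_iv = select_instruments(exposure, ld, exposure_clump)
    if len(exp_iv) == 0:
        raise UndefinedProportionError(
            f"no instruments for exposure {exposure.trait_name!r}"
        )
    alpha = ivw(harmonize(exp_iv, outcome, palindrome_policy), model=ivw_model)

    rows: list[MediationScanRow] = []
    for med in mediator_tables:
        med_iv = select_instruments(med, ld, mediator_clump)
        if len(med_iv) == 0:
            logger.info("mediator %s skipped: no instruments", med.trait_name)
            continue
        try:
            h1 = harmonize(exp_iv, med, palindrome_policy)
            beta1 = ivw(h1, model=ivw_model)
            h2 = harmonize(med_iv, outcome, palindrome_policy)
            beta2 = ivw(h2, model=ivw_model)
            result = two_step_mediation(alpha, beta1, beta2)
        except Exception as exc:  # skip degenerate mediators, keep scanning
            logger.info("mediator %s skipped: %s", med.trait_name, exc)
            continue
        qualifies = beta1.pval < significance and beta2.pval < significance
        rows.append(MediationScanRow(
            mediator_name=med.trait_name, result=result, qualifies=qualifies,
            n_snp_step1=beta1.n_snp, n_snp_step2=beta2.n_snp,
        ))
    rows.sort(key=lambda r: abs(r.result.proportion), reverse=True)
    return rows


def scan_to_frame(rows: list[MediationScanRow]) -> pd.DataFrame:
    """Tidy mediation summary table (percent proportions at one decimal)."""
    records = []
    for r in rows:
        m = r.result
        records.append({
            "mediator": r.mediator_name,
            "alpha": m.alpha.beta, "se_alpha": m.alpha.se,
            "beta1": m.beta1.beta, "se_beta1": m.beta1.se, "p_beta1": m.beta1.pval,
            "beta2": m.beta2.beta, "se_beta2": m.beta2.se, "p_beta2": m.beta2.pval,
            "indirect": m.indirect, "se_indirect": m.se_indirect,
            "proportion_pct": m.proportion_pct, "se_proportion": m.se_proportion,
            "p_indirect": m.p_indirect,
            "qualifies": r.qualifies, "inconsistent": m.inconsistent,
            "nsnp_step1": r.n_snp_step1, "nsnp_step2": r.n_snp_step2,
        })
    return pd.DataFrame(records)
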