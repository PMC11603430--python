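"""Core two-sample MR estimators: Wald ratio, IVW, MR-Egger, Cochran's Q.

All estimators consume a :class:`~mrmediation.harmonize.HarmonizedSet` and
return an :class:`MREstimate` carrying the causal effect on the log-odds (or
SD) scale together with its odds-ratio representation and 95% CI.

The IVW estimator is implemented in ratio form: per-variant Wald ratios
theta_j = beta_out_j / beta_exp_j with first-order SEs
sigma_j = se_out_j / |beta_exp_j| are pooled with inverse-variance weights
w_j = sigma_j^-2. This is algebraically identical to weighted regression of
beta_out on beta_exp through the origin with weights se_out^-2 (the
equivalence is asserted in the test suite against an independent weighted
least-squares fit). The default multiplicative-random-effects model inflates
the fixed-effect SE by max(1, sqrt(Q/(k-1))), so it is never narrower than
the fixed-effect model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, UndefinedRatioError
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

Z_95 = 1.96  # conventional 95% normal multiplier


@dataclass
class MREstimate:
    """A causal-effect estimate with OR/CI representation.

    ``beta`` is on the scale of the outcome coefficients (log-odds for a
    binary outcome) per unit exposure; ``or_value`` and the CI are its
    exponential. ``ci_mult`` is the two-sided 95% critical value used
    (1.96 normal, or a t quantile for the Egger slope).
    """

    method: str  # wald | ivw_fe | ivw_mre | egger_slope
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_mult: float = Z_95
    or_value: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.or_value = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - self.ci_mult * self.se)
        self.ci_high = math.exp(self.beta + self.ci_mult * self.se)


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test across per-variant ratio estimates."""

    q: float
    df: int
    pval: float
    i2: float


@dataclass
class EggerResult:
    """MR-Egger regression: slope (causal effect) plus pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _ratio_components(h: HarmonizedSet):
    """Wald ratios, their SEs and weights, excluding zero exposure effects."""
    be = h.df["beta_exp"].to_numpy(dtype=float)
    bo = h.df["beta_out"].to_numpy(dtype=float)
    so = h.df["se_out"].to_numpy(dtype=float)
    nonzero = be != 0.0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.warning(
            "%s vs %s: excluded %d variants with zero exposure effect",
            h.exposure_name, h.outcome_name, n_excluded,
        )
    if not nonzero.any():
        raise UndefinedRatioError("every variant has zero exposure effect")
    be, bo, so = be[nonzero], bo[nonzero], so[nonzero]
    theta = bo / be
    sigma = so / np.abs(be)
    w = sigma ** -2.0
    return theta, sigma, w


def wald_ratio(record, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is the first-order delta approximation
    ``se_out / |beta_exp|``; with ``second_order=True`` the exposure-side
    uncertainty is propagated as well:
    ``sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4)``.
    """
    be = float(record["beta_exp"])
    bo = float(record["beta_out"])
    so = float(record["se_out"])
    if be == 0.0:
        raise UndefinedRatioError("Wald ratio undefined for beta_exp = 0")
    beta = bo / be
    if second_order:
        se_exp = float(record["se_exp"])
        se = math.sqrt(so ** 2 / be ** 2 + bo ** 2 * se_exp ** 2 / be ** 4)
    else:
        se = so / abs(be)
    return MREstimate("wald", beta, se, _two_sided_normal_p(beta / se), n_snp=1)


def cochran_q(h: HarmonizedSet, pooled_beta: float) -> HeterogeneityResult:
    """Q = sum_j w_j (theta_j - pooled)^2 with IVW ratio weights; df = k-1."""
    theta, _, w = _ratio_components(h)
    k = len(theta)
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs k >= 2, got {k}")
    q = float(np.sum(w * (theta - pooled_beta) ** 2))
    df = k - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q, df, pval, i2)


def ivw(h: HarmonizedSet, model: str = "mre") -> MREstimate:
    """Inverse-variance-weighted pooled causal estimate.

    ``model="fe"`` gives the fixed-effect SE ``sqrt(1/sum w)``;
    ``model="mre"`` (default) multiplies it by ``max(1, sqrt(Q/(k-1)))``.
    A single instrument degenerates to the Wald ratio.
    """
    if model not in ("fe", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    theta, sigma, w = _ratio_components(h)
    k = len(theta)
    if k == 1:
        est = MREstimate("wald", float(theta[0]), float(sigma[0]),
                         _two_sided_normal_p(theta[0] / sigma[0]), n_snp=1)
        return est
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    if model == "mre":
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (k - 1)))
    return MREstimate(f"ivw_{model}", beta, se,
                      _two_sided_normal_p(beta / se), n_snp=k)


def egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression of beta_out on beta_exp with intercept.

    Variants are first oriented so every beta_exp is positive (the estimate
    is invariant to joint sign flips by construction). Weights are
    se_out^-2; SEs carry a multiplicative overdispersion factor
    ``sqrt(max(1, RSS_w/(k-2)))`` and p-values use t with k-2 df.
    """
    be = h.df["beta_exp"].to_numpy(dtype=float)
    bo = h.df["beta_out"].to_numpy(dtype=float)
    so = h.df["se_out"].to_numpy(dtype=float)
    nonzero = be != 0.0
    be, bo, so = be[nonzero], bo[nonzero], so[nonzero]
    k = len(be)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs k >= 3, got {k}")

    sign = np.sign(be)
    x = be * sign
    y = bo * sign
    w = so ** -2.0

    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx ** 2
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sxx * sy - sx * sxy) / denom

    resid = y - intercept - slope * x
    rss_w = float((w * resid ** 2).sum())
    phi = max(1.0, rss_w / (k - 2))
    slope_se = math.sqrt(phi * sw / denom)
    intercept_se = math.sqrt(phi * sxx / denom)

    tdist = stats.t(k - 2)
    slope_p = float(2.0 * tdist.sf(abs(slope / slope_se)))
    intercept_p = float(2.0 * tdist.sf(abs(intercept / intercept_se)))
    tcrit = float(tdist.ppf(0.975))

    slope_est = MREstimate("egger_slope", float(slope), slope_se, slope_p,
                           n_snp=k, ci_mult=tcrit)
    return EggerResult(slope_est, float(intercept), intercept_se, intercept_p)


def _round3(x: float) -> str:
    return str(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN))


def to_or(e: MREstimate) -> tuple[str, str]:
    """Format an estimate as OR and 95% CI strings at three decimals.

    Rounding is half-even, matching the convention of most statistical
    reporting. Returns ``(or_str, "low-high")``.
    """
    return _round3(e.or_value), f"{_round3(e.ci_low)}-{_round3(e.ci_high)}"
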