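"""Instrument-level sensitivity analyses: leave-one-out and MR-PRESSO.

MR-PRESSO (pleiotropy residual sum and outlier test) is re-implemented from
its published description. For each variant j the expected outcome effect is
``theta_(-j) * beta_exp_j`` where ``theta_(-j)`` is the IVW slope computed
without variant j; the observed statistic is the weighted residual sum of
squares ``RSS = sum_j se_out_j^-2 (beta_out_j - theta_(-j) beta_exp_j)^2``.
Its null distribution is built by parametric resampling of both the exposure
and outcome effects, giving an empirical global p-value with the standard
(1 + exceedances)/(n_sim + 1) correction, per-variant outlier p-values
(Bonferroni-adjusted over k), an outlier-corrected IVW estimate, and a
distortion test comparing the correction against removals of random variant
subsets of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientInstrumentsError
from .harmonize import HarmonizedSet
from .mr import MREstimate, ivw

DEFAULT_N_SIM = 5000
DEFAULT_OUTLIER_ALPHA = 0.05
DEFAULT_N_DISTORTION = 1000


def leave_one_out(h: HarmonizedSet, model: str = "mre") -> pd.DataFrame:
    """IVW re-estimated with each variant excluded in turn.

    Returns one row per omitted variant with the usual estimate columns;
    with k = 2 each row is the Wald ratio of the remaining variant.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs k >= 2, got {h.n_snp}"
        )
    rows = []
    for snp in h.snp_ids():
        est = ivw(h.drop([snp]), model=model)
        rows.append({
            "omitted_snp": snp, "method": est.method, "nsnp": est.n_snp,
            "beta": est.beta, "se": est.se, "pval": est.pval,
            "or": est.or_value, "ci_low": est.ci_low, "ci_high": est.ci_high,
        })
    return pd.DataFrame(rows)


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_obs: float
    global_pval: float
    outlier_pvals: pd.DataFrame  # snp, pval, pval_bonferroni
    outlier_ids: list[str]
    beta_raw: MREstimate
    beta_corrected: MREstimate | None
    distortion_pval: float
    n_sim: int
    seed: int
    audit: dict = field(default_factory=dict)


def _loo_slopes(be, bo, so):
    """Leave-one-out IVW slopes for every variant, in ratio form."""
    theta = bo / be
    w = (np.abs(be) / so) ** 2  # sigma^-2 with sigma = so/|be|
    sw = w.sum(axis=-1, keepdims=True)
    swt = (w * theta).sum(axis=-1, keepdims=True)
    return (swt - w * theta) / (sw - w)


def presso(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    seed: int = 0,
    n_distortion: int = DEFAULT_N_DISTORTION,
    model: str = "mre",
) -> PressoResult:
    """Run the global, outlier and distortion tests. Deterministic per seed.

    Raises :class:`InsufficientInstrumentsError` for k < 4 and a
    ``corrected-estimate-undefined`` error when fewer than two variants
    survive outlier removal.
    """
    df = h.df[h.df["beta_exp"] != 0.0].reset_index(drop=True)
    k = len(df)
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs k >= 4, got {k}")
    if n_sim < 1000:
        raise ValueError(f"n_sim must be >= 1000, got {n_sim}")

    rng = np.random.default_rng(seed)
    snps = df["snp"].to_numpy()
    be = df["beta_exp"].to_numpy(dtype=float)
    se_e = df["se_exp"].to_numpy(dtype=float)
    bo = df["beta_out"].to_numpy(dtype=float)
    so = df["se_out"].to_numpy(dtype=float)
    w_out = so ** -2.0

    theta_loo = _loo_slopes(be, bo, so)
    resid = bo - theta_loo * be
    stat_obs = w_out * resid ** 2
    rss_obs = float(stat_obs.sum())

    # parametric resampling under the no-pleiotropy expectation
    be_s = rng.normal(be, se_e, size=(n_sim, k))
    bo_s = rng.normal(theta_loo * be, so, size=(n_sim, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_loo_s = _loo_slopes(be_s, bo_s, so)
    resid_s = bo_s - theta_loo_s * be_s
    stat_s = w_out * resid_s ** 2
    rss_s = stat_s.sum(axis=1)

    global_pval = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(stat_s >= stat_obs, axis=0)) / (n_sim + 1)
    outlier_p_bonf = np.minimum(1.0, outlier_p * k)
    outlier_table = pd.DataFrame({
        "snp": snps, "pval": outlier_p, "pval_bonferroni": outlier_p_bonf,
    })
    flagged = outlier_p_bonf < outlier_alpha
    outlier_ids = [str(s) for s in snps[flagged]]

    beta_raw = ivw(h, model=model)
    n_keep = k - len(outlier_ids)
    if n_keep < 2:
        raise InsufficientInstrumentsError(
            "corrected estimate undefined: fewer than 2 variants survive outlier removal"
        )
    beta_corrected = ivw(h.drop(outlier_ids), model=model) if outlier_ids else None

    distortion_pval = float("nan")
    if outlier_ids:
        s = len(outlier_ids)
        d_obs = beta_corrected.beta - beta_raw.beta
        d_sim = np.empty(n_distortion)
        theta = bo / be
        w_ratio = (np.abs(be) / so) ** 2
        for i in range(n_distortion):
            remove = rng.choice(k, size=s, replace=False)
            keep = np.ones(k, dtype=bool)
            keep[remove] = False
            d_sim[i] = (w_ratio[keep] * theta[keep]).sum() / w_ratio[keep].sum() \
                - beta_raw.beta
        distortion_pval = float(
            (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_distortion + 1)
        )

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_table,
        outlier_ids=outlier_ids,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
        audit={"k": k, "n_flagged": len(outlier_ids)},
    )
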