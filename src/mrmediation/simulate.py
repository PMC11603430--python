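"""Tri-trait GWAS summary-statistics simulator with known causal structure.

The generative model is the standard two-step mediation diagram: an exposure
X, a mediator M and a binary outcome Y with

    X: per-SNP marginal effect  gamma_j
    M: b1 * gamma_j + delta_j          (delta_j = direct SNP effect on M)
    Y: (tau + b1*b2) * gamma_j + b2 * delta_j + alpha_pl_j   (log-odds)

so the true total effect of X on Y is ``tau + b1*b2`` and the true proportion
mediated is ``b1*b2 / (tau + b1*b2)``. Two blocks of SNPs are simulated:
``m_snps`` exposure instruments (gamma != 0) and ``m_snps_med`` mediator
instruments (gamma = 0, delta ~ N(0, delta_sd)) that give the mediator its own
genetic architecture, as a real mediator GWAS would. Horizontal pleiotropy
(``pleio_mode``) perturbs the exposure-instrument block: delta (a path to M
not through X) and alpha_pl (a direct path to Y).

Estimated effects are the true marginal effects plus Gaussian noise with the
usual large-sample standard errors for a standardized genotype:

    SE_X = 1/sqrt(n_exp * 2 f (1-f))            (continuous trait, SD units)
    SE_Y = 1/sqrt(n_out * phi (1-phi) * 2 f (1-f))   (binary, log-odds)

where f is the effect-allele frequency and phi the outcome case fraction.
With ``ld_block_size > 1`` the noise is exchangeably correlated (r = ld_rho)
within consecutive blocks, and the LD reference records those correlations.

Defaults emulate the cohorts this pipeline is meant for: a UK-Biobank-scale
sleep trait (n = 300,000), a MiBioGen-scale microbial-abundance mediator
(n = 18,340) and a FinnGen-scale rare binary outcome (n = 314,017, case
fraction 0.004), with effect sizes at the worked-example values b1 = -0.89,
b2 = 0.577, total effect -2.175 (proportion mediated 0.236).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .instruments import LDReference
from .sumstats import CANONICAL_COLUMNS, SumStatsTable, write_sumstats

_BASES = np.array(list("ACGT"))
#: ordered pairs of distinct bases; some are palindromic (A/T, C/G) on purpose
_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass
class SimConfig:
    """Parameters of the tri-trait generative model. See module docstring."""

    m_snps: int = 50            # exposure instruments
    m_snps_med: int = 30        # mediator-specific instruments (gamma = 0)
    n_exp: int = 300_000
    n_med: int = 18_340
    n_out: int = 314_017
    case_fraction_out: float = 0.004
    maf_low: float = 0.05
    maf_high: float = 0.5
    gamma_sd: float = 0.02      # SD of true instrument effects on X
    delta_sd: float = 0.15      # SD of mediator-instrument effects on M
    b1: float = -0.89           # X -> M
    b2: float = 0.577           # M -> Y (log-odds per unit M)
    tau: float = -1.661465      # direct X -> Y (log-odds); total = tau + b1*b2
    pleio_mode: str = "none"    # none | balanced | directional
    pleio_sd: float = 0.0
    pleio_mean: float = 0.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    pos_step_kb: int = 1000     # SNP j at position j * pos_step_kb kb on chr 1
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        if self.m_snps < 2:
            raise ConfigError(f"m_snps must be >= 2, got {self.m_snps}")
        if self.m_snps_med < 0:
            raise ConfigError(f"m_snps_med must be >= 0, got {self.m_snps_med}")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 100:
                raise ConfigError(f"{name} must be >= 100, got {getattr(self, name)}")
        if not 0 < self.case_fraction_out < 1:
            raise ConfigError(
                f"case_fraction_out must be in (0,1), got {self.case_fraction_out}"
            )
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ConfigError(
                f"need 0 < maf_low <= maf_high <= 0.5, got ({self.maf_low}, {self.maf_high})"
            )
        if self.pleio_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleio_mode {self.pleio_mode!r}")
        if self.ld_block_size < 1:
            raise ConfigError(f"ld_block_size must be >= 1, got {self.ld_block_size}")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError(f"ld_rho must be in [0,1), got {self.ld_rho}")
        if self.pos_step_kb < 1:
            raise ConfigError(f"pos_step_kb must be >= 1, got {self.pos_step_kb}")


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulated dataset.

    ``gamma``/``delta``/``alpha_pl`` are per-SNP arrays over all simulated
    SNPs (exposure instruments first, then mediator instruments). ``delta``
    holds every direct SNP effect on the mediator: pleiotropic perturbations
    in the exposure block, the mediator's own instrument effects in the
    mediator block.
    """

    gamma: np.ndarray
    delta: np.ndarray
    alpha_pl: np.ndarray
    b1: float
    b2: float
    tau: float
    total_effect: float = field(init=False)
    true_proportion_mediated: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_effect = self.tau + self.b1 * self.b2
        indirect = self.b1 * self.b2
        if indirect == 0.0:
            self.true_proportion_mediated = 0.0
        elif self.total_effect == 0.0:
            self.true_proportion_mediated = float("nan")
        else:
            self.true_proportion_mediated = indirect / self.total_effect


def _draw_noise(rng, se: np.ndarray, block: int, rho: float) -> np.ndarray:
    """Gaussian estimation noise, exchangeably correlated within LD blocks."""
    m = len(se)
    if block <= 1 or rho == 0.0:
        return rng.normal(0.0, se)
    z = np.empty(m)
    for start in range(0, m, block):
        stop = min(start + block, m)
        k = stop - start
        # exchangeable correlation via shared + idiosyncratic components
        shared = rng.normal()
        own = rng.normal(size=k)
        z[start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    return z * se


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return 2.0 * norm.sf(np.abs(beta) / se)


def simulate_tri_trait(
    config: SimConfig,
) -> tuple[SumStatsTable, SumStatsTable, SumStatsTable, SimTruth, LDReference]:
    """Generate exposure, mediator and outcome summary tables plus truth.

    Returns ``(exposure, mediator, outcome, truth, ld)``. The three tables
    carry identical variants, alleles and effect-allele frequencies; the LD
    reference records r = ld_rho within blocks and 0 across. Identical
    config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m_x, m_m = config.m_snps, config.m_snps_med
    m = m_x + m_m

    maf = rng.uniform(config.maf_low, config.maf_high, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    gamma = np.zeros(m)
    gamma[:m_x] = rng.normal(0.0, config.gamma_sd, size=m_x)
    delta = np.zeros(m)
    alpha_pl = np.zeros(m)
    if config.pleio_mode == "balanced":
        delta[:m_x] = rng.normal(0.0, config.pleio_sd, size=m_x)
        alpha_pl[:] = rng.normal(0.0, config.pleio_sd, size=m)
    elif config.pleio_mode == "directional":
        delta[:m_x] = rng.normal(config.pleio_mean, config.pleio_sd, size=m_x)
        alpha_pl[:] = rng.normal(config.pleio_mean, config.pleio_sd, size=m)
    if m_m:
        delta[m_x:] = rng.normal(0.0, config.delta_sd, size=m_m)

    truth = SimTruth(gamma=gamma, delta=delta, alpha_pl=alpha_pl,
                     b1=config.b1, b2=config.b2, tau=config.tau)

    true_x = gamma
    true_m = config.b1 * gamma + delta
    true_y = truth.total_effect * gamma + config.b2 * delta + alpha_pl

    het = 2.0 * maf * (1.0 - maf)
    phi = config.case_fraction_out
    se_x = 1.0 / np.sqrt(config.n_exp * het)
    se_m = 1.0 / np.sqrt(config.n_med * het)
    se_y = 1.0 / np.sqrt(config.n_out * phi * (1.0 - phi) * het)

    beta_x = true_x + _draw_noise(rng, se_x, config.ld_block_size, config.ld_rho)
    beta_m = true_m + _draw_noise(rng, se_m, config.ld_block_size, config.ld_rho)
    beta_y = true_y + _draw_noise(rng, se_y, config.ld_block_size, config.ld_rho)

    snp_ids = np.array([f"rs{j + 1}" for j in range(m)])
    pos = (np.arange(1, m + 1) * config.pos_step_kb * 1000).astype(np.int64)

    def table(name, ttype, beta, se, n):
        df = pd.DataFrame({
            "snp": snp_ids, "chr": config.chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": maf,
            "beta": beta, "se": se, "pval": _two_sided_p(beta, se),
            "n": np.full(m, n, dtype=np.int64),
        })[CANONICAL_COLUMNS]
        return SumStatsTable(name, ttype, df, provenance="simulated")

    exposure = table("exposure", "continuous", beta_x, se_x, config.n_exp)
    mediator = table("mediator", "continuous", beta_m, se_m, config.n_med)
    outcome = table("outcome", "binary", beta_y, se_y, config.n_out)

    r = np.eye(m)
    if config.ld_block_size > 1:
        for start in range(0, m, config.ld_block_size):
            stop = min(start + config.ld_block_size, m)
            r[start:stop, start:stop] = config.ld_rho
            np.fill_diagonal(r[start:stop, start:stop], 1.0)
    ld = LDReference(snp_ids=list(snp_ids), r=r)

    return exposure, mediator, outcome, truth, ld


def write_fixture_set(config: SimConfig, out_dir) -> dict:
    """Simulate and write the three tables, LD reference and truth to disk.

    Returns a manifest dict (also written as ``manifest.yaml``) listing the
    five data files and the seed. Re-running with the same config reproduces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, mediator, outcome, truth, ld = simulate_tri_trait(config)

    paths = {
        "exposure": out_dir / "exposure.tsv",
        "mediator": out_dir / "mediator.tsv",
        "outcome": out_dir / "outcome.tsv",
        "ld": out_dir / "ld.tsv",
        "truth": out_dir / "truth.yaml",
    }
    write_sumstats(exposure, paths["exposure"])
    write_sumstats(mediator, paths["mediator"])
    write_sumstats(outcome, paths["outcome"])
    ld.write(paths["ld"])

    truth_doc = {
        "b1": truth.b1, "b2": truth.b2, "tau": truth.tau,
        "total_effect": truth.total_effect,
        "true_proportion_mediated": truth.true_proportion_mediated,
        "gamma": [float(v) for v in truth.gamma],
        "delta": [float(v) for v in truth.delta],
        "alpha_pl": [float(v) for v in truth.alpha_pl],
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "files": {k: str(v) for k, v in paths.items()},
        "sha256": {k: _sha256(v) for k, v in paths.items()},
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
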