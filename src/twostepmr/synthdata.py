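"""Synthetic tripartite GWAS summary statistics with known truth.

Emulates the statistical shape of a two-step MR study: three independent
cohorts measuring an exposure (a quantitative lipid trait), a mediator (an
immune-cell trait), and a binary outcome (log-odds scale), each reporting
per-SNP effect estimates, SEs and p-values.  The structural model is

    X = sum_j gamma_j G_j + e_x
    M = alpha X + sum_k delta_k G_k + e_m
    Y = tau' X + b_m M + pleiotropy + e_y   (log-odds scale)

so the marginal SNP effects are gamma_j on X; alpha*gamma_j and delta_k on
M; (tau' + b_m alpha) gamma_j + pleio_j and b_m delta_k on Y.  Estimated
betas are drawn as b_hat = b_true + N(0, se) with se = 1/sqrt(2 maf (1-maf)
n); the three cohorts use independent noise (no sample overlap).  The
binary outcome is simulated directly at the summary-statistic level, with
``n_out`` interpreted as an effective sample size.

Truth (the realized gamma vector, alpha, b_m, tau', the total effect and
the true mediated proportion) is returned alongside, so every pipeline
stage is testable without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats as st

from .exceptions import ConfigurationError
from .instruments import LDMatrix
from .sumstats import SummaryStatRecord

_NONPALINDROMIC_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SyntheticConfig:
    """Generating parameters of a synthetic two-step MR scenario.

    Defaults emulate a large modern lipidomics GWAS for the exposure
    (n=100,000), a flow-cytometry immune-trait GWAS of 3,757 individuals
    with pQTL-scale instrument effects, and a case-control outcome study
    expressed as an effective sample size of ~31,400 (the
    4/(1/cases+1/controls) equivalent of roughly 8,000 cases against
    391,000 controls).
    """

    n_snp_exposure: int = 30
    n_snp_mediator: int = 30
    gamma_dist: tuple[float, float] = (0.2, 0.05)
    delta_dist: tuple[float, float] = (0.35, 0.10)
    alpha: float = 0.4
    b_m: float = 0.25
    tau_direct: float = 0.1
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exp: int = 100_000
    n_med: int = 3_757
    n_out: int = 31_430
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_blocks: Sequence[tuple[int, float]] | None = None  # (size, within-block r2)
    palindrome_fraction: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_snp_exposure < 1 or self.n_snp_mediator < 1:
            raise ConfigurationError("instrument counts must be >= 1")
        if min(self.n_exp, self.n_med, self.n_out) < 100:
            raise ConfigurationError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy kind {self.pleiotropy!r}")
        if not (0 <= self.palindrome_fraction <= 1):
            raise ConfigurationError("palindrome_fraction must be in [0, 1]")
        if self.ld_blocks is not None:
            for size, r2 in self.ld_blocks:
                if size < 1 or not (0 <= r2 <= 1):
                    raise ConfigurationError("ld_blocks entries must be (size>=1, r2 in [0,1])")


@dataclass
class SimulationTruth:
    """The generating parameters realized in one simulated scenario."""

    gamma: np.ndarray
    delta: np.ndarray
    alpha: float
    b_m: float
    tau_direct: float
    total_effect: float = field(init=False)
    mediated_proportion_true: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_effect = self.tau_direct + self.alpha * self.b_m
        self.mediated_proportion_true = (
            self.alpha * self.b_m / self.total_effect if self.total_effect != 0 else float("nan")
        )


def _variant_ids(config: SyntheticConfig) -> list[str]:
    total = config.n_snp_exposure + config.n_snp_mediator
    return [f"rs{i + 1:05d}" for i in range(total)]


def _exposure_block_sizes(config: SyntheticConfig) -> list[int]:
    """Block sizes covering the exposure instruments (singletons by default)."""
    if config.ld_blocks is None:
        return [1] * config.n_snp_exposure
    sizes = [size for size, _ in config.ld_blocks]
    if sum(sizes) != config.n_snp_exposure:
        raise ConfigurationError("ld_blocks sizes must sum to n_snp_exposure")
    return sizes


def simulate_tripartite(
    config: SyntheticConfig | None = None,
) -> tuple[
    list[SummaryStatRecord], list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth
]:
    """Simulate exposure, mediator and outcome GWAS over a shared SNP panel.

    Returns three record lists (one per cohort, covering all SNPs) and the
    :class:`SimulationTruth`.  Deterministic given ``config.seed``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n_e, n_m = config.n_snp_exposure, config.n_snp_mediator
    total = n_e + n_m
    ids = _variant_ids(config)

    gamma = rng.normal(*config.gamma_dist, size=n_e)
    # within an LD block the member SNPs tag one shared causal signal
    block_sizes = _exposure_block_sizes(config)
    pos0 = 0
    for size in block_sizes:
        gamma[pos0 : pos0 + size] = gamma[pos0]
        pos0 += size
    delta = rng.normal(*config.delta_dist, size=n_m)

    if config.pleiotropy == "none":
        pleio = np.zeros(n_e)
    elif config.pleiotropy == "balanced":
        pleio = rng.normal(0.0, config.pleiotropy_sd, size=n_e)
    else:
        pleio = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_e)

    maf = rng.uniform(*config.maf_range, size=total)
    palindromic = rng.random(total) < config.palindrome_fraction
    pair_pick = rng.integers(0, 4, size=total)
    alleles = [
        _PALINDROMIC_PAIRS[pair_pick[i]] if palindromic[i] else _NONPALINDROMIC_PAIRS[pair_pick[i]]
        for i in range(total)
    ]

    # marginal SNP effects per trait
    b_exp = np.concatenate([gamma, np.zeros(n_m)])
    b_med = np.concatenate([config.alpha * gamma, delta])
    b_out = np.concatenate(
        [(config.tau_direct + config.b_m * config.alpha) * gamma + pleio, config.b_m * delta]
    )

    def study(b_true: np.ndarray, n: int) -> list[SummaryStatRecord]:
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
        bhat = b_true + rng.normal(0.0, se)
        pval = np.clip(2.0 * st.norm.sf(np.abs(bhat) / se), np.finfo(float).tiny, 1.0)
        eaf = np.clip(maf + rng.normal(0.0, 0.005, size=total), 0.001, 0.999)
        return [
            SummaryStatRecord(
                variant_id=ids[i],
                effect_allele=alleles[i][0],
                other_allele=alleles[i][1],
                beta=float(bhat[i]),
                se=float(se[i]),
                pval=float(pval[i]),
                eaf=float(eaf[i]),
                n=float(n),
                chrom="1",
                pos=1_000_000 * (i + 1),
            )
            for i in range(total)
        ]

    exposure = study(b_exp, config.n_exp)
    mediator = study(b_med, config.n_med)
    outcome = study(b_out, config.n_out)
    truth = SimulationTruth(
        gamma=gamma, delta=delta, alpha=config.alpha, b_m=config.b_m,
        tau_direct=config.tau_direct,
    )
    return exposure, mediator, outcome, truth


def simulate_ld(config: SyntheticConfig | None = None) -> LDMatrix:
    """Block-diagonal r^2 matrix matching :func:`simulate_tripartite` IDs.

    Within-block r^2 is constant at the configured value, between-block 0;
    mediator instruments are singleton blocks.
    """
    config = config or SyntheticConfig()
    if config.ld_blocks is None:
        raise ConfigurationError("simulate_ld requires ld_blocks in the config")
    ids = _variant_ids(config)
    total = len(ids)
    r2 = np.eye(total)
    pos0 = 0
    for size, block_r2 in config.ld_blocks:
        block = slice(pos0, pos0 + size)
        sub = np.full((size, size), block_r2)
        np.fill_diagonal(sub, 1.0)
        r2[block, block] = sub
        pos0 += size
    return LDMatrix(variant_ids=ids, r2=r2)


def inject_outlier(
    stats: Sequence[SummaryStatRecord], index: int, shift_in_se_units: float
) -> list[SummaryStatRecord]:
    """Displace one record's beta by ``shift * se``; everything else unchanged."""
    if not (0 <= index < len(stats)):
        raise ValueError(f"index {index} out of range for {len(stats)} records")
    out = list(stats)
    rec = out[index]
    out[index] = dataclasses.replace(rec, beta=rec.beta + shift_in_se_units * rec.se)
    return out
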