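"""Heterogeneity, pleiotropy, leave-one-out and MR-PRESSO diagnostics.

These checks probe the exclusion-restriction assumption: Cochran's Q
measures dispersion of the per-SNP ratios around the IVW estimate, the
Egger intercept tests for directional pleiotropy, leave-one-out looks for
single driving SNPs, and MR-PRESSO detects and removes outlying
instruments by comparing observed residual sums of squares with a
parametric simulation under the no-pleiotropy model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st

from .estimators import EggerEstimate, MREstimate, ivw
from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .sumstats import HarmonizedSet


@dataclass
class HeterogeneityReport:
    """Cochran's Q against the IVW consensus."""

    q: float
    df: int
    pval: float

    @property
    def heterogeneity_present(self) -> bool:
        return self.pval < 0.05


def cochran_q(h: HarmonizedSet, beta_ivw: float) -> HeterogeneityReport:
    """Q = sum w_j (ratio_j - beta_ivw)^2 with w_j = b_x^2/s_y^2; upper-tail
    chi-square p on n-1 df."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("cochran_q requires >= 2 instruments")
    w = h.beta_exposure**2 / h.se_outcome**2
    ratios = h.beta_outcome / h.beta_exposure
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    df = h.n_snp - 1
    return HeterogeneityReport(q=q, df=df, pval=float(st.chi2.sf(q, df)))


@dataclass
class PleiotropyTest:
    """Egger-intercept directional-pleiotropy test."""

    intercept_pval: float
    pleiotropy_present: bool  # p < alpha
    passes_screen: bool  # screening requires p strictly > 0.05


def egger_intercept_test(e: EggerEstimate, alpha: float = 0.05) -> PleiotropyTest:
    p = e.intercept_pval
    return PleiotropyTest(
        intercept_pval=p,
        pleiotropy_present=p < alpha,
        passes_screen=p > alpha,
    )


@dataclass
class LeaveOneOutEntry:
    omitted_variant_id: str
    beta: float
    se: float
    pval: float


@dataclass
class LeaveOneOutResult:
    entries: list[LeaveOneOutEntry]
    full: MREstimate
    driving_variants: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "omitted_variant_id": e.omitted_variant_id,
                    "beta": e.beta,
                    "se": e.se,
                    "pval": e.pval,
                    "driving": e.omitted_variant_id in self.driving_variants,
                }
                for e in self.entries
            ]
        )


def leave_one_out(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> LeaveOneOutResult:
    """IVW re-fits omitting each instrument in turn.

    A SNP is flagged as "driving" when its omission flips the sign of the
    estimate or moves the p-value across 0.05.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("leave_one_out requires >= 3 instruments")
    full = ivw(h, effects_model=effects_model)
    entries = []
    driving = []
    for j in range(h.n_snp):
        mask = np.ones(h.n_snp, dtype=bool)
        mask[j] = False
        est = ivw(h.subset(mask), effects_model=effects_model)
        entries.append(
            LeaveOneOutEntry(str(h.variant_id[j]), est.beta, est.se, est.pval)
        )
        sign_flip = np.sign(est.beta) != np.sign(full.beta)
        p_cross = (est.pval - 0.05) * (full.pval - 0.05) < 0
        if sign_flip or p_cross:
            driving.append(str(h.variant_id[j]))
    return LeaveOneOutResult(entries=entries, full=full, driving_variants=driving)


@dataclass
class PressoReport:
    """MR-PRESSO global, outlier and distortion test results."""

    global_pval: float
    outlier_indices: list[int]
    outlier_pvals: np.ndarray
    corrected_estimate: Optional[MREstimate]
    distortion_pval: Optional[float]
    rss_observed: float = field(default=math.nan)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out IVW slopes, one per SNP.

    ``by`` may be 1-D (observed) or 2-D (n_sim x n) for simulated data.
    """
    s2 = np.sum(w * bx**2)
    s1 = (w * bx * by).sum(axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 42,
    effects_model: str = "multiplicative_random",
) -> PressoReport:
    """Pleiotropy residual sum of squares and outlier test.

    Global test: the observed weighted RSS of leave-one-out IVW predictions
    is ranked within the RSS distribution of ``n_sim`` parametric
    simulations of the outcome betas under the no-pleiotropy model.
    Outlier test: each SNP's observed squared residual is ranked within its
    simulated residual tail, Bonferroni-adjusted over the instrument count.
    Distortion test: the shift between the full and outlier-corrected IVW
    estimates is ranked against the shift from removing random non-outlier
    subsets of the same size.  Deterministic given ``seed``.
    """
    if n_sim <= 0:
        raise ConfigurationError("n_sim must be > 0")
    if h.n_snp < 4:
        raise InsufficientInstrumentsError("mr_presso requires >= 4 instruments")
    rng = np.random.default_rng(seed)
    bx, by = h.beta_exposure, h.beta_outcome
    sy = h.se_outcome
    w = 1.0 / sy**2
    n = h.n_snp

    beta_loo = _loo_slopes(bx, by, w)
    resid_obs = by - beta_loo * bx
    rss_obs = float(np.sum(w * resid_obs**2))

    # parametric simulation under the no-pleiotropy model
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, n))
    beta_loo_sim = _loo_slopes(bx, by_sim, w)
    resid_sim = by_sim - beta_loo_sim * bx
    rss_sim = np.sum(w * resid_sim**2, axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    # per-SNP outlier test on weighted squared residuals
    exceed = np.sum(w * resid_sim**2 >= w * resid_obs**2, axis=0)
    outlier_pvals = exceed / n_sim
    adjusted = np.minimum(outlier_pvals * n, 1.0)
    outlier_indices = [int(i) for i in np.flatnonzero(adjusted < outlier_alpha)]

    corrected = None
    distortion_pval = None
    if outlier_indices and n - len(outlier_indices) >= 2:
        keep = np.setdiff1d(np.arange(n), outlier_indices)
        corrected = ivw(h.subset(keep), effects_model=effects_model)
        full = ivw(h, effects_model=effects_model)
        if corrected.beta != 0:
            obs_distortion = abs(full.beta - corrected.beta)
            n_draw = min(n_sim, 1000)
            draws = np.empty(n_draw)
            for i in range(n_draw):
                sub = rng.choice(keep, size=len(keep), replace=True)
                s1 = np.sum(w[sub] * bx[sub] * by[sub])
                s2 = np.sum(w[sub] * bx[sub] ** 2)
                draws[i] = abs(s1 / s2 - corrected.beta)
            distortion_pval = float((1 + np.sum(draws >= obs_distortion)) / (n_draw + 1))
    return PressoReport(
        global_pval=global_pval,
        outlier_indices=outlier_indices,
        outlier_pvals=np.asarray(outlier_pvals),
        corrected_estimate=corrected,
        distortion_pval=distortion_pval,
        rss_observed=rss_obs,
    )


def scatter_data(h: HarmonizedSet, fitted: dict[str, MREstimate] | None = None) -> pd.DataFrame:
    """Tabular equivalent of the MR scatter plot: b_x vs b_y with SEs, plus
    one fitted-line slope column per supplied method estimate."""
    df = h.to_frame()
    if fitted:
        for name, est in fitted.items():
            df[f"fit_{name}"] = est.beta * h.beta_exposure
    return df


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Tabular equivalent of the funnel plot: Wald ratio vs its precision."""
    ratios = h.beta_outcome / h.beta_exposure
    ratio_se = h.se_outcome / np.abs(h.beta_exposure)
    return pd.DataFrame(
        {"variant_id": h.variant_id, "ratio": ratios, "precision": 1.0 / ratio_se}
    )
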