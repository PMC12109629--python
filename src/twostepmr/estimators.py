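"""The five two-sample MR estimators, Wald ratios, and the OR scale.

Every method combines per-SNP Wald ratios (outcome beta over exposure beta)
under different robustness assumptions:

* inverse-variance weighted (IVW) — weighted regression of outcome on
  exposure betas through the origin; unbiased when no instrument is
  pleiotropic; the primary method.
* MR-Egger — the same regression with a free intercept; the slope is robust
  to directional pleiotropy under the InSIDE assumption and the intercept
  is a pleiotropy test.
* weighted median — consistent when instruments carrying >= 50% of the
  weight are valid.
* simple / weighted mode — consistent when the largest group of instruments
  with equal ratios is valid (zero modal pleiotropy assumption).

Estimators are scikit-learn style: construct with hyper-parameters, call
``fit`` on a :class:`~twostepmr.sumstats.HarmonizedSet`, read fitted
attributes (``beta_``, ``se_``, ``pval_``, ...).  Module-level functions
(:func:`ivw`, :func:`egger`, ...) are thin wrappers that return the
:class:`MREstimate` directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    NoInstrumentsError,
)
from .sumstats import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = float(st.norm.ppf(0.975))


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * st.norm.sf(abs(beta) / se))


def _t_p(beta: float, se: float, df: int) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * st.t.sf(abs(beta) / se, df=df))


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, lower 95%, upper 95%)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds (or trait-unit) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    or_: float = field(default=math.nan)
    or_low: float = field(default=math.nan)
    or_high: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se
        if math.isnan(self.or_):
            self.or_, self.or_low, self.or_high = to_odds_ratio(self.beta, self.se)


@dataclass
class EggerEstimate(MREstimate):
    """MR-Egger slope plus the pleiotropy intercept test."""

    intercept: float = 0.0
    intercept_se: float = 0.0
    intercept_pval: float = 1.0


def wald_ratio(b_x: float, s_x: float, b_y: float, s_y: float) -> MREstimate:
    """Single-SNP causal estimate b_y/b_x with first-order se s_y/|b_x|."""
    if b_x == 0:
        raise DegenerateInstrumentError("wald_ratio undefined for b_x = 0")
    beta = b_y / b_x
    se = s_y / abs(b_x)
    return MREstimate("wald_ratio", beta, se, _normal_p(beta, se), n_snp=1)


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order standard errors."""
    if np.any(h.beta_exposure == 0):
        raise DegenerateInstrumentError("ratio undefined: some b_x = 0")
    return h.beta_outcome / h.beta_exposure, h.se_outcome / np.abs(h.beta_exposure)


def ivw_sums(h: HarmonizedSet) -> tuple[float, float]:
    """The two weighted sums of the IVW closed form: (sum w*bx*by, sum w*bx^2)."""
    w = 1.0 / h.se_outcome**2
    return float(np.sum(w * h.beta_exposure * h.beta_outcome)), float(
        np.sum(w * h.beta_exposure**2)
    )


class _SummaryMREstimator(BaseEstimator):
    """Shared fit/validation machinery for the summary-data MR estimators."""

    _min_snp: int = 1
    _method: str = ""

    def fit(self, X: HarmonizedSet, y=None):
        h = self._coerce(X)
        if h.n_snp < self._min_snp:
            raise InsufficientInstrumentsError(
                f"{self._method} requires >= {self._min_snp} instruments, got {h.n_snp}"
            )
        est = self._fit(h)
        self.estimate_ = est
        self.beta_ = est.beta
        self.se_ = est.se
        self.pval_ = est.pval
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        self.n_snp_ = est.n_snp
        return self

    @staticmethod
    def _coerce(X) -> HarmonizedSet:
        if isinstance(X, HarmonizedSet):
            return X
        if isinstance(X, pd.DataFrame):
            return HarmonizedSet.from_frame(X)
        raise TypeError("expected a HarmonizedSet or a harmonized DataFrame")

    def _fit(self, h: HarmonizedSet) -> MREstimate:  # pragma: no cover - abstract
        raise NotImplementedError


class InverseVarianceWeighted(_SummaryMREstimator):
    """IVW: weighted regression of b_y on b_x through the origin, weights 1/s_y^2.

    ``effects_model="multiplicative_random"`` (default) inflates the fixed-
    effects SE by sqrt(Q/(n-1)) when the instruments are overdispersed;
    ``"fixed"`` never inflates.  A single instrument falls back to the Wald
    ratio (logged).
    """

    _min_snp = 1
    _method = "ivw"

    def __init__(self, effects_model: str = "multiplicative_random"):
        self.effects_model = effects_model

    def _fit(self, h: HarmonizedSet) -> MREstimate:
        if h.n_snp == 0:
            raise NoInstrumentsError("no instruments for IVW")
        if h.n_snp == 1:
            logger.info("ivw: single instrument, falling back to Wald ratio")
            est = wald_ratio(
                h.beta_exposure[0], h.se_exposure[0], h.beta_outcome[0], h.se_outcome[0]
            )
            return MREstimate("ivw", est.beta, est.se, est.pval, n_snp=1)
        s1, s2 = ivw_sums(h)
        beta = s1 / s2
        se = 1.0 / math.sqrt(s2)
        if self.effects_model == "multiplicative_random":
            w = 1.0 / h.se_outcome**2
            q = float(np.sum(w * (h.beta_outcome - beta * h.beta_exposure) ** 2))
            overdispersion = q / (h.n_snp - 1)
            if overdispersion > 1.0:
                se *= math.sqrt(overdispersion)
        elif self.effects_model != "fixed":
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        return MREstimate("ivw", beta, se, _normal_p(beta, se), n_snp=h.n_snp)


class EggerRegression(_SummaryMREstimator):
    """MR-Egger: weighted regression of b_y on b_x with a free intercept.

    Each SNP is oriented so b_x >= 0 before fitting (standard
    identification convention).  SEs use the multiplicative random-effects
    convention se_fixed * max(1, sigma); p-values are t with n-2 df.
    """

    _min_snp = 3
    _method = "egger"

    def _fit(self, h: HarmonizedSet) -> EggerEstimate:
        flip = np.where(h.beta_exposure < 0, -1.0, 1.0)
        bx = h.beta_exposure * flip
        by = h.beta_outcome * flip
        w = 1.0 / h.se_outcome**2
        design = sm.add_constant(bx, has_constant="add")
        res = sm.WLS(by, design, weights=w).fit()
        sigma = math.sqrt(max(res.scale, 0.0))
        se_fixed = np.sqrt(np.diag(res.normalized_cov_params))
        inflate = max(1.0, sigma)
        intercept, slope = res.params
        se_int, se_slope = se_fixed * inflate
        df = h.n_snp - 2
        return EggerEstimate(
            method="egger",
            beta=float(slope),
            se=float(se_slope),
            pval=_t_p(slope, se_slope, df),
            n_snp=h.n_snp,
            intercept=float(intercept),
            intercept_se=float(se_int),
            intercept_pval=_t_p(intercept, se_int, df),
        )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value where the normalized cumulative weight crosses 0.5, with linear
    interpolation between the bracketing ratios."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


class WeightedMedian(_SummaryMREstimator):
    """Weighted median of Wald ratios, weights 1/se(ratio)^2.

    The SE comes from a parametric bootstrap: exposure and outcome betas are
    resampled from normal(b, s) ``n_boot`` times with a fixed seed.
    """

    _min_snp = 3
    _method = "weighted_median"

    def __init__(self, n_boot: int = 1000, seed: int = 42):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, h: HarmonizedSet) -> MREstimate:
        ratios, ratio_se = _ratios(h)
        weights = 1.0 / ratio_se**2
        beta = _weighted_median(ratios, weights)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            bx = rng.normal(h.beta_exposure, h.se_exposure)
            by = rng.normal(h.beta_outcome, h.se_outcome)
            bx = np.where(bx == 0, np.finfo(float).tiny, bx)
            r = by / bx
            w = (np.abs(bx) / h.se_outcome) ** 2
            boots[i] = _weighted_median(r, w)
        se = float(np.std(boots, ddof=1)) if self.n_boot > 1 else 0.0
        return MREstimate("weighted_median", beta, se, _normal_p(beta, se), n_snp=h.n_snp)


def _silverman_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule on the ratio distribution (0 if degenerate)."""
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(st.median_abs_deviation(ratios, scale="normal"))
    return factor * 0.9 * min(sd, mad) * n ** (-0.2)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float, n_grid: int = 512) -> float:
    """Argmax of the weighted Gaussian KDE; discrete weighted mode when the
    bandwidth degenerates (ties broken toward the smallest ratio)."""
    if h <= 0 or not math.isfinite(h):
        uniq = np.unique(ratios)
        totals = np.array([weights[ratios == u].sum() for u in uniq])
        return float(uniq[np.argmax(totals)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)
    dens = (weights[:, None] * dens).sum(axis=0)
    return float(grid[np.argmax(dens)])


class ModeBased(_SummaryMREstimator):
    """Simple or weighted mode of the Wald-ratio density.

    ``variant="simple"`` uses equal weights; ``"weighted"`` uses
    1/se(ratio)^2.  Bandwidth is ``bandwidth_factor`` times the modified
    Silverman rule; SE by parametric bootstrap with a fixed seed.
    """

    _min_snp = 3

    def __init__(
        self,
        variant: str = "simple",
        bandwidth_factor: float = 1.0,
        n_boot: int = 1000,
        seed: int = 42,
    ):
        self.variant = variant
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed

    @property
    def _method(self) -> str:  # type: ignore[override]
        return f"{self.variant}_mode"

    def _fit(self, h: HarmonizedSet) -> MREstimate:
        if self.variant not in ("simple", "weighted"):
            raise ValueError(f"unknown mode variant {self.variant!r}")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be > 0")
        ratios, ratio_se = _ratios(h)

        def weights_for(r: np.ndarray, r_se: np.ndarray) -> np.ndarray:
            if self.variant == "weighted":
                return 1.0 / r_se**2
            return np.ones_like(r)

        bw = _silverman_bandwidth(ratios, self.bandwidth_factor)
        beta = _kde_mode(ratios, weights_for(ratios, ratio_se), bw)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            bx = rng.normal(h.beta_exposure, h.se_exposure)
            by = rng.normal(h.beta_outcome, h.se_outcome)
            bx = np.where(bx == 0, np.finfo(float).tiny, bx)
            r = by / bx
            r_se = h.se_outcome / np.abs(bx)
            boots[i] = _kde_mode(r, weights_for(r, r_se), _silverman_bandwidth(r, self.bandwidth_factor))
        se = float(np.std(boots, ddof=1)) if self.n_boot > 1 else 0.0
        return MREstimate(self._method, beta, se, _normal_p(beta, se), n_snp=h.n_snp)


def ivw(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MREstimate:
    return InverseVarianceWeighted(effects_model=effects_model).fit(h).estimate_


def egger(h: HarmonizedSet) -> EggerEstimate:
    return EggerRegression().fit(h).estimate_


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 42) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(h).estimate_


def mode_estimator(
    h: HarmonizedSet,
    variant: str = "simple",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 42,
) -> MREstimate:
    return (
        ModeBased(variant=variant, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed)
        .fit(h)
        .estimate_
    )


@dataclass
class MRConfig:
    """Estimator and pipeline settings shared across methods."""

    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    n_sim: int = 1000
    seed: int = 42
    presso_clean: bool = True
    presso_outlier_alpha: float = 0.05


@dataclass
class MethodBundle:
    """Results of all five methods on one harmonized pair (IVW primary)."""

    ivw: MREstimate
    egger: Optional[EggerEstimate] = None
    weighted_median: Optional[MREstimate] = None
    weighted_mode: Optional[MREstimate] = None
    simple_mode: Optional[MREstimate] = None
    notes: list[str] = field(default_factory=list)

    @property
    def estimates(self) -> dict[str, MREstimate]:
        out = {"ivw": self.ivw}
        for name in ("egger", "weighted_median", "weighted_mode", "simple_mode"):
            est = getattr(self, name)
            if est is not None:
                out[name] = est
        return out

    @property
    def complete(self) -> bool:
        return len(self.estimates) == 5

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": est.method,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "or_": est.or_,
                "or_low": est.or_low,
                "or_high": est.or_high,
            }
            for est in self.estimates.values()
        ]
        return pd.DataFrame(rows)


def run_all_methods(h: HarmonizedSet, config: MRConfig | None = None) -> MethodBundle:
    """Run the five-method suite; degrade gracefully below three instruments."""
    cfg = config or MRConfig()
    primary = ivw(h, effects_model=cfg.effects_model)
    bundle = MethodBundle(ivw=primary)
    if h.n_snp < 3:
        bundle.notes.append(
            f"only {h.n_snp} instrument(s): Egger/median/mode require >= 3, reported absent"
        )
        return bundle
    bundle.egger = egger(h)
    bundle.weighted_median = weighted_median(h, n_boot=cfg.n_boot, seed=cfg.seed)
    bundle.weighted_mode = mode_estimator(
        h, variant="weighted", bandwidth_factor=cfg.bandwidth_factor, n_boot=cfg.n_boot, seed=cfg.seed
    )
    bundle.simple_mode = mode_estimator(
        h, variant="simple", bandwidth_factor=cfg.bandwidth_factor, n_boot=cfg.n_boot, seed=cfg.seed
    )
    return bundle
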