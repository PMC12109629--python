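"""Two-step MR mediation: product of coefficients, screening, proportions.

The headline computation: the effect of an exposure (a lipid species) on a
binary outcome (osteoporosis, log-odds scale) is decomposed through a
mediator (an immune-cell trait).  Step 1 estimates the exposure->mediator
effect (Beta X) by IVW on the exposure's instruments; step 2 estimates the
mediator->outcome effect (Beta Y) on the mediator's instruments.  The
mediated effect is the product Beta XY = Beta X * Beta Y; its uncertainty
comes from the delta method, and the mediated proportion is Beta XY over
the total exposure->outcome effect.  A screening cascade (IVW p cutoff,
direction concordance across all five methods, Egger-intercept pleiotropy
test, Bonferroni verdict) narrows many candidate pairs to the few carried
into mediation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .estimators import (
    MethodBundle,
    MRConfig,
    MREstimate,
    ivw,
    run_all_methods,
)
from .exceptions import ConfigurationError, NoInstrumentsError
from .instruments import InstrumentCriteria, LDMatrix, clump, select_significant
from .sensitivity import mr_presso
from .sumstats import HarmonizedSet, SummaryStatRecord, harmonize


def mediated_effect(beta_x: float, beta_y: float) -> float:
    """Product-of-coefficients mediated effect, Beta XY = Beta X * Beta Y."""
    return beta_x * beta_y


def mediation_ci(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Delta-method SE and CI for the product of two independent estimates.

    Variance = beta_x^2 se_y^2 + beta_y^2 se_x^2 (first-order; the
    second-order se_x^2 se_y^2 term is omitted).  Returns
    (se_xy, ci_low, ci_high).
    """
    if se_x < 0 or se_y < 0:
        raise ValueError("standard errors must be >= 0")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = float(st.norm.ppf(0.5 + level / 2.0))
    beta_xy = mediated_effect(beta_x, beta_y)
    se_xy = math.sqrt(beta_x**2 * se_y**2 + beta_y**2 * se_x**2)
    return se_xy, beta_xy - z * se_xy, beta_xy + z * se_xy


def mediated_proportion(
    beta_xy: float,
    beta_total: float,
    product_ci: tuple[float, float] | None = None,
) -> tuple[float, Optional[tuple[float, float]]]:
    """Mediated proportion Beta XY / total effect (a fraction; may be
    negative or exceed 1).

    The proportion CI divides the product-CI bounds by the total-effect
    point estimate, preserving division order (uncertainty in the total is
    ignored).
    """
    if beta_total == 0:
        raise ValueError("mediated proportion undefined for zero total effect")
    prop = beta_xy / beta_total
    ci = None
    if product_ci is not None:
        ci = (product_ci[0] / beta_total, product_ci[1] / beta_total)
    return prop, ci


@dataclass
class MediationResult:
    """Full two-step decomposition for one exposure/mediator/outcome triple."""

    exposure: str
    mediator: str
    outcome: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    beta_total: float
    se_total: float
    beta_xy: float = field(init=False)
    beta_xy_se: float = field(init=False)
    beta_xy_ci: tuple[float, float] = field(init=False)
    direct_effect: float = field(init=False)
    mediated_proportion: float = field(init=False)
    proportion_ci: tuple[float, float] = field(init=False)
    n_snp_x: int = 0
    n_snp_y: int = 0
    n_snp_total: int = 0

    def __post_init__(self) -> None:
        self.beta_xy = mediated_effect(self.beta_x, self.beta_y)
        self.beta_xy_se, lo, hi = mediation_ci(self.beta_x, self.se_x, self.beta_y, self.se_y)
        self.beta_xy_ci = (lo, hi)
        self.direct_effect = self.beta_total - self.beta_xy
        prop, ci = mediated_proportion(self.beta_xy, self.beta_total, self.beta_xy_ci)
        self.mediated_proportion = prop
        self.proportion_ci = ci

    def label(self) -> str:
        """Human-readable classification of the mediation pattern.

        "partial" when the mediated effect shares the total effect's sign
        (a positive proportion), "attenuating" when it opposes it; the
        "negative" qualifier marks a negative mediated effect, i.e. the two
        step estimates have opposed signs.
        """
        base = "partial" if self.mediated_proportion > 0 else "attenuating"
        sign = "negative" if self.beta_xy < 0 else "positive"
        return f"{base} {sign} mediation"

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta_x": self.beta_x,
            "se_x": self.se_x,
            "beta_y": self.beta_y,
            "se_y": self.se_y,
            "beta_total": self.beta_total,
            "se_total": self.se_total,
            "mediated_effect": self.beta_xy,
            "mediated_low": self.beta_xy_ci[0],
            "mediated_up": self.beta_xy_ci[1],
            "direct_effect": self.direct_effect,
            "mediated_proportion": self.mediated_proportion,
            "proportion_low": self.proportion_ci[0],
            "proportion_up": self.proportion_ci[1],
            "label": self.label(),
        }


_MEDIATION_COLUMNS = [
    "exposure", "mediator", "outcome", "beta_x", "se_x", "beta_y", "se_y",
    "beta_total", "se_total", "mediated_effect", "mediated_low", "mediated_up",
    "direct_effect", "mediated_proportion", "proportion_low", "proportion_up", "label",
]


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Report table mirroring a mediated-effects summary (one row per triple)."""
    return pd.DataFrame([r.to_row() for r in results], columns=_MEDIATION_COLUMNS)


@dataclass
class ScreenCriteria:
    """The three-part retention rule applied to each candidate pair."""

    ivw_p_max: float = 0.05
    require_direction_concordance: bool = True
    egger_intercept_p_min: float = 0.05
    bonferroni_n: int = 1
    family_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("ivw_p_max", "egger_intercept_p_min", "family_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.bonferroni_n < 1:
            raise ConfigurationError("bonferroni_n must be >= 1")


@dataclass
class ScreenOutcome:
    pair_id: str
    p_pass: bool
    direction_pass: bool
    pleiotropy_pass: bool
    verdict: str  # fail | suggestive | significant
    ivw_pval: float
    het_pval: Optional[float] = None


def screen_pair(
    bundle: MethodBundle,
    het=None,
    egger_p: float | None = None,
    criteria: ScreenCriteria | None = None,
    pair_id: str = "",
) -> ScreenOutcome:
    """Apply the retention criteria to one pair's five-method results.

    Passing requires IVW p below ``ivw_p_max``, concordant effect
    directions across all five methods, and an Egger intercept p strictly
    above ``egger_intercept_p_min``.  Passing pairs are "significant" below
    the Bonferroni-corrected level ``family_alpha/bonferroni_n`` and
    "suggestive" otherwise.
    """
    criteria = criteria or ScreenCriteria()
    p = bundle.ivw.pval
    p_pass = p < criteria.ivw_p_max
    if criteria.require_direction_concordance:
        betas = [est.beta for est in bundle.estimates.values()]
        direction_pass = bundle.complete and (all(b > 0 for b in betas) or all(b < 0 for b in betas))
    else:
        direction_pass = True
    if egger_p is None and bundle.egger is not None:
        egger_p = bundle.egger.intercept_pval
    pleiotropy_pass = egger_p is not None and egger_p > criteria.egger_intercept_p_min
    if not (p_pass and direction_pass and pleiotropy_pass):
        verdict = "fail"
    elif p < criteria.family_alpha / criteria.bonferroni_n:
        verdict = "significant"
    else:
        verdict = "suggestive"
    het_pval = getattr(het, "pval", het)
    return ScreenOutcome(
        pair_id=pair_id,
        p_pass=p_pass,
        direction_pass=direction_pass,
        pleiotropy_pass=pleiotropy_pass,
        verdict=verdict,
        ivw_pval=p,
        het_pval=het_pval,
    )


def screen_table(outcomes: Sequence[ScreenOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": o.pair_id,
                "ivw_pval": o.ivw_pval,
                "p_pass": o.p_pass,
                "direction_pass": o.direction_pass,
                "pleiotropy_pass": o.pleiotropy_pass,
                "het_pval": o.het_pval,
                "verdict": o.verdict,
            }
            for o in outcomes
        ]
    )


def _prepare_stage(
    iv_source: Sequence[SummaryStatRecord],
    outcome_stats: Sequence[SummaryStatRecord],
    criteria: InstrumentCriteria,
    config: MRConfig,
    ld: LDMatrix | None,
    stage: str,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Select, clump, harmonize, PRESSO-clean and F-filter one stage."""
    sig = select_significant(iv_source, criteria.p_threshold)
    if not sig:
        raise NoInstrumentsError(f"{stage}: no genome-wide-significant instruments")
    if ld is not None:
        sig = clump(sig, ld, criteria)
    try:
        h = harmonize(sig, outcome_stats, exposure_name=exposure_name, outcome_name=outcome_name)
    except NoInstrumentsError as exc:
        raise NoInstrumentsError(f"{stage}: {exc}") from exc
    if config.presso_clean and h.n_snp >= 4:
        report = mr_presso(
            h,
            n_sim=config.n_sim,
            outlier_alpha=config.presso_outlier_alpha,
            seed=config.seed,
            effects_model=config.effects_model,
        )
        if report.outlier_indices and h.n_snp - len(report.outlier_indices) >= 2:
            keep = np.setdiff1d(np.arange(h.n_snp), report.outlier_indices)
            h = h.subset(keep)
    f = (h.beta_exposure / h.se_exposure) ** 2
    strong = f >= criteria.f_min
    if not strong.any():
        raise NoInstrumentsError(f"{stage}: all instruments weak (F < {criteria.f_min})")
    if not strong.all():
        h = h.subset(strong)
    return h


def stage_ivw(
    iv_source: Sequence[SummaryStatRecord],
    outcome_stats: Sequence[SummaryStatRecord],
    criteria: InstrumentCriteria | None = None,
    config: MRConfig | None = None,
    ld: LDMatrix | None = None,
    stage: str = "stage",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> MREstimate:
    """IVW estimate for one directed pair after full instrument processing."""
    criteria = criteria or InstrumentCriteria()
    config = config or MRConfig()
    h = _prepare_stage(
        iv_source, outcome_stats, criteria, config, ld, stage, exposure_name, outcome_name
    )
    return ivw(h, effects_model=config.effects_model)


def two_step_mediation(
    exposure_stats: Sequence[SummaryStatRecord],
    mediator_stats: Sequence[SummaryStatRecord],
    outcome_stats: Sequence[SummaryStatRecord],
    config: MRConfig | None = None,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
) -> MediationResult:
    """The two-step decomposition for one exposure/mediator/outcome triple.

    Step 1 (Beta X): IVW of the mediator on the exposure's instruments.
    Step 2 (Beta Y): IVW of the outcome on the mediator's instruments.
    Total: IVW of the outcome on the exposure's instruments.  Each stage
    runs the full instrument cascade (significance, optional clumping,
    PRESSO cleanup, F filter).
    """
    config = config or MRConfig()
    criteria = criteria or InstrumentCriteria()
    est_x = stage_ivw(
        exposure_stats, mediator_stats, criteria, config, ld,
        stage="exposure->mediator", exposure_name=exposure_name, outcome_name=mediator_name,
    )
    est_y = stage_ivw(
        mediator_stats, outcome_stats, criteria, config, ld,
        stage="mediator->outcome", exposure_name=mediator_name, outcome_name=outcome_name,
    )
    est_total = stage_ivw(
        exposure_stats, outcome_stats, criteria, config, ld,
        stage="exposure->outcome", exposure_name=exposure_name, outcome_name=outcome_name,
    )
    return MediationResult(
        exposure=exposure_name,
        mediator=mediator_name,
        outcome=outcome_name,
        beta_x=est_x.beta,
        se_x=est_x.se,
        beta_y=est_y.beta,
        se_y=est_y.se,
        beta_total=est_total.beta,
        se_total=est_total.se,
        n_snp_x=est_x.n_snp,
        n_snp_y=est_y.n_snp,
        n_snp_total=est_total.n_snp,
    )


def reverse_mr(
    outcome_stats: Sequence[SummaryStatRecord],
    exposure_stats: Sequence[SummaryStatRecord],
    config: MRConfig | None = None,
    criteria: InstrumentCriteria | None = None,
    ld: LDMatrix | None = None,
    outcome_name: str = "outcome",
    exposure_name: str = "exposure",
) -> MethodBundle:
    """Identical machinery with roles swapped: instruments from the outcome
    study, effects read off the exposure study."""
    config = config or MRConfig()
    criteria = criteria or InstrumentCriteria()
    h = _prepare_stage(
        outcome_stats, exposure_stats, criteria, config, ld,
        stage="reverse", exposure_name=outcome_name, outcome_name=exposure_name,
    )
    return run_all_methods(h, config)
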