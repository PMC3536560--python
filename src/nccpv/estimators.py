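"""Six confidence-interval constructions for nested case-control
predictive values.

All six approaches share the same point estimate (the sampling-fraction-
corrected predictive value); they differ only in how the standard error
and interval are formed:

1. naive Wald       - binomial SE of the *uncorrected* observed proportion,
                      on the observed denominator.
2. corrected Wald   - binomial SE of the corrected predictive value, still
                      on the observed denominator.
3. bootstrap        - percentile interval over stratified resamples of the
                      cases and of the sampled controls (sampling fraction
                      held at its design value).
4. delta method     - variance propagated from the binomial errors of
                      sensitivity and specificity through the Bayes formula
                      at the cohort prevalence, on the probability scale.
5. weighted logit   - model-based SE of the logit from the weighted
                      logistic regression, interval formed on the logit
                      scale and back-transformed.
6. delta method,    - approach 4 on the log-odds scale, back-transformed.
   logit scale

Wald intervals on the probability scale are truncated to [0, 1] and the
truncation is flagged; logit-scale intervals lie inside (0, 1) by
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import glm
from .exceptions import BoundaryError, ValidationError
from .tables import (
    NestedSample,
    Target,
    bayes_predictive_value,
    corrected_predictive_value,
)

__all__ = [
    "EstimatorConfig",
    "IntervalEstimate",
    "ci_naive_wald",
    "ci_corrected_wald",
    "ci_bootstrap",
    "ci_mercaldo",
    "ci_weighted_logistic",
    "ci_mercaldo_logit",
    "estimate_all",
    "APPROACHES",
    "estimates_to_dataframe",
]

logger = logging.getLogger(__name__)

_SCALE = {1: "natural", 2: "natural", 3: "percentile", 4: "natural",
          5: "logit", 6: "logit"}


@dataclass(frozen=True)
class EstimatorConfig:
    """Shared configuration of the interval estimators.

    ``z`` is the standard-normal quantile for the two-sided ``level`` and is
    always derived from ``level`` (no hard-coded 1.96), so non-95% levels
    work throughout.
    """

    level: float = 0.95
    bootstrap_reps: int = 1000
    seed: int | None = None
    continuity_correction: bool = False

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValidationError(f"level must lie in (0, 1), got {self.level}")
        if self.bootstrap_reps < 2:
            raise ValidationError(
                f"bootstrap_reps must be >= 2, got {self.bootstrap_reps}"
            )

    @property
    def z(self) -> float:
        return float(norm.ppf((1.0 + self.level) / 2.0))


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with its confidence bounds.

    ``se`` is ``None`` for the bootstrap (no closed-form SE); ``scale``
    records the scale on which the SE/interval was formed.
    """

    target: Target
    estimate: float
    lower: float
    upper: float
    se: float | None
    scale: str
    approach: int
    level: float
    truncated: bool = False
    continuity_corrected: bool = False
    diagnostics: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "target", Target.coerce(self.target))
        if not (0.0 <= self.lower <= self.estimate <= self.upper <= 1.0):
            raise ValidationError(
                f"interval ordering violated: need 0 <= lower <= estimate <= "
                f"upper <= 1, got ({self.lower}, {self.estimate}, {self.upper})"
            )
        if self.se is not None and self.se < 0:
            raise ValidationError(f"se must be non-negative, got {self.se}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _counts(sample: NestedSample, cc: bool) -> tuple[float, float, float, float]:
    shift = 0.5 if cc else 0.0
    return (sample.a + shift, sample.c + shift,
            sample.b1 + shift, sample.d1 + shift)


def _observed_proportion(
    sample: NestedSample, target: Target, cc: bool
) -> tuple[float, float]:
    """Uncorrected proportion and its observed denominator."""
    a, c, b1, d1 = _counts(sample, cc)
    if target is Target.PPV:
        return a / (a + b1), a + b1
    return d1 / (c + d1), c + d1


def _truncate(lo: float, hi: float) -> tuple[float, float, bool]:
    lo_t, hi_t = max(lo, 0.0), min(hi, 1.0)
    return lo_t, hi_t, (lo_t != lo or hi_t != hi)


def _wald(
    sample: NestedSample, target: Target, cfg: EstimatorConfig, approach: int
) -> IntervalEstimate:
    cc = cfg.continuity_correction
    estimate = corrected_predictive_value(sample, target, continuity_correction=cc)
    p_obs, n_obs = _observed_proportion(sample, target, cc)
    prop = p_obs if approach == 1 else estimate
    se = math.sqrt(prop * (1.0 - prop) / n_obs)
    lo, hi, truncated = _truncate(estimate - cfg.z * se, estimate + cfg.z * se)
    return IntervalEstimate(
        target=target, estimate=estimate, lower=lo, upper=hi, se=se,
        scale="natural", approach=approach, level=cfg.level,
        truncated=truncated, continuity_corrected=cc,
    )


def ci_naive_wald(
    sample: NestedSample, target: Target | str, cfg: EstimatorConfig | None = None
) -> IntervalEstimate:
    """Approach 1: Wald interval with the SE of the uncorrected observed
    proportion on the observed denominator, centred on the corrected
    estimate (the point estimate is common to all approaches)."""
    return _wald(sample, Target.coerce(target), cfg or EstimatorConfig(), 1)


def ci_corrected_wald(
    sample: NestedSample, target: Target | str, cfg: EstimatorConfig | None = None
) -> IntervalEstimate:
    """Approach 2: Wald interval with the corrected predictive value in the
    SE numerator but the observed (unweighted) denominator."""
    return _wald(sample, Target.coerce(target), cfg or EstimatorConfig(), 2)


def ci_bootstrap(
    sample: NestedSample, target: Target | str, cfg: EstimatorConfig | None = None
) -> IntervalEstimate:
    """Approach 3: stratified percentile bootstrap.

    Cases are resampled with replacement within cases and sampled controls
    within controls (fixed-margin design: the case count, control count and
    sampling fraction are design constants). The interval is the pair of
    empirical ``(1 +/- level)/2`` quantiles (linear interpolation between
    order statistics). Replicates with an empty denominator are
    continuity-corrected in place and tallied in the diagnostics.
    """
    target = Target.coerce(target)
    cfg = cfg or EstimatorConfig()
    cc = cfg.continuity_correction
    estimate = corrected_predictive_value(sample, target, continuity_correction=cc)
    sf = sample.sampling_fraction
    n_case, n_ctrl = sample.n_cases, sample.n_controls
    rng = np.random.default_rng(cfg.seed)
    a_star = rng.binomial(n_case, sample.a / n_case, size=cfg.bootstrap_reps)
    b1_star = rng.binomial(n_ctrl, sample.b1 / n_ctrl, size=cfg.bootstrap_reps)
    if target is Target.PPV:
        num, comp = a_star.astype(float), b1_star / sf
        num_cc, comp_cc = a_star + 0.5, (b1_star + 0.5) / sf
    else:
        num = (n_ctrl - b1_star) / sf
        comp = (n_case - a_star).astype(float)
        num_cc = (n_ctrl - b1_star + 0.5) / sf
        comp_cc = n_case - a_star + 0.5
    empty = (num + comp) == 0
    n_empty = int(empty.sum())
    if n_empty:
        logger.info(
            "bootstrap: %d of %d replicates had an empty %s denominator and "
            "were continuity-corrected", n_empty, cfg.bootstrap_reps,
            target.value.upper(),
        )
        num = np.where(empty, num_cc, num)
        comp = np.where(empty, comp_cc, comp)
    values = num / (num + comp)
    alpha = (1.0 - cfg.level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    # a percentile interval brackets the observed statistic except in
    # pathological tiny-count cases; widen to include it so the estimate
    # ordering invariant holds
    lo, hi = min(float(lo), estimate), max(float(hi), estimate)
    return IntervalEstimate(
        target=target, estimate=estimate, lower=lo, upper=hi, se=None,
        scale="percentile", approach=3, level=cfg.level,
        continuity_corrected=cc,
        diagnostics={"empty_denominator_replicates": n_empty},
    )


def _accuracy(
    sample: NestedSample, cfg: EstimatorConfig
) -> tuple[float, float, float, float]:
    """Plug-in Se, Sp and the stratum sizes, optionally continuity-corrected."""
    a, c, b1, d1 = _counts(sample, cfg.continuity_correction)
    n_case, n_ctrl = a + c, b1 + d1
    se, sp = a / n_case, d1 / n_ctrl
    if not (0.0 < se < 1.0 and 0.0 < sp < 1.0):
        raise BoundaryError(
            f"sensitivity ({se:g}) and specificity ({sp:g}) must lie strictly "
            "inside (0, 1) for the delta-method approaches; enable the "
            "continuity correction to proceed"
        )
    return se, sp, n_case, n_ctrl


def ci_mercaldo(
    sample: NestedSample,
    cohort_prevalence: float | None = None,
    target: Target | str = Target.PPV,
    cfg: EstimatorConfig | None = None,
) -> IntervalEstimate:
    """Approach 4: delta-method variance of the Bayes predictive value on the
    probability scale.

    The variance propagates the independent binomial errors of Se (from the
    cases) and Sp (from the sampled controls) through the Bayes formula; the
    cohort prevalence is treated as known. Defaults to the prevalence of the
    sample's own cohort, for which the point estimate coincides exactly with
    the weighted estimator.
    """
    target = Target.coerce(target)
    cfg = cfg or EstimatorConfig()
    p = sample.cohort_prevalence if cohort_prevalence is None else cohort_prevalence
    if not 0.0 < p < 1.0:
        raise ValidationError(f"cohort prevalence must lie in (0, 1), got {p}")
    se_, sp_, n_case, n_ctrl = _accuracy(sample, cfg)
    estimate = bayes_predictive_value(se_, sp_, p, target)
    q = 1.0 - p
    if target is Target.PPV:
        denom = se_ * p + (1.0 - sp_) * q
        var = (
            p * p * q * q * (1.0 - sp_) ** 2 * se_ * (1.0 - se_) / n_case
            + p * p * q * q * se_ * se_ * sp_ * (1.0 - sp_) / n_ctrl
        ) / denom**4
    else:
        denom = sp_ * q + (1.0 - se_) * p
        var = (
            p * p * q * q * sp_ * sp_ * se_ * (1.0 - se_) / n_case
            + p * p * q * q * (1.0 - se_) ** 2 * sp_ * (1.0 - sp_) / n_ctrl
        ) / denom**4
    se = math.sqrt(var)
    lo, hi, truncated = _truncate(estimate - cfg.z * se, estimate + cfg.z * se)
    return IntervalEstimate(
        target=target, estimate=estimate, lower=lo, upper=hi, se=se,
        scale="natural", approach=4, level=cfg.level, truncated=truncated,
        continuity_corrected=cfg.continuity_correction,
    )


def ci_weighted_logistic(
    sample: NestedSample,
    target: Target | str = Target.PPV,
    cfg: EstimatorConfig | None = None,
) -> IntervalEstimate:
    """Approach 5: weighted logistic regression.

    The interval is formed on the logit scale with the model-based SE from
    the weighted fit's covariance and back-transformed, which keeps the
    bounds inside (0, 1) and is the construction that uses the logit SE
    directly.
    """
    target = Target.coerce(target)
    cfg = cfg or EstimatorConfig()
    fit = glm.fit_weighted_logit(
        sample, continuity_correction=cfg.continuity_correction
    )
    estimate = fit.predicted(target)
    se = glm.logit_se(fit, target)
    logit = math.log(estimate / (1.0 - estimate))
    lo = 1.0 / (1.0 + math.exp(-(logit - cfg.z * se)))
    hi = 1.0 / (1.0 + math.exp(-(logit + cfg.z * se)))
    return IntervalEstimate(
        target=target, estimate=estimate, lower=lo, upper=hi, se=se,
        scale="logit", approach=5, level=cfg.level,
        continuity_corrected=cfg.continuity_correction,
        diagnostics={"iterations": fit.iterations, "deviance": fit.deviance},
    )


def ci_mercaldo_logit(
    sample: NestedSample,
    cohort_prevalence: float | None = None,
    target: Target | str = Target.PPV,
    cfg: EstimatorConfig | None = None,
) -> IntervalEstimate:
    """Approach 6: the delta-method variance of approach 4 on the log-odds
    scale, with the interval back-transformed through the inverse logit."""
    target = Target.coerce(target)
    cfg = cfg or EstimatorConfig()
    p = sample.cohort_prevalence if cohort_prevalence is None else cohort_prevalence
    if not 0.0 < p < 1.0:
        raise ValidationError(f"cohort prevalence must lie in (0, 1), got {p}")
    se_, sp_, n_case, n_ctrl = _accuracy(sample, cfg)
    estimate = bayes_predictive_value(se_, sp_, p, target)
    if target is Target.PPV:
        var = (1.0 - se_) / (se_ * n_case) + sp_ / ((1.0 - sp_) * n_ctrl)
    else:
        var = se_ / ((1.0 - se_) * n_case) + (1.0 - sp_) / (sp_ * n_ctrl)
    se = math.sqrt(var)
    logit = math.log(estimate / (1.0 - estimate))
    lo = 1.0 / (1.0 + math.exp(-(logit - cfg.z * se)))
    hi = 1.0 / (1.0 + math.exp(-(logit + cfg.z * se)))
    return IntervalEstimate(
        target=target, estimate=estimate, lower=lo, upper=hi, se=se,
        scale="logit", approach=6, level=cfg.level,
        continuity_corrected=cfg.continuity_correction,
    )


APPROACHES = {
    1: ci_naive_wald,
    2: ci_corrected_wald,
    3: ci_bootstrap,
    4: ci_mercaldo,
    5: ci_weighted_logistic,
    6: ci_mercaldo_logit,
}


def estimate_interval(
    approach: int,
    sample: NestedSample,
    target: Target | str,
    cfg: EstimatorConfig | None = None,
    cohort_prevalence: float | None = None,
) -> IntervalEstimate:
    """Dispatch a single approach by its conventional number (1-6)."""
    if approach in (4, 6):
        return APPROACHES[approach](sample, cohort_prevalence, target, cfg)
    if approach not in APPROACHES:
        raise ValidationError(f"approach must be one of 1..6, got {approach}")
    return APPROACHES[approach](sample, target, cfg)


def estimate_all(
    sample: NestedSample,
    cohort_prevalence: float | None = None,
    cfg: EstimatorConfig | None = None,
    approaches: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    targets: tuple[Target, ...] = (Target.PPV, Target.NPV),
) -> list[IntervalEstimate]:
    """All requested approaches for both predictive values."""
    cfg = cfg or EstimatorConfig()
    return [
        estimate_interval(app, sample, tgt, cfg, cohort_prevalence)
        for app in approaches
        for tgt in (Target.coerce(t) for t in targets)
    ]


_FRAME_COLUMNS = [
    "approach", "target", "estimate", "lower", "upper", "se", "scale",
    "level", "truncated", "continuity_corrected",
]


def estimates_to_dataframe(estimates: list[IntervalEstimate]) -> pd.DataFrame:
    """Tidy frame of results (one row per approach x target)."""
    rows = [
        {
            "approach": e.approach,
            "target": e.target.value,
            "estimate": e.estimate,
            "lower": e.lower,
            "upper": e.upper,
            "se": e.se,
            "scale": e.scale,
            "level": e.level,
            "truncated": e.truncated,
            "continuity_corrected": e.continuity_corrected,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def estimates_from_dataframe(frame: pd.DataFrame) -> list[IntervalEstimate]:
    """Inverse of :func:`estimates_to_dataframe` (round-trip safe)."""
    out = []
    for _, row in frame.iterrows():
        se = row["se"]
        out.append(
            IntervalEstimate(
                target=Target.coerce(row["target"]),
                estimate=float(row["estimate"]),
                lower=float(row["lower"]),
                upper=float(row["upper"]),
                se=None if pd.isna(se) else float(se),
                scale=str(row["scale"]),
                approach=int(row["approach"]),
                level=float(row["level"]),
                truncated=bool(row["truncated"]),
                continuity_corrected=bool(row["continuity_corrected"]),
            )
        )
    return out
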