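"""Core 2x2 data types and weighted point estimation of predictive values.

A diagnostic cohort cross-classifies subjects by true disease status
(reference test) and index-test result:

              test +   test -
    diseased    TP       FN        (cases)
    healthy     FP       TN        (controls)

In a nested case-control sample all cases are kept but only a random
fraction ``sf`` of the cohort's controls receives the index test. The
predictive values of the full cohort are recovered by re-inflating the
sampled control cells with the inverse sampling fraction:

    PPV = a / (a + b1 / sf)          NPV = (d1 / sf) / (c + d1 / sf)

where ``a``/``c`` are the case counts by test result and ``b1``/``d1`` the
sampled-control counts. Both values equal the Bayes expressions in terms of
sensitivity, specificity and cohort prevalence (an exact algebraic
identity, not an approximation).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict
from numbers import Integral
from pathlib import Path

import pandas as pd

from .exceptions import DegenerateTableError, InvalidDesignError, ValidationError

__all__ = [
    "Target",
    "CohortTable",
    "NestedSample",
    "sampling_fraction",
    "cohort_predictive_value",
    "corrected_predictive_value",
    "bayes_predictive_value",
    "read_nested_sample_csv",
    "nested_sample_from_json",
]


class Target(str, enum.Enum):
    """Which post-test probability is being estimated."""

    PPV = "ppv"
    NPV = "npv"

    @classmethod
    def coerce(cls, value: "Target | str") -> "Target":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(
                f"target must be 'ppv' or 'npv', got {value!r}"
            ) from None


def _check_count(name: str, value) -> int:
    if isinstance(value, bool) or not isinstance(value, Integral):
        raise ValidationError(f"{name} must be an integer count, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class CohortTable:
    """Full 2x2 cross-classification of a cohort or source population.

    Parameters
    ----------
    tp, fp, fn, tn
        True-positive, false-positive, false-negative and true-negative
        counts (non-negative integers; total must be positive).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.n == 0:
            raise ValidationError("cohort table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def cases(self) -> int:
        return self.tp + self.fn

    @property
    def controls(self) -> int:
        return self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.cases / self.n

    @property
    def sensitivity(self) -> float:
        if self.cases == 0:
            raise DegenerateTableError("sensitivity undefined: no diseased subjects")
        return self.tp / self.cases

    @property
    def specificity(self) -> float:
        if self.controls == 0:
            raise DegenerateTableError("specificity undefined: no healthy subjects")
        return self.tn / self.controls

    def as_nested_sample(self) -> "NestedSample":
        """View the full cohort as a nested sample with sampling fraction 1."""
        return NestedSample(
            a=self.tp,
            c=self.fn,
            b1=self.fp,
            d1=self.tn,
            cohort_controls=self.controls,
            cohort_size=self.n,
        )


@dataclass(frozen=True)
class NestedSample:
    """Observed nested case-control counts plus the cohort context.

    All cohort cases are in the sample (``a`` test-positive, ``c``
    test-negative); ``b1``/``d1`` are the sampled controls by index-test
    result. ``cohort_controls`` is the size of the cohort's control pool and
    ``cohort_size`` the full cohort size, so that
    ``cohort_size = a + c + cohort_controls``.
    """

    a: int
    c: int
    b1: int
    d1: int
    cohort_controls: int
    cohort_size: int

    def __post_init__(self):
        for name in ("a", "c", "b1", "d1", "cohort_controls", "cohort_size"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.a + self.c < 1:
            raise ValidationError(
                "a + c >= 1 violated: a nested sample must contain all cohort "
                "cases and at least one of them"
            )
        if self.cohort_controls == 0:
            raise InvalidDesignError(
                "cohort_controls > 0 violated: the cohort has no control pool"
            )
        if self.b1 + self.d1 == 0:
            raise InvalidDesignError(
                "b1 + d1 > 0 violated: no controls were sampled, the sampling "
                "fraction is undefined"
            )
        if self.b1 + self.d1 > self.cohort_controls:
            raise ValidationError(
                f"b1 + d1 <= cohort_controls violated: sampled "
                f"{self.b1 + self.d1} controls from a pool of "
                f"{self.cohort_controls}"
            )
        if self.cohort_size != self.a + self.c + self.cohort_controls:
            raise ValidationError(
                f"cohort_size = (a + c) + cohort_controls violated: "
                f"{self.cohort_size} != {self.a + self.c} + {self.cohort_controls}"
            )

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        """Number of sampled controls."""
        return self.b1 + self.d1

    @property
    def n1(self) -> int:
        """Nested sample size (cases plus sampled controls)."""
        return self.n_cases + self.n_controls

    @property
    def sampling_fraction(self) -> float:
        return (self.b1 + self.d1) / self.cohort_controls

    @property
    def cohort_prevalence(self) -> float:
        return self.n_cases / self.cohort_size

    @property
    def sensitivity(self) -> float:
        return self.a / self.n_cases

    @property
    def specificity(self) -> float:
        """Specificity estimated from the sampled controls (controls are a
        random sample of the pool, so no weighting is needed)."""
        return self.d1 / self.n_controls

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def sampling_fraction(sample: NestedSample) -> float:
    """Fraction of the cohort's control pool included in the nested sample."""
    return sample.sampling_fraction


def _weighted_cells(
    a: float, c: float, b1: float, d1: float, sf: float, target: Target
) -> tuple[float, float]:
    """Numerator and complement cell of the requested predictive value, on
    the cohort scale.

    One shared path serves both targets by swapping (a <-> d1, b1 <-> c) and
    inflating the control cell by 1/sf, so the two formulas cannot drift
    apart.
    """
    if target is Target.PPV:
        return a, b1 / sf
    return d1 / sf, c


def corrected_predictive_value(
    sample: NestedSample,
    target: Target | str,
    *,
    continuity_correction: bool = False,
) -> float:
    """Inverse-sampling-fraction-weighted predictive value.

    With ``sf = 1`` (all controls sampled) this is the raw cohort
    proportion. A degenerate denominator raises
    :class:`~nccpv.exceptions.DegenerateTableError` unless
    ``continuity_correction`` adds 0.5 to all four nested counts
    (Haldane-Anscombe); the sampling fraction keeps its design value.
    """
    target = Target.coerce(target)
    sf = sample.sampling_fraction
    shift = 0.5 if continuity_correction else 0.0
    num, comp = _weighted_cells(
        sample.a + shift, sample.c + shift, sample.b1 + shift, sample.d1 + shift,
        sf, target,
    )
    denom = num + comp
    if denom <= 0:
        raise DegenerateTableError(
            f"{target.value.upper()} denominator is empty "
            f"(no test-{'positives' if target is Target.PPV else 'negatives'}); "
            "enable the continuity correction to proceed"
        )
    return num / denom


def cohort_predictive_value(cohort: CohortTable, target: Target | str) -> float:
    """Exact predictive value of a fully observed cohort."""
    target = Target.coerce(target)
    if target is Target.PPV:
        denom = cohort.tp + cohort.fp
        if denom == 0:
            raise DegenerateTableError("PPV undefined: no test-positive subjects")
        return cohort.tp / denom
    denom = cohort.tn + cohort.fn
    if denom == 0:
        raise DegenerateTableError("NPV undefined: no test-negative subjects")
    return cohort.tn / denom


def bayes_predictive_value(
    se: float, sp: float, p: float, target: Target | str
) -> float:
    """Predictive value from sensitivity, specificity and prevalence.

    ``PPV = Se*p / (Se*p + (1-Sp)*(1-p))`` and
    ``NPV = Sp*(1-p) / (Sp*(1-p) + (1-Se)*p)``.
    """
    target = Target.coerce(target)
    for name, v in (("sensitivity", se), ("specificity", sp), ("prevalence", p)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    if target is Target.PPV:
        num = se * p
        denom = num + (1.0 - sp) * (1.0 - p)
    else:
        num = sp * (1.0 - p)
        denom = num + (1.0 - se) * p
    if denom <= 0:
        raise DegenerateTableError(
            f"{target.value.upper()} undefined: zero probability of the "
            "conditioning test result"
        )
    return num / denom


_CSV_COLUMNS = ("a", "c", "b1", "d1", "cohort_controls", "cohort_size")


def read_nested_sample_csv(path: str | Path) -> NestedSample:
    """Read a one-record CSV with named columns a, c, b1, d1,
    cohort_controls, cohort_size (header required, UTF-8)."""
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [col for col in _CSV_COLUMNS if col not in frame.columns]
    if missing:
        raise ValidationError(f"CSV is missing required columns: {missing}")
    if len(frame) != 1:
        raise ValidationError(
            f"expected exactly one record, found {len(frame)} rows"
        )
    row = frame.iloc[0]
    return NestedSample(**{col: int(row[col]) for col in _CSV_COLUMNS})


def nested_sample_from_json(text: str) -> NestedSample:
    """Parse the JSON mirror of :class:`NestedSample`."""
    payload = json.loads(text)
    if not isinstance(payload, dict):
        raise ValidationError("JSON payload must be an object of counts")
    unknown = set(payload) - set(_CSV_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown fields in JSON payload: {sorted(unknown)}")
    missing = set(_CSV_COLUMNS) - set(payload)
    if missing:
        raise ValidationError(f"missing fields in JSON payload: {sorted(missing)}")
    return NestedSample(**payload)
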