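"""Monte-Carlo engine for confidence-interval coverage of predictive values.

The resampling design mirrors a two-stage diagnostic study:

1. a fixed *source population* (a 2x2 table of known size) defines the true
   diagnostic accuracy;
2. each replicate draws a *cohort* of the same size with replacement from
   the source population (one multinomial draw), so the cohort prevalence
   varies around the source prevalence;
3. a *nested case-control sample* keeps every cohort case and draws
   ``ratio`` controls per case from the cohort's control pool;
4. every requested interval approach is evaluated on the nested sample,
   using the realized cohort prevalence, and scored against the truth.

Two truth policies are supported. The default, ``"cohort_prevalence"``,
scores each interval against the predictive value implied by the source
population's sensitivity/specificity at the replicate's realized cohort
prevalence: the diagnostic accuracy of a test is prevalence-invariant, so
this is the estimand the nested sample actually targets once the cohort has
been drawn. ``"source"`` scores against the fixed source-population value,
which additionally charges every approach for the cohort-level prevalence
noise none of their variance formulas contains.

Coverage is judged against the acceptability band ``level +/- 2 SE`` with
``SE = sqrt(level*(1-level)/B)``; for a 95% level and B=1000 replicates the
band is (0.936, 0.964).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import EstimatorConfig, estimate_interval
from .exceptions import (
    BoundaryError,
    DegenerateTableError,
    InvalidDesignError,
    SeparationError,
    ValidationError,
)
from .tables import (
    CohortTable,
    NestedSample,
    Target,
    bayes_predictive_value,
    cohort_predictive_value,
)

__all__ = [
    "SourceSpec",
    "SimDesign",
    "CoverageResult",
    "build_source_population",
    "draw_cohort",
    "draw_nested_sample",
    "run_coverage_study",
    "acceptability_interval",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SourceSpec:
    """Parameters of a source population to reconstruct as integer counts."""

    prevalence: float
    sensitivity: float
    specificity: float
    population_size: int = 1400
    label: str = ""

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError(
                f"prevalence must lie in (0, 1), got {self.prevalence}"
            )
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")
        if self.population_size < 1:
            raise ValidationError("population_size must be positive")


def build_source_population(spec: SourceSpec) -> CohortTable:
    """Integer 2x2 source population matching the spec to 2 decimals.

    Cases are ``round(p*N)``, true positives ``round(Se*cases)``, true
    negatives ``round(Sp*controls)`` (round-half-even on the float product),
    remaining cells by subtraction. The realized prevalence, sensitivity
    and specificity must reproduce the spec after rounding to 2 decimals,
    otherwise the spec is rejected as unrepresentable at this size.
    """
    n = spec.population_size
    cases = round(spec.prevalence * n)
    controls = n - cases
    tp = round(spec.sensitivity * cases)
    tn = round(spec.specificity * controls)
    fn = cases - tp
    fp = controls - tn
    if min(tp, fp, fn, tn) < 0 or cases == 0 or controls == 0:
        raise ValidationError(
            f"spec {spec} yields a negative or empty cell at N={n}"
        )
    table = CohortTable(tp=tp, fp=fp, fn=fn, tn=tn)
    realized = (table.prevalence, table.sensitivity, table.specificity)
    stated = (spec.prevalence, spec.sensitivity, spec.specificity)
    if any(round(r, 2) != round(s, 2) for r, s in zip(realized, stated)):
        raise ValidationError(
            f"reconstructed population {table} does not round-trip the stated "
            f"parameters {stated} at 2 decimals (realized {realized})"
        )
    return table


def draw_cohort(
    source: CohortTable, n: int, rng: np.random.Generator
) -> CohortTable:
    """One cohort of size ``n`` drawn with replacement from the source
    population (a single multinomial draw over the four cells)."""
    if n < 1:
        raise ValidationError("cohort size must be positive")
    probs = np.array([source.tp, source.fp, source.fn, source.tn]) / source.n
    tp, fp, fn, tn = rng.multinomial(n, probs)
    return CohortTable(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))


def draw_nested_sample(
    cohort: CohortTable,
    ratio: int,
    rng: np.random.Generator,
    *,
    replace: bool = True,
) -> NestedSample:
    """Nested case-control sample: all cases plus ``ratio`` controls per case.

    With ``replace=True`` (default) the controls are drawn with replacement
    from the cohort's control pool, capped at the pool size; this keeps the
    design feasible when ``ratio * cases`` exceeds the pool and mirrors
    bootstrap-style control selection. With ``replace=False`` the controls
    are drawn without replacement (a hypergeometric split of the pool), and
    ``ratio * cases`` must not exceed the pool.
    """
    if ratio < 1:
        raise ValidationError(f"case-control ratio must be >= 1, got {ratio}")
    cases = cohort.cases
    pool = cohort.controls
    if cases < 1:
        raise DegenerateTableError("cohort contains no cases")
    if pool < 1:
        raise InvalidDesignError("cohort contains no controls")
    n_sample = ratio * cases
    if replace:
        n_sample = min(n_sample, pool)
        b1 = int(rng.binomial(n_sample, cohort.fp / pool))
    else:
        if n_sample > pool:
            raise InvalidDesignError(
                f"cannot sample {n_sample} controls without replacement from "
                f"a pool of {pool}"
            )
        b1 = int(rng.hypergeometric(cohort.fp, cohort.tn, n_sample))
    return NestedSample(
        a=cohort.tp,
        c=cohort.fn,
        b1=b1,
        d1=n_sample - b1,
        cohort_controls=pool,
        cohort_size=cohort.n,
    )


def acceptability_interval(
    level: float, replicates: int
) -> tuple[float, float, float]:
    """Monte-Carlo acceptability band for empirical coverage.

    ``se = sqrt(nominal*(1-nominal)/B)`` with ``nominal = 1 - level``;
    returns ``(level - 2 se, level + 2 se, se)``. Coverage below the band is
    undercoverage, above it overcoverage.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must lie in (0, 1), got {level}")
    if replicates < 1:
        raise ValidationError("replicates must be positive")
    nominal = 1.0 - level
    se = math.sqrt(nominal * (1.0 - nominal) / replicates)
    return level - 2.0 * se, level + 2.0 * se, se


_ALL_APPROACHES = (1, 2, 3, 4, 5, 6)
_RECOVERABLE = (BoundaryError, SeparationError, DegenerateTableError)


@dataclass(frozen=True)
class SimDesign:
    """Configuration of one coverage-simulation cell."""

    source: SourceSpec | CohortTable
    case_control_ratio: int = 1
    replicates: int = 1000
    bootstrap_reps: int = 1000
    level: float = 0.95
    seed: int = 0
    approaches: tuple[int, ...] = _ALL_APPROACHES
    targets: tuple[Target | str, ...] = (Target.PPV, Target.NPV)
    cohort_size: int | None = None
    replace: bool = True
    truth_policy: str = "cohort_prevalence"

    def __post_init__(self):
        object.__setattr__(
            self, "targets", tuple(Target.coerce(t) for t in self.targets)
        )
        object.__setattr__(self, "approaches", tuple(self.approaches))
        if self.replicates < 1:
            raise ValidationError("replicates must be positive")
        if self.case_control_ratio < 1:
            raise ValidationError("case_control_ratio must be >= 1")
        unknown = set(self.approaches) - set(_ALL_APPROACHES)
        if unknown:
            raise ValidationError(f"unknown approaches: {sorted(unknown)}")
        if self.truth_policy not in ("cohort_prevalence", "source"):
            raise ValidationError(
                "truth_policy must be 'cohort_prevalence' or 'source', "
                f"got {self.truth_policy!r}"
            )
        table = self.source_table()
        n = self.cohort_n()
        exp_cases = n * table.prevalence
        exp_controls = n - exp_cases
        if self.case_control_ratio * exp_cases > exp_controls:
            raise InvalidDesignError(
                f"ratio {self.case_control_ratio} requires "
                f"{self.case_control_ratio * exp_cases:.0f} controls per "
                f"cohort on average but only {exp_controls:.0f} are expected"
            )

    def source_table(self) -> CohortTable:
        if isinstance(self.source, CohortTable):
            return self.source
        return build_source_population(self.source)

    def cohort_n(self) -> int:
        return self.cohort_size or self.source_table().n

    def to_dict(self) -> dict:
        src = self.source
        if isinstance(src, CohortTable):
            src_repr = {"tp": src.tp, "fp": src.fp, "fn": src.fn, "tn": src.tn}
        else:
            src_repr = {
                "prevalence": src.prevalence,
                "sensitivity": src.sensitivity,
                "specificity": src.specificity,
                "population_size": src.population_size,
                "label": src.label,
            }
        return {
            "source": src_repr,
            "case_control_ratio": self.case_control_ratio,
            "replicates": self.replicates,
            "bootstrap_reps": self.bootstrap_reps,
            "level": self.level,
            "seed": self.seed,
            "approaches": list(self.approaches),
            "targets": [t.value for t in self.targets],
            "cohort_size": self.cohort_n(),
            "replace": self.replace,
            "truth_policy": self.truth_policy,
        }


@dataclass
class _Tally:
    covered: int = 0
    width_sum: float = 0.0
    estimate_sum: float = 0.0
    used: int = 0
    degenerate: int = 0


@dataclass(frozen=True)
class CoverageResult:
    """Aggregated coverage and width per (approach, target).

    ``truth`` holds the fixed source-population predictive values; under the
    default truth policy the per-replicate comparison value additionally
    tracks the realized cohort prevalence (see module docstring).
    """

    design: SimDesign
    coverage: dict
    mean_width: dict
    mean_estimate: dict
    replicates_used: dict
    degenerate_replicates: dict
    truth: dict
    redrawn_cohorts: int
    mean_cohort_prevalence: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for app in self.design.approaches:
            for tgt in self.design.targets:
                key = (app, tgt)
                rows.append(
                    {
                        "approach": app,
                        "target": tgt.value,
                        "coverage": self.coverage[key],
                        "mean_width": self.mean_width[key],
                        "mean_estimate": self.mean_estimate[key],
                        "replicates_used": self.replicates_used[key],
                        "degenerate_replicates": self.degenerate_replicates[key],
                        "truth": self.truth[tgt],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "design": self.design.to_dict(),
            "redrawn_cohorts": self.redrawn_cohorts,
            "mean_cohort_prevalence": self.mean_cohort_prevalence,
            "results": self.to_dataframe().to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)


def _truth_value(
    design: SimDesign,
    source: CohortTable,
    cohort_prevalence: float,
    target: Target,
) -> float:
    if design.truth_policy == "source":
        return cohort_predictive_value(source, target)
    return bayes_predictive_value(
        source.sensitivity, source.specificity, cohort_prevalence, target
    )


def run_coverage_study(design: SimDesign) -> CoverageResult:
    """Run one simulation cell and aggregate coverage and width.

    One RNG stream per replicate is spawned from the root seed (and a
    second, independent stream for the bootstrap within the replicate), so
    per-replicate draws do not depend on which approaches are requested.
    Cohorts with no cases, or with too few controls for the requested ratio
    under without-replacement sampling, are redrawn and counted. Replicates
    an approach cannot process (boundary Se/Sp, zero cells, empty
    denominators) are excluded for that approach only and tallied.
    """
    source = design.source_table()
    n = design.cohort_n()
    tallies = {
        (app, tgt): _Tally()
        for app in design.approaches
        for tgt in design.targets
    }
    root = np.random.SeedSequence(design.seed)
    redraws = 0
    prevalence_sum = 0.0
    for child in root.spawn(design.replicates):
        draw_ss, boot_ss = child.spawn(2)
        rng = np.random.default_rng(draw_ss)
        while True:
            cohort = draw_cohort(source, n, rng)
            if cohort.cases < 1 or cohort.controls < 1:
                redraws += 1
                continue
            if (
                not design.replace
                and design.case_control_ratio * cohort.cases > cohort.controls
            ):
                redraws += 1
                continue
            break
        sample = draw_nested_sample(
            cohort, design.case_control_ratio, rng, replace=design.replace
        )
        prevalence_sum += sample.cohort_prevalence
        boot_seed = int(boot_ss.generate_state(1)[0] % (2**31))
        cfg = EstimatorConfig(
            level=design.level, bootstrap_reps=design.bootstrap_reps,
            seed=boot_seed,
        )
        for tgt in design.targets:
            truth = _truth_value(design, source, sample.cohort_prevalence, tgt)
            for app in design.approaches:
                tally = tallies[(app, tgt)]
                try:
                    est = estimate_interval(app, sample, tgt, cfg)
                except _RECOVERABLE as exc:
                    tally.degenerate += 1
                    logger.debug(
                        "approach %d %s: replicate excluded (%s)",
                        app, tgt.value, exc,
                    )
                    continue
                tally.used += 1
                tally.covered += est.lower <= truth <= est.upper
                tally.width_sum += est.width
                tally.estimate_sum += est.estimate
    if redraws:
        logger.info("redrew %d cohorts (no cases or insufficient controls)",
                    redraws)
    coverage, mean_width, mean_estimate, used, degenerate = {}, {}, {}, {}, {}
    for key, tally in tallies.items():
        if tally.used == 0:
            raise InvalidDesignError(
                f"approach {key[0]} ({key[1].value}) processed no replicates"
            )
        coverage[key] = tally.covered / tally.used
        mean_width[key] = tally.width_sum / tally.used
        mean_estimate[key] = tally.estimate_sum / tally.used
        used[key] = tally.used
        degenerate[key] = tally.degenerate
    truth = {
        tgt: cohort_predictive_value(source, tgt) for tgt in design.targets
    }
    return CoverageResult(
        design=design,
        coverage=coverage,
        mean_width=mean_width,
        mean_estimate=mean_estimate,
        replicates_used=used,
        degenerate_replicates=degenerate,
        truth=truth,
        redrawn_cohorts=redraws,
        mean_cohort_prevalence=prevalence_sum / design.replicates,
    )


def scatter_coverage_width(
    frame: pd.DataFrame, path, level: float = 0.95, replicates: int = 1000
) -> None:
    """Coverage-versus-width scatter (one panel per target) with the
    acceptability band drawn as vertical lines. Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi, _ = acceptability_interval(level, replicates)
    targets = sorted(frame["target"].unique())
    fig, axes = plt.subplots(1, len(targets), figsize=(5 * len(targets), 4),
                             squeeze=False)
    for ax, tgt in zip(axes[0], targets):
        sub = frame[frame["target"] == tgt]
        ax.scatter(sub["coverage"], sub["mean_width"], c=sub["approach"],
                   cmap="tab10", vmin=1, vmax=10)
        for _, row in sub.iterrows():
            ax.annotate(str(int(row["approach"])),
                        (row["coverage"], row["mean_width"]),
                        textcoords="offset points", xytext=(4, 2), fontsize=8)
        ax.axvline(level, color="grey", lw=1)
        ax.axvline(lo, color="grey", lw=0.8, ls="--")
        ax.axvline(hi, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("coverage")
        ax.set_ylabel("mean CI width")
        ax.set_title(tgt.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
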