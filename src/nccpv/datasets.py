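"""Built-in example data: a small worked example and the deep-vein-
thrombosis (DVT) diagnostic-accuracy source populations.

The DVT specifications describe two dichotomised index tests evaluated
against repeated compression ultrasonography in primary-care patients
suspected of DVT: a quantitative D-dimer assay (very sensitive, poorly
specific) and the calf-circumference-difference test, abnormal when the
affected calf is more than 3 cm larger than the other (moderately
sensitive and specific). The published accuracy estimates are tabulated at
source-population prevalences of 0.05, 0.10 and 0.20 with a fixed
population size of 1400.
"""

from __future__ import annotations

from .exceptions import ValidationError
from .simulate import SourceSpec
from .tables import CohortTable, NestedSample

__all__ = ["worked_example", "dvt_accuracy", "DVT_TESTS", "DVT_PREVALENCES"]

DVT_TESTS = ("d_dimer", "calf_difference")
DVT_PREVALENCES = (0.05, 0.1, 0.2)

# (test, prevalence) -> (sensitivity, specificity)
_DVT_ACCURACY = {
    ("d_dimer", 0.05): (0.96, 0.32),
    ("d_dimer", 0.1): (0.97, 0.33),
    ("d_dimer", 0.2): (0.96, 0.33),
    ("calf_difference", 0.05): (0.69, 0.65),
    ("calf_difference", 0.1): (0.68, 0.64),
    ("calf_difference", 0.2): (0.67, 0.65),
}


def worked_example() -> tuple[CohortTable, NestedSample]:
    """Toy cohort of 440 subjects with a 1-in-10 control sample.

    The cohort is (TP=30, FP=100, FN=10, TN=300); the nested sample keeps
    all 40 cases and 40 of the 400 controls (sampling fraction 0.1), giving
    the textbook identities PPV = 30/130 and NPV = 300/310 on both the full
    cohort and the corrected nested sample.
    """
    cohort = CohortTable(tp=30, fp=100, fn=10, tn=300)
    sample = NestedSample(
        a=30, c=10, b1=10, d1=30, cohort_controls=400, cohort_size=440
    )
    return cohort, sample


def dvt_accuracy(test: str, prevalence: float) -> SourceSpec:
    """Published DVT source-population accuracy for one test and prevalence.

    Parameters
    ----------
    test
        ``"d_dimer"`` or ``"calf_difference"``.
    prevalence
        One of 0.05, 0.1, 0.2.
    """
    key = (test, float(prevalence))
    if key not in _DVT_ACCURACY:
        raise ValidationError(
            f"no tabulated accuracy for test={test!r} at prevalence="
            f"{prevalence!r}; available tests {DVT_TESTS} at prevalences "
            f"{DVT_PREVALENCES}"
        )
    se, sp = _DVT_ACCURACY[key]
    return SourceSpec(
        prevalence=float(prevalence),
        sensitivity=se,
        specificity=sp,
        population_size=1400,
        label=f"{test} @ prevalence {prevalence}",
    )
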