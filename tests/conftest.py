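import hypothesis
import pytest
from hypothesis import strategies as st

from nccpv import NestedSample
from nccpv.datasets import worked_example

# derandomised so the suite is reproducible run-to-run
hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_cohort():
    return worked_example()[0]


@pytest.fixture(scope="session")
def toy_sample():
    return worked_example()[1]


@st.composite
def nested_samples(draw, min_cell=0, max_cell=200):
    """Random valid nested case-control samples.

    ``min_cell`` >= 1 keeps all four cells positive (needed for the
    saturated logistic fit and the delta-method approaches).
    """
    a = draw(st.integers(min_cell, max_cell))
    c = draw(st.integers(max(min_cell, 1 - a), max_cell))
    b1 = draw(st.integers(min_cell, max_cell))
    d1 = draw(st.integers(max(min_cell, 1 - b1), max_cell))
    extra = draw(st.integers(0, 500))
    controls = b1 + d1 + extra
    return NestedSample(
        a=a, c=c, b1=b1, d1=d1,
        cohort_controls=controls, cohort_size=a + c + controls,
    )
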