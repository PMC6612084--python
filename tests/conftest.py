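import pytest

from hemoqc import accumulate_effects, make_plan, select_optimal_levels
from hemoqc.synthetic_data import load_fixture


@pytest.fixture(scope="session")
def plan():
    """The reference experiment plan: 4 clinical factors, L9, 30 runs each."""
    return make_plan(load_fixture("table2"), runs_per_condition=30)


@pytest.fixture(scope="session")
def reference_results():
    """Per-condition counts of the reference experiment (270 runs)."""
    return load_fixture("table4")


@pytest.fixture(scope="session")
def reference_effects(plan, reference_results):
    return accumulate_effects(plan, reference_results)


@pytest.fixture(scope="session")
def reference_selection(reference_effects):
    return select_optimal_levels(reference_effects, direction="smaller")
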