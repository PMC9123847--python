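"""Shared synthetic fixtures (session-scoped; everything is generated)."""

import numpy as np
import pytest

from deltatrack import model, synthetic


@pytest.fixture(scope="session")
def human_cohort():
    return synthetic.make_human_cohort(synthetic.HumanCohortSpec(seed=11))


@pytest.fixture(scope="session")
def human_fit(human_cohort):
    return model.fit_natural_history(human_cohort.pairs, units="years")


@pytest.fixture(scope="session")
def mouse_cohort():
    return synthetic.make_mouse_cohort(synthetic.MouseCohortSpec(seed=7))


@pytest.fixture(scope="session")
def mouse_control_pairs(mouse_cohort):
    ctrl = mouse_cohort.visits[mouse_cohort.visits["group"] == "AS_control"]
    visits = [
        model.VisitRecord(r.mouse_id, r.age, r.delta, r.group)
        for r in ctrl.itertuples(index=False)
    ]
    return model.build_pairs(visits, "all_combinations")


@pytest.fixture(scope="session")
def mouse_fit(mouse_control_pairs):
    return model.fit_natural_history(mouse_control_pairs, units="weeks")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
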