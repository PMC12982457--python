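"""Shared fixtures.

The expensive end-to-end objects (the cross-validated trimodal study and
a fitted gait pipeline) are session-scoped: the acceptance checks and
several unit tests read different aspects of the same fitted artifacts.
"""

from __future__ import annotations

import numpy as np
import pytest

from parkfuse.gait import GaitUnimodalModel
from parkfuse.model import TrimodalPDModel
from parkfuse.synthetic import easy_cohort_specs, make_trimodal_cohorts

E2E_SEED = 0
E2E_N_PER_CLASS = 15


@pytest.fixture(scope="session")
def cohorts():
    """Easy-preset synthetic study cohorts (15 PD + 15 HC per modality)."""
    return make_trimodal_cohorts(
        easy_cohort_specs(E2E_N_PER_CLASS, E2E_N_PER_CLASS, seed=E2E_SEED))


@pytest.fixture(scope="session")
def e2e_results(cohorts):
    """Full 5-fold cross-validated trimodal study at the fixed seed."""
    model = TrimodalPDModel(cohorts, encoder_epochs=(8, 10, 10))
    return model.fit(seed=E2E_SEED)


@pytest.fixture(scope="session")
def gait_fit(cohorts):
    """Gait pipeline fitted on the full gait cohort (for cluster-recovery
    and loss-trace checks)."""
    model = GaitUnimodalModel(epochs=10, seed=E2E_SEED)
    model.fit(cohorts.samples("gait"))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
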