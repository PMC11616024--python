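import dataclasses

import pytest

import methylmark as mm
from methylmark.synthetic_data import CohortSpec


@pytest.fixture(scope="session")
def bundle1():
    """Default-layout synthetic study, seed 1 (shared, read-only)."""
    return mm.simulate_study(mm.default_config(seed=1))


@pytest.fixture(scope="session")
def cascade1(bundle1):
    return mm.run_cascade(bundle1, mm.CascadeParams())


@pytest.fixture(scope="session")
def model1(bundle1, cascade1):
    return mm.fit_logistic(
        bundle1.matrix, bundle1.sheet, sorted(cascade1.final_markers), "TRAIN"
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Cheap study: 40 sites, 3 cohorts, for unit-level checks."""
    cfg = dataclasses.replace(
        mm.default_config(seed=11),
        n_specific=3,
        n_pancancer=4,
        n_background=6,
        n_neutral=27,
        cohorts=(
            CohortSpec("TRAIN", "COAD", 15, 15),
            CohortSpec("BLOOD", "BLOOD", 0, 20),
            CohortSpec("OT_BRCA", "BRCA", 12, 6),
            CohortSpec("OT_LUAD", "LUAD", 12, 6),
        ),
    )
    return mm.simulate_study(cfg)
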