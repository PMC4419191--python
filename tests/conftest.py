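import numpy as np
import pytest

from pathsea.core import SampleDesign
from pathsea.synth import StudySpec, generate_study


def make_design(
    n_conditions: int = 2,
    units_per_condition: int = 2,
    tech_reps: int = 1,
    label: str = "D",
) -> SampleDesign:
    """Small fully-crossed design for unit tests."""
    sample_ids, cond_of, unit_of, ds_of = [], {}, {}, {}
    for ci in range(n_conditions):
        c = f"c{ci + 1}"
        for b in range(units_per_condition):
            u = f"u{ci + 1}_{b + 1}"
            for t in range(tech_reps):
                s = f"{label}_{u}_t{t + 1}"
                sample_ids.append(s)
                cond_of[s] = c
                unit_of[s] = u
                ds_of[s] = label
    return SampleDesign(tuple(sample_ids), cond_of, unit_of, ds_of)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    return generate_study(StudySpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
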