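import numpy as np
import pytest

import festuca_demography as fd
from festuca_demography import reference


@pytest.fixture(scope="session")
def printed_matrices():
    """The four transcribed published projection matrices."""
    return reference.PRINTED_MATRICES


@pytest.fixture(scope="session")
def field_means():
    return reference.FIELD_MEANS


@pytest.fixture(scope="session")
def field_sems():
    return reference.FIELD_SEMS


@pytest.fixture(scope="session")
def ns_natural(printed_matrices):
    return printed_matrices[("NS", "natural")]


@pytest.fixture(scope="session")
def reference_truths():
    """GroupTruth per group at the field design sizes."""
    return {
        g: fd.GroupTruth(
            rates=reference.FIELD_MEANS[g],
            transmission=(
                reference.TRANSMISSION[g[1]] if g[0] == "S" else None
            ),
        )
        for g in reference.GROUPS
    }


@pytest.fixture(scope="session")
def census(reference_truths):
    """One synthetic census at the field design, fixed seed."""
    return fd.generate_census(reference_truths, seed=20_080_601)


def random_stage_matrix(rng: np.random.Generator) -> fd.StageMatrix:
    """A random valid life-cycle matrix with a positive growth loop."""
    s2 = rng.uniform(0.05, 1.0)
    e1 = rng.uniform(0.0, 1.0)
    return fd.StageMatrix.from_elements(
        F=rng.uniform(0.1, 80.0),
        G_J1=rng.uniform(0.05, 1.0),
        G_J2=(1 - e1) * s2,
        G_A1=e1 * s2,
        G_A2=rng.uniform(0.0, 1.0),
        S_A=rng.uniform(0.0, 0.99),
    )
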