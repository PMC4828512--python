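import numpy as np
import pytest

from hipposeg.phantom import PhantomSpec, generate_cohort

# A down-scaled phantom spec for pipeline-level tests: same statistical
# structure as the default (minority foreground, texture, bias, noise) on a
# grid small enough that feature extraction stays fast.
SMALL_SPEC = PhantomSpec(
    grid_shape=(24, 28, 28),
    semi_axes=(4.5, 5.5, 5.5),
    max_translation=2,
    deform_smoothness=4.0,
)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, table = generate_cohort(12, SMALL_SPEC, seed=7)
    return cohort, table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
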