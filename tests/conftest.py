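import numpy as np
import pytest

from fundusfusion.phantom import PhantomSpec, generate_cohort, render_fundus_phantom


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(
        n_healthy=6, n_early=6, n_moderate=3, n_severe=3,
        image_rows=120, image_cols=180, thinning_fraction_early=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_image(tiny_spec, tiny_cohort):
    return render_fundus_phantom(tiny_cohort[0], tiny_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
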