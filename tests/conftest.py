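import numpy as np
import pytest

import mscsepsis as m


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort with strong planted drivers (raw, NaN holes)."""
    return m.generate_cohort(
        m.SynthConfig(n_patients=60, prevalence=0.3, d=8, drivers=(0, 1), delta=2.0,
                      missing_rate=0.15, seed=11)
    )


@pytest.fixture(scope="session")
def scaled_cohort(small_cohort):
    scaled, _params = m.preprocess_cohort(small_cohort)
    return scaled


@pytest.fixture()
def toy_anchors():
    """Four hand-placed anchors in 2-D."""
    A = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
    return m.AnchorSet(anchors=A, chosen_k=4, silhouette_by_k={})
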