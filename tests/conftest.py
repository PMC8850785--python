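import numpy as np
import pytest

from painlimits import ThresholdSpec, draw_threshold
from painlimits.censoring import Sample, SubjectMean


def make_sample(beta0, beta1, alpha, n, male_fraction=0.5, seed=0,
                row="12", load="pinching", contact="blunt"):
    """Synthetic sample of exact per-subject means from known truth."""
    rng = np.random.default_rng(seed)
    spec = ThresholdSpec(int(row.split("/")[0]), load, contact,
                         beta0, beta1, alpha)
    n_male = int(round(n * male_fraction))
    members = []
    for i in range(n):
        g = 1 if i < n_male else 0
        y = draw_threshold(spec, g, rng)
        members.append(SubjectMean(f"S{i:03d}", g, y, n_repeats=1))
    return Sample(row, load, contact, members)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def forehead_spec():
    # semi-sharp pinching at the forehead: gender effect fixed at zero
    return ThresholdSpec(1, "pinching", "semi-sharp", 4.22, 0.0, 0.46)
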