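import numpy as np
import pytest

from cisfootprint.pwm import PWM, bundled_nfkb_pwms


@pytest.fixture(scope="session")
def pwms():
    return bundled_nfkb_pwms()


@pytest.fixture
def toy_pwm():
    # 3-column matrix with unambiguous consensus GCA
    counts = np.array([
        [1.0, 0.0, 9.0],
        [2.0, 8.0, 1.0],
        [6.0, 1.0, 0.0],
        [1.0, 1.0, 0.0],
    ])
    return PWM(id="TOY1", tf_name="toy", counts=counts)


def random_pwm(rng, length, max_count=20):
    counts = rng.integers(0, max_count, size=(4, length)).astype(float)
    # guarantee every column has a positive count
    counts[rng.integers(0, 4), :] += 1
    return PWM(id="RND", tf_name="rnd", counts=counts)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
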