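import numpy as np
import pytest

from dfspectrum import JointSFS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_joint_sfs(rng, n=None, n3=None, integer=True, max_count=20):
    """A random small polarized joint SFS with equal P1/P2 sizes."""
    n = n or int(rng.integers(2, 9))
    n3 = n3 or int(rng.integers(1, 9))
    shape = (n + 1, n + 1, n3 + 1)
    if integer:
        counts = rng.integers(0, max_count + 1, shape).astype(float)
    else:
        counts = rng.random(shape) * max_count
    if counts.sum() == 0:
        counts[0, 1, 1] = 1.0
    return JointSFS(counts, polarized=True)
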