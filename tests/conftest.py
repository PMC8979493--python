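import numpy as np
import pytest

from sdx.features import FeatureMatrix
from sdx.optimize import WeightedInstance, _find_twohit_pairs, build_instance


def random_instance(rng, n_max=30, m_max=12, twohit_prob=0.4):
    """Random weighted instance, occasionally with same-gene (I, O) pairs."""
    n = int(rng.integers(4, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    direction = "increased" if rng.random() < 0.5 else "decreased"
    d = rng.normal(0, 1, n)
    # guarantee responsive mass
    if direction == "increased" and not (d < 0).any():
        d[0] = -abs(d[0]) - 0.1
    if direction == "decreased" and not (d > 0).any():
        d[0] = abs(d[0]) + 0.1

    labels = []
    i = 0
    g = 0
    while i < m:
        if twohit_prob > 0 and i + 1 < m and rng.random() < twohit_prob:
            labels += [f"GX{g}(I)", f"GX{g}(O)"]
            i += 2
        else:
            cls = rng.choice(["A", "I", "O"])
            labels.append(f"GY{g}({cls})")
            i += 1
        g += 1
    p = rng.uniform(0.1, 0.5)
    a = (rng.random((m, n)) < p).astype(np.int8)
    fm = FeatureMatrix(labels, [f"s{j}" for j in range(n)], a)
    return build_instance(d, direction, fm)


def unit_instance(a, direction="decreased", labels=None):
    """Instance with d' = 1, rho = 1 for all samples (Dendrix regime)."""
    a = np.asarray(a, dtype=np.int8)
    m, n = a.shape
    labels = labels or [f"f{i}" for i in range(m)]
    fm = FeatureMatrix(labels, [f"s{j}" for j in range(n)], a)
    return WeightedInstance(np.ones(n), np.ones(n), direction, fm, _find_twohit_pairs(fm))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
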