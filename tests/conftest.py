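import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_phenotypes():
    """2 varieties x 2 indicators, 2 replicates, values chosen for hand arithmetic."""
    rows = []
    values = {
        # (variety, indicator): (control reps, treatment reps)
        ("A", "ind1"): ((4, 4), (2, 2)),   # ratio 0.5
        ("A", "ind2"): ((2, 2), (1, 3)),   # ratio 1.0
        ("B", "ind1"): ((5, 5), (10, 10)),  # ratio 2.0
        ("B", "ind2"): ((1, 3), (4, 4)),   # ratio 2.0
    }
    for (var, ind), (ctrl, trt) in values.items():
        for rep, v in enumerate(ctrl, 1):
            rows.append((var, ind, "control", rep, float(v)))
        for rep, v in enumerate(trt, 1):
            rows.append((var, ind, "treatment", rep, float(v)))
    return pd.DataFrame(
        rows, columns=["variety", "indicator", "condition", "replicate", "value"]
    )


def random_matrix(rng, n, p, positive=False):
    x = rng.standard_normal((n, p))
    if positive:
        x = np.exp(x)
    return pd.DataFrame(x, columns=[f"v{j}" for j in range(p)])
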