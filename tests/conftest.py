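import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def groups_to_frame(groups: dict) -> pd.DataFrame:
    """Stack a {label: values} mapping into a tidy (group, y) frame."""
    return pd.concat(
        [pd.DataFrame({"group": g, "y": np.asarray(v, dtype=float)}) for g, v in groups.items()],
        ignore_index=True,
    )


@pytest.fixture
def mixed_variance_fixture():
    """Four unbalanced normal groups with unequal variances (frozen seed).

    The expected Tukey/Welch/Kruskal-Wallis values asserted against this
    fixture were computed independently in R (TukeyHSD, oneway.test,
    kruskal.test) and frozen into the tests.
    """
    rng = np.random.default_rng(42)
    return {
        "A": rng.normal(10, 1, 8),
        "B": rng.normal(11, 1.5, 10),
        "C": rng.normal(9, 2, 9),
        "D": rng.normal(12, 1, 7),
    }
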