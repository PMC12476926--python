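import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_observations():
    """One species at 2 sites, 6 individuals each; a second species at 4 sites."""
    rows = []
    rng = np.random.default_rng(7)
    for sp, sites in (("spA", ["S1", "S2"]), ("spB", ["S1", "S2", "S3", "S4"])):
        for site in sites:
            for v in np.exp(rng.normal(0.0, 0.3, size=6)):
                rows.append({"site": site, "species": sp, "trait": "wood_density", "value": v})
    return pd.DataFrame(rows)


def two_pass_variance(values):
    """Independent textbook n-1 variance of log values (test oracle)."""
    logs = [np.log(v) for v in values]
    m = sum(logs) / len(logs)
    return sum((l - m) ** 2 for l in logs) / (len(logs) - 1)
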