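import numpy as np
import pandas as pd
import pytest

from lcgrowth.basis import SplineSpec
from lcgrowth.lcmm import GrowthData, MixtureSpec
from lcgrowth.simulate import toy_reference


@pytest.fixture(scope="session")
def charts():
    return toy_reference()


def make_two_class_panel(n=120, sigma=0.2, seed=0, delta=3.0):
    """A small well-separated two-class panel on a 6-visit schedule."""
    rng = np.random.default_rng(seed)
    ages = np.array([0.0, 0.5, 1.0, 2.0, 3.5, 5.0])
    rows = []
    for i in range(n):
        g = i % 2
        b0 = rng.normal(0, 0.3)
        mean = (delta / 2 if g == 0 else -delta / 2) + 0.1 * ages
        z = mean + b0 + rng.normal(0, sigma, size=len(ages))
        for t, zv in zip(ages, z):
            rows.append((f"s{i:03d}", "y", t, zv, "TOY", t))
    return pd.DataFrame(
        rows, columns=["subject_id", "response", "age_years", "z", "chart_used", "corrected_age_years"]
    )


@pytest.fixture(scope="session")
def two_class_panel():
    return make_two_class_panel()


@pytest.fixture(scope="session")
def two_class_fit(two_class_panel):
    from lcgrowth.lcmm import fit

    data = GrowthData.from_panel(two_class_panel, ("y",))
    spec = MixtureSpec(responses=("y",), K=2, spline={"y": SplineSpec((1.0, 2.5))})
    return fit(data, spec, n_restarts=3, seed=0)
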