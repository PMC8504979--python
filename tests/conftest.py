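import numpy as np
import pandas as pd
import pytest

from bnimpute import MixedDataset, VariableSpec


@pytest.fixture
def cont3():
    """Three correlated continuous variables (chain A -> B -> C), n=400."""
    rng = np.random.default_rng(11)
    a = rng.normal(size=400)
    b = 0.6 * a + rng.normal(size=400)
    c = 0.6 * b + rng.normal(size=400)
    frame = pd.DataFrame({"A": a, "B": b, "C": c})
    specs = [VariableSpec(n, "continuous") for n in "ABC"]
    return MixedDataset(specs, frame)


@pytest.fixture
def mixed4():
    """Two discrete + two continuous variables with real dependence."""
    rng = np.random.default_rng(7)
    n = 300
    g = rng.choice(["aa", "ab", "bb"], size=n, p=[0.25, 0.5, 0.25])
    shift = np.select([g == "aa", g == "ab"], [0.0, 0.7], default=1.4)
    x = shift + rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    d = np.where(rng.random(n) < 0.5, "yes", "no")
    specs = [
        VariableSpec("g", "discrete", levels=("aa", "ab", "bb")),
        VariableSpec("d", "discrete", levels=("no", "yes")),
        VariableSpec("x", "continuous"),
        VariableSpec("y", "continuous"),
    ]
    return MixedDataset(specs, pd.DataFrame({"g": g, "d": d, "x": x, "y": y}))


def make_dataset(columns, discrete=(), genetic=()):
    """Build a MixedDataset from a dict of column arrays/lists."""
    specs = []
    for name in columns:
        specs.append(
            VariableSpec(
                name,
                "discrete" if name in discrete else "continuous",
                genetic=name in genetic,
            )
        )
    return MixedDataset(specs, pd.DataFrame(dict(columns)))
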