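import numpy as np
import pandas as pd
import pytest

from hybfact.containers import Factorial
from hybfact.simdata import SimulationConfig, simulate_factorial


@pytest.fixture
def tiny_factorial() -> Factorial:
    """2x2 complete factorial with yields 1..4."""
    crosses = pd.DataFrame(
        {
            "parent1": ["A", "A", "B", "B"],
            "parent2": ["X", "Y", "X", "Y"],
            "yield": [1.0, 2.0, 3.0, 4.0],
        }
    )
    return Factorial(["A", "B"], ["X", "Y"], crosses)


@pytest.fixture
def incomplete_factorial() -> Factorial:
    """2x2 factorial with one missing cell, used by the yield-feature examples."""
    crosses = pd.DataFrame(
        {
            "parent1": ["A", "A", "B"],
            "parent2": ["X", "Y", "X"],
            "yield": [10.0, 12.0, 8.0],
        }
    )
    return Factorial(["A", "B"], ["X", "Y"], crosses)


@pytest.fixture(scope="session")
def additive_factorial():
    """Purely additive large factorial (no SCA, no error)."""
    cfg = SimulationConfig(
        n1=60, n2=20, n_crosses=600, sigma2_sca=0.0, sigma2_e=0.0, seed=101
    )
    return simulate_factorial(cfg)


@pytest.fixture(scope="session")
def standard_factorial():
    """Mid-size factorial with all variance components active."""
    cfg = SimulationConfig(
        n1=60, n2=20, n_crosses=600, sigma2_sca=2.0, sigma2_e=0.25, seed=7
    )
    return simulate_factorial(cfg)


def random_small_factorial(rng: np.random.Generator) -> Factorial:
    """A random factorial with n1, n2 <= 6 for brute-force checks."""
    n1 = int(rng.integers(2, 7))
    n2 = int(rng.integers(2, 7))
    p1 = [f"A{k}" for k in range(n1)]
    p2 = [f"B{k}" for k in range(n2)]
    all_pairs = [(i, j) for i in p1 for j in p2]
    n_c = int(rng.integers(max(n1, n2), n1 * n2 + 1))
    # rejection sample until every parent is covered
    while True:
        idx = rng.choice(len(all_pairs), size=n_c, replace=False)
        pairs = [all_pairs[k] for k in idx]
        if {i for i, _ in pairs} == set(p1) and {j for _, j in pairs} == set(p2):
            break
    crosses = pd.DataFrame(
        {
            "parent1": [i for i, _ in pairs],
            "parent2": [j for _, j in pairs],
            "yield": rng.normal(100, 5, n_c),
        }
    )
    return Factorial(p1, p2, crosses)
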