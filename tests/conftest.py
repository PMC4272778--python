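import numpy as np
import pytest

from nestedloop import (
    FactorialDesign,
    ParameterSpec,
    example_design,
    synth_factorial_results,
)


@pytest.fixture(scope="session")
def meta_design() -> FactorialDesign:
    """The 768-scenario example design: OR x selection x p_c x tau2 x k."""
    return example_design()


@pytest.fixture(scope="session")
def six_method_table(meta_design):
    """Deterministic 768-row table with six methods, no noise.

    The linear predictor loads mostly on the outermost parameters so the
    table looks like a plausible simulation-study summary.
    """
    return synth_factorial_results(
        meta_design,
        main_effects={
            "or": [0.0, -0.29, -0.40, -0.69],
            "selection": [0.0, -0.05, -0.10, -0.20],
            "p_c": [0.0, 0.01, 0.03, 0.06],
        },
        methods=["peto", "peters", "trimfill", "m1", "m2", "m3"],
        criteria=["est"],
        method_offsets={"peters": 0.01, "trimfill": 0.02, "m1": 0.03,
                        "m2": 0.04, "m3": 0.05},
        noise_sd=0.0,
    )


@pytest.fixture()
def tiny_design() -> FactorialDesign:
    return FactorialDesign([
        ParameterSpec("a", [1, 2], direction="reversed"),
        ParameterSpec("b", ["x", "y"]),
    ])


def random_design(rng: np.random.Generator, max_params: int = 4,
                  max_levels: int = 4) -> FactorialDesign:
    """A random small factorial design with random directions."""
    n_params = int(rng.integers(1, max_params + 1))
    params = []
    for i in range(n_params):
        n_levels = int(rng.integers(1, max_levels + 1))
        levels = list(rng.choice(100, size=n_levels, replace=False))
        direction = "reversed" if rng.random() < 0.5 else "as-given"
        params.append(ParameterSpec(f"p{i}", levels, direction))
    return FactorialDesign(params)
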