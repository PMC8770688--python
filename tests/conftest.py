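import numpy as np
import pytest

from arrowsim.task_environment import (
    CONTINUOUS_ATTRIBUTES,
    FitnessLandscape,
    default_landscapes,
    make_landscape,
)


@pytest.fixture
def landscapes():
    return default_landscapes()


@pytest.fixture
def landscape(landscapes):
    return landscapes[0]


def one_d_landscape(optimum: int, width: float = 20.0, noise_sd: float = 0.0,
                    attribute: str = "length") -> FitnessLandscape:
    """A landscape where only one attribute contributes (its maximum is the
    full 1000-calorie ceiling); useful for 1-D trajectory oracles."""
    return FitnessLandscape(
        season=1,
        optima={a: optimum if a == attribute else 50 for a in CONTINUOUS_ATTRIBUTES},
        maxima={a: 1000.0 if a == attribute else 0.0 for a in CONTINUOUS_ATTRIBUTES},
        widths={a: width for a in CONTINUOUS_ATTRIBUTES},
        noise_sd=noise_sd,
    )


def random_landscape(rng: np.random.Generator, noise_sd: float = 0.0) -> FitnessLandscape:
    """A random calibrated unimodal landscape."""
    maxima = rng.uniform(100, 500, 3)
    maxima = maxima / maxima.sum() * 1000.0
    return make_landscape(
        {
            "season": 1,
            "optima": {a: int(rng.integers(1, 101)) for a in CONTINUOUS_ATTRIBUTES},
            "maxima": dict(zip(CONTINUOUS_ATTRIBUTES, maxima)),
            "widths": {a: float(rng.uniform(8, 40)) for a in CONTINUOUS_ATTRIBUTES},
            "noise_sd": noise_sd,
        }
    )
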