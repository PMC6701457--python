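import numpy as np
import pytest

from traitsmm import (
    ObservationMap,
    RateMatrix,
    kron_sum_amalgamate,
)


@pytest.fixture
def tail_matrix() -> RateMatrix:
    """Character T: tail absent/present with gain rate alpha, loss rate beta."""
    return RateMatrix.binary(0.3, 0.7, states=("a", "p"))


@pytest.fixture
def color_matrix() -> RateMatrix:
    """Character C: tail color red/blue."""
    return RateMatrix.binary(0.2, 0.5, states=("r", "b"))


@pytest.fixture
def smm_ind(tail_matrix, color_matrix) -> RateMatrix:
    """Independent amalgam over (ar, ab, pr, pb)."""
    return kron_sum_amalgamate([tail_matrix, color_matrix])


@pytest.fixture
def tcp_obs_map() -> ObservationMap:
    return ObservationMap.from_dict(
        {"a": {"ar", "ab"}, "r": {"pr"}, "b": {"pb"}}, inapplicable="a"
    )


def random_rate_matrix(rng: np.random.Generator, k: int, states=None) -> RateMatrix:
    off = rng.uniform(0.1, 2.0, size=(k, k))
    return RateMatrix.from_offdiag(
        states if states is not None else [f"s{i}" for i in range(k)], off
    )
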