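import numpy as np
import pytest

from engramsim.nn_core import LayerShapes, NetworkParams, init_network


def jitter_params(params: NetworkParams, seed: int = 0,
                  sd: float = 0.3) -> NetworkParams:
    """Move parameters to a generic point.

    Zero-initialized biases can leave tiny networks exactly on ReLU
    kinks, where central finite differences straddle the kink and
    disagree with the subgradient; small seeded noise on every parameter
    avoids that measure-zero set.
    """
    rng = np.random.default_rng(seed)
    for name in params._ARRAYS:
        arr = getattr(params, name)
        arr[...] += rng.normal(0.0, sd, arr.shape)
    return params


@pytest.fixture
def reduced_shapes() -> LayerShapes:
    """4x4 input, 2+2 filters, small FC — cheap finite-difference runs."""
    return LayerShapes(input_hw=4, in_channels=1, conv1_filters=2,
                       conv2_filters=2, kernel=2, pool_after_conv1=False,
                       pool_after_conv2=False, fc_units=5)


@pytest.fixture
def pooled_shapes() -> LayerShapes:
    """Reduced net that still exercises 2x2 max-pool gradient routing."""
    return LayerShapes(input_hw=8, in_channels=1, conv1_filters=2,
                       conv2_filters=3, kernel=3, pool_after_conv1=True,
                       pool_after_conv2=False, fc_units=4)


@pytest.fixture
def reduced_net(reduced_shapes):
    return jitter_params(init_network(reduced_shapes, 3, seed=11), seed=42)
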