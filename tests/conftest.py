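import numpy as np
import pytest

from prenmr import synthetic, workflow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gt_noiseless():
    return synthetic.default_ground_truth(noise_sigma=0.0)


@pytest.fixture
def mock_study(tmp_path, gt_noiseless):
    """Noiseless mock study directory; returns the config path."""
    return workflow.write_mock_study(tmp_path / "study", gt_noiseless)
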