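import numpy as np
import pytest

from gazeattr.model import desk_config
from gazeattr.synth import SyntheticSpec, build_dataset
from gazeattr.types import Fixation, Scanpath


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small synthetic corpus shared by read-only tests."""
    spec = SyntheticSpec(n_images=6, n_participants_per_group=3, image_size=(32, 32), seed=42)
    records, truth = build_dataset(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def tiny_config():
    """A model configuration small enough for per-sample full gradients."""
    return desk_config(
        conv_filters=(2,), lstm_hidden=4, input_image_size=(8, 8), epochs=2, batch_size=8
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_scanpath(xy_dur, image_id="img_000", group="TD", participant=0):
    fixations = [Fixation(x, y, d) for x, y, d in xy_dur]
    return Scanpath(fixations, participant, image_id, group)
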