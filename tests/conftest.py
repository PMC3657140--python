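import numpy as np
import pytest

from emoconn.model_space import (
    build_modulatory_space,
    to_dcm_spec,
    winner_structural_model,
)
from emoconn.task_design import PAPER_BLOCK_ORDER, parse_block_order


@pytest.fixture(scope="session")
def paper_design():
    return parse_block_order(PAPER_BLOCK_ORDER)


@pytest.fixture(scope="session")
def short_design():
    """A compact design for fast simulation tests (6 blocks, 60 volumes)."""
    return parse_block_order("NHSNFR", 21.0, n_volumes=60)


@pytest.fixture(scope="session")
def modulatory_models():
    return {m.id: m for m in build_modulatory_space()}


@pytest.fixture(scope="session")
def winner():
    return winner_structural_model()


@pytest.fixture(scope="session")
def spec_m21_sad(winner, modulatory_models):
    return to_dcm_spec(winner, modulatory_models[21], "sad")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
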