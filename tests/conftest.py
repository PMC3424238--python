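import numpy as np
import pytest

from episeq.evaluation import loocv
from episeq.io import ChainRecord
from episeq.synthetic import (
    COMPLEMENTARY_ENCODERS,
    SyntheticConfig,
    generate_dataset,
    preset_complementary,
    preset_null,
)
from episeq.windowing import extract_windows

#: small forests for protocol-level tests where only the plumbing matters
FAST_FOREST = {"n_estimators": 25}


@pytest.fixture(scope="session")
def tiny_records():
    """Four short single-chain antigens with all tracks, modest signal."""
    cfg = SyntheticConfig(
        n_antigens=4,
        chain_length_range=(60, 70),
        chains_per_antigen=(1, 1),
        patch_length_range=(10, 15),
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def tiny_chain(tiny_records):
    return tiny_records[0].chains[0]


def make_windows(seq, L=5, labels=None, **tracks):
    """Windows of a throwaway chain built from a bare sequence."""
    chain = ChainRecord("A", seq, labels=labels, **tracks)
    return extract_windows(chain, L, "t")


@pytest.fixture(scope="session")
def complementary_loocv():
    """Full LOOCV on the complementary-signals preset (shared: expensive)."""
    records = generate_dataset(preset_complementary(seed=1))
    return loocv(
        records,
        encoder_names=COMPLEMENTARY_ENCODERS,
        weights="search",
        seed=1,
    )


@pytest.fixture(scope="session")
def null_loocv():
    """LOOCV of the composition sub-classifier on the no-signal preset."""
    records = generate_dataset(preset_null(seed=1))
    return loocv(records, encoder_names=("composition",), weights=None, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
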