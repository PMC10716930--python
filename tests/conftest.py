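"""Shared fixtures: a synthetic patent universe with known ground truth,
its drug-patent database, a curated corpus and a trained language model.

The heavy artifacts are session-scoped and deterministic (fixed seeds), so
every test sees the same universe, partition and model.
"""

import numpy as np
import pytest

from patgen import fixtures, langmodel, patentdb

UNIVERSE_SEED = 20240101
SPLIT_SEED = 11
CORPUS_SEED = 5
FRAC_PATENTED = 0.6
N_UNIVERSE = 5000
N_CORPUS = 2000

#: desk-scale training configuration used throughout the suite
DESK_HP = langmodel.LMHyperParams(
    dropout=0.1,
    learning_rate=1e-3,
    batch_size=64,
    hidden_units=96,
    epochs=30,
    validation_fraction=0.1,
    seed=7,
    embedding_dim=32,
)


@pytest.fixture(scope="session")
def universe():
    spec = fixtures.FixtureSpec(n_target=N_UNIVERSE, seed=UNIVERSE_SEED)
    return fixtures.make_universe(spec)


@pytest.fixture(scope="session")
def split(universe):
    return fixtures.split_universe(universe, FRAC_PATENTED, SPLIT_SEED)


@pytest.fixture(scope="session")
def db(split, tmp_path_factory):
    path = tmp_path_factory.mktemp("db") / "drugpatent.sqlite"
    return patentdb.build_db(
        list(split.patented) + list(split.novel),
        split.patents,
        path=str(path),
        exclude_ocr=False,
    )


@pytest.fixture(scope="session")
def patented_std(split):
    return fixtures.as_standard(split.patented)


@pytest.fixture(scope="session")
def novel_std(split):
    return fixtures.as_standard(split.novel)


@pytest.fixture(scope="session")
def fixture_corpus(split):
    return fixtures.make_corpus(split.patented, N_CORPUS, CORPUS_SEED)


@pytest.fixture(scope="session")
def trained_lm(fixture_corpus):
    """GRU trained 30 epochs on the 2,000-molecule fixture corpus (~1 min)."""
    return langmodel.train_lm(fixture_corpus, DESK_HP)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
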