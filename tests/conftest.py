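"""Shared fixtures: tiny synthetic corpora and fast estimator parameter sets."""

import numpy as np
import pytest

from lncmir import FixtureSpec, generate

#: Fast parameters for tests that exercise pipeline plumbing, not accuracy.
FAST_FEATURIZER = dict(doc_epochs=5, n_walks=4, walk_len=10, k_nn=5, top_k=5)
FAST_CLASSIFIER = dict(conv_blocks=(8,), dense_units=(16,), epochs=4, patience=0,
                       validation_fraction=0.0, batch_size=32)


@pytest.fixture(scope="session")
def tiny_corpus():
    """12 lncRNAs, 6 miRNAs, 20 planted-signal positive pairs."""
    spec = FixtureSpec(n_lnc=12, n_mir=6, n_pos=20, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def fixture_corpus():
    """The default desk-scale corpus: 50 lncRNAs, 20 miRNAs, 100 positives."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
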