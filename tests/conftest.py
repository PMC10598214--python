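import numpy as np
import pytest

import pepprior as pp


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus at seed 7 (the recovery-study conditions)."""
    return pp.generate_labeled_corpus(pp.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def corpus_splits(default_corpus):
    assignments = pp.cluster_split(default_corpus.sequences, seed=7)
    split_of = {a.sequence_id: a.split for a in assignments}
    sets = {"train": [], "val": [], "test": []}
    for ls in default_corpus.labeled:
        sets[split_of[ls.sequence_id]].append(ls)
    return sets


@pytest.fixture(scope="session")
def trained_model(corpus_splits):
    """One-hot-backend model trained once per session on the seed-7 corpus."""
    backend = pp.OneHotContextBackend(radius=7)
    model, report = pp.train(
        backend,
        pp.HeadConfig(),
        corpus_splits["train"],
        corpus_splits["val"],
        pp.TrainingConfig(max_epochs=40, patience=3, seed=7),
    )
    return model, report


def random_probability_curve(rng, n, quantize=True, with_mask=False):
    """A random per-position probability track; quantized so ties occur."""
    p = rng.random(n)
    if quantize:
        p = np.round(p, 1)
    mask = np.ones(n, dtype=bool)
    if with_mask:
        mask = rng.random(n) > 0.2
        if not mask.any():
            mask[rng.integers(n)] = True
    return p, mask
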