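"""Shared fixtures and small-instance builders."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pftp import (
    BagOfWordsCorpus,
    GibbsState,
    Hyperparameters,
    LabelMatrix,
    LabelSpace,
    TopicPartition,
    Vocabulary,
    make_partition,
)
from pftp.inference import expand_tokens, init_state


@dataclass
class TinyInstance:
    """A small fully explicit instance for oracle comparisons."""

    corpus: BagOfWordsCorpus
    labels: LabelMatrix
    partition: TopicPartition
    hyper: Hyperparameters

    @property
    def subsets(self):
        return [list(s) for s in self.partition.subsets]


def make_tiny_instance(
    rng: np.random.Generator,
    n_docs: int = 2,
    n_labels: int = 2,
    m: int = 1,
    background_topics: int = 1,
    W: int = 3,
    max_tokens_per_doc: int = 3,
    hyper: Hyperparameters | None = None,
) -> TinyInstance:
    """Random tiny instance: every document gets >= 1 observed label and
    a random token multiset over a W-block vocabulary."""
    vocab = Vocabulary(tuple(f"B{w}" for w in range(W)))
    counts = np.zeros((n_docs, W), dtype=np.int64)
    for d in range(n_docs):
        n_tok = int(rng.integers(1, max_tokens_per_doc + 1))
        for w in rng.integers(0, W, size=n_tok):
            counts[d, w] += 1
    corpus = BagOfWordsCorpus(
        vocab, tuple(f"P{d}" for d in range(n_docs)), counts
    )
    background = background_topics > 0
    space = LabelSpace(
        tuple(f"GO:{i:07d}" for i in range(1, n_labels + 1)), background=background
    )
    rows = np.zeros((n_docs, space.n_extended), dtype=np.uint8)
    for d in range(n_docs):
        n_obs = int(rng.integers(1, n_labels + 1))
        rows[d, rng.choice(n_labels, size=n_obs, replace=False)] = 1
        if background:
            rows[d, -1] = 1
    labels = LabelMatrix(space, rows)
    partition = make_partition(n_labels, m, background_topics)
    if hyper is None:
        hyper = Hyperparameters(
            alpha=float(rng.uniform(0.1, 2.0)),
            beta=float(rng.uniform(0.1, 2.0)),
            lam=float(rng.uniform(0.1, 2.0)),
        )
    return TinyInstance(corpus, labels, partition, hyper)


def random_initialized_state(
    inst: TinyInstance, rng: np.random.Generator
) -> GibbsState:
    return init_state(inst.corpus, inst.labels, inst.partition, rng)


def token_arrays(inst: TinyInstance):
    return expand_tokens(inst.corpus)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
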