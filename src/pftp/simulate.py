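"""Simulation from the model's own generative process.

Used as the source of test fixtures and for parameter-recovery
experiments: sample a true model (per-label topic distributions pi_l on
each label's subset, per-topic word distributions theta_k), then sample
labeled corpora from it (per protein: an admissible label set, Dirichlet
label weights psi_d, and per token label -> topic -> word draws).

The default corpus emulates a small, strongly structured multi-label
problem — 300 proteins, 4 labels with 2 topics each plus one background
topic, a 60-block vocabulary, 2 labels per protein and 120 tokens per
protein — not the k-mer statistics of a real proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus import AMINO_ACIDS, BagOfWordsCorpus, Vocabulary
from .errors import ConfigurationError
from .model import (
    GibbsState,
    Hyperparameters,
    LabelMatrix,
    LabelSpace,
    TopicPartition,
    make_partition,
)

#: Fixture defaults: D, L, m, B, W, labels/protein, tokens/protein and the
#: generating Dirichlet concentrations.
DEFAULT_FIXTURE = dict(
    D=300, L=4, m=2, B=1, W=60, labels_per_doc=2, tokens_per_doc=120,
    alpha=0.5, beta=0.5, lam=0.1,
)


@dataclass
class TrueModel:
    """Ground-truth parameters a corpus is generated from."""

    partition: TopicPartition
    pi: np.ndarray  # (L', K), zero outside each label's subset
    theta: np.ndarray  # (K, W)
    hyper: Hyperparameters
    label_space: LabelSpace


@dataclass
class SyntheticCorpus:
    """A generated corpus with its full ground truth."""

    corpus: BagOfWordsCorpus
    labels: LabelMatrix
    psi: np.ndarray  # (D, L') true label weights
    doc_of: np.ndarray  # token-level truths
    word_of: np.ndarray
    label_of: np.ndarray
    topic_of: np.ndarray

    _partition: TopicPartition = None

    def as_state(self) -> GibbsState:
        """Load the true token assignments as a Gibbs state."""
        return GibbsState(
            doc_of=self.doc_of,
            word_of=self.word_of,
            label_of=self.label_of,
            topic_of=self.topic_of,
            n_docs=self.corpus.n_docs,
            n_words=self.corpus.vocabulary.size,
            partition=self._partition,
        )


def synthetic_vocabulary(W: int) -> Vocabulary:
    """A deterministic W-block vocabulary of 2-mer-like strings."""
    blocks = []
    for a, b in product(AMINO_ACIDS, AMINO_ACIDS):
        blocks.append(a + b)
        if len(blocks) == W:
            break
    if len(blocks) < W:
        raise ConfigurationError(f"cannot build {W} blocks from 2-mers")
    return Vocabulary(tuple(sorted(blocks)))


def sample_model(
    L: int,
    m: int,
    B: int,
    W: int,
    hyper: Hyperparameters,
    seed: int,
    label_ids: tuple[str, ...] | None = None,
) -> TrueModel:
    """Draw a true model: pi_l ~ Dir(alpha) on each label's subset,
    theta_k ~ Dir(lambda) on the vocabulary."""
    rng = np.random.default_rng(seed)
    partition = make_partition(L, m, B)
    space = LabelSpace(
        labels=label_ids or tuple(f"GO:{i:07d}" for i in range(1, L + 1)),
        background=B > 0,
    )
    Lp = partition.n_extended
    pi = np.zeros((Lp, partition.n_topics))
    for l in range(Lp):
        sub = list(partition.subset_of(l))
        pi[l, sub] = rng.dirichlet(np.full(len(sub), hyper.alpha))
    theta = rng.dirichlet(np.full(W, hyper.lam), size=partition.n_topics)
    return TrueModel(partition, pi, theta, hyper, space)


def sample_corpus(
    model: TrueModel,
    D: int,
    labels_per_doc: int = 2,
    tokens_per_doc: int | None = 120,
    seed: int = 0,
    label_bernoulli_p: float | None = None,
    poisson_tokens: bool = False,
) -> SyntheticCorpus:
    """Generate D proteins from ``model``.

    Label admissibility per protein: a uniformly chosen set of
    ``labels_per_doc`` labels, or (when ``label_bernoulli_p`` is given)
    independent Bernoulli inclusion with at least one retry-enforced
    label.  Token count per protein is fixed at ``tokens_per_doc`` or
    Poisson with that mean when ``poisson_tokens``.  Per token:
    l ~ psi_d, z ~ pi_l, w ~ theta_z.
    """
    rng = np.random.default_rng(seed)
    part = model.partition
    space = model.label_space
    L = space.n_labels
    Lp = space.n_extended
    rows = np.zeros((D, Lp), dtype=np.uint8)
    for d in range(D):
        if label_bernoulli_p is not None:
            while True:
                mask = rng.random(L) < label_bernoulli_p
                if mask.any():
                    break
            rows[d, :L] = mask
        else:
            chosen = rng.choice(L, size=labels_per_doc, replace=False)
            rows[d, chosen] = 1
        if space.background:
            rows[d, -1] = 1
    labels = LabelMatrix(space, rows)
    psi = np.zeros((D, Lp))
    doc_of, word_of, label_of, topic_of = [], [], [], []
    W = model.theta.shape[1]
    for d in range(D):
        active = np.flatnonzero(rows[d])
        psi[d, active] = rng.dirichlet(np.full(active.size, model.hyper.beta))
        n = (
            int(rng.poisson(tokens_per_doc))
            if poisson_tokens
            else int(tokens_per_doc)
        )
        if n == 0:
            continue
        ls = rng.choice(Lp, size=n, p=psi[d])
        for l in ls:
            k = rng.choice(part.n_topics, p=model.pi[l])
            w = rng.choice(W, p=model.theta[k])
            doc_of.append(d)
            word_of.append(int(w))
            label_of.append(int(l))
            topic_of.append(int(k))
    vocab = synthetic_vocabulary(W)
    counts = np.zeros((D, W), dtype=np.int64)
    if doc_of:
        np.add.at(counts, (doc_of, word_of), 1)
    corpus = BagOfWordsCorpus(
        vocab, tuple(f"SYN{d:05d}" for d in range(D)), counts
    )
    out = SyntheticCorpus(
        corpus=corpus,
        labels=labels,
        psi=psi,
        doc_of=np.array(doc_of, dtype=np.int64),
        word_of=np.array(word_of, dtype=np.int64),
        label_of=np.array(label_of, dtype=np.int64),
        topic_of=np.array(topic_of, dtype=np.int64),
    )
    out._partition = part
    return out


def _tv(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


def match_topics(
    theta_hat: np.ndarray,
    theta_true: np.ndarray,
    partition: TopicPartition,
    exhaustive_max: int = 6,
) -> tuple[dict[int, tuple[int, ...]], float]:
    """Optimal within-subset topic matching by total-variation distance.

    Topics within one label's subset are exchangeable a priori, so
    estimates are compared to the truth after the permutation of each
    subset that minimizes the summed TV distance.  Subsets up to
    ``exhaustive_max`` topics are matched by exhaustive permutation
    search; larger ones by Hungarian assignment (same optimum for this
    additive objective).  Returns the per-label permutation (sigma maps
    true-topic position -> estimated-topic position) and the mean TV
    over all topics.
    """
    if theta_hat.shape != theta_true.shape:
        raise ConfigurationError("theta shapes differ")
    perms: dict[int, tuple[int, ...]] = {}
    total = 0.0
    n_topics = 0
    for l in range(partition.n_extended):
        sub = list(partition.subset_of(l))
        cost = np.array(
            [[_tv(theta_hat[i], theta_true[j]) for j in sub] for i in sub]
        )
        if len(sub) <= exhaustive_max:
            best, best_perm = np.inf, None
            for perm in permutations(range(len(sub))):
                c = sum(cost[perm[j], j] for j in range(len(sub)))
                if c < best:
                    best, best_perm = c, perm
        else:
            ri, ci = linear_sum_assignment(cost)
            best_perm = tuple(int(ri[list(ci).index(j)]) for j in range(len(sub)))
            best = float(cost[ri, ci].sum())
        perms[l] = best_perm
        total += best
        n_topics += len(sub)
    return perms, total / n_topics
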