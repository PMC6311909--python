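"""Collapsed Gibbs sampling: training, fold-in prediction, estimation.

Training integrates out the label weights psi_d, the label-to-topic
distributions pi_l and the topic-to-word distributions theta_k, and
samples a joint (label, topic) assignment for every token from its
collapsed conditional

    p(l, k | rest)  ∝  (beta + N_dl)
                     · (alpha + N_lk) / (alpha·K_l + N_l)
                     · (lambda + N_kw) / (lambda·W + N_k)

restricted to labels admissible for the document and topics in the
label's own subset K_l (counts exclude the token being resampled).
Estimation averages the posterior-mean point estimates over thinned
post-burn-in states of a single chain; label-topic identity is pinned
by the partition, so no label switching can occur between samples.

Prediction folds a new protein in with every label admissible, holding
the trained pi and theta fixed and resampling only the document-level
label counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln

from .corpus import BagOfWordsCorpus
from .errors import ConfigurationError, InternalError
from .model import (
    GibbsState,
    Hyperparameters,
    LabelMatrix,
    TopicPartition,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingSchedule:
    """Gibbs chain schedule: total sweeps, burn-in, thinning interval.

    The conventional training schedule is one chain of 2000 sweeps with
    1000 burn-in and a retained state every 50 sweeps (20 samples);
    prediction uses 1000 sweeps with 500 burn-in, thin 50.
    """

    iterations: int = 2000
    burn_in: int = 1000
    thin: int = 50
    chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ConfigurationError(
                f"burn_in ({self.burn_in}) must be < iterations ({self.iterations})"
            )
        if self.thin < 1:
            raise ConfigurationError(f"thin must be >= 1, got {self.thin}")
        if self.chains < 1:
            raise ConfigurationError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def retained_sweeps(self) -> list[int]:
        """1-based sweep indices whose states are retained."""
        return [
            self.burn_in + (j + 1) * self.thin for j in range(self.n_retained)
        ]

    @staticmethod
    def training_default(seed: int = 0) -> "SamplingSchedule":
        return SamplingSchedule(2000, 1000, 50, 1, seed)

    @staticmethod
    def prediction_default(seed: int = 0) -> "SamplingSchedule":
        return SamplingSchedule(1000, 500, 50, 1, seed)


@dataclass
class ModelEstimate:
    """Posterior-mean parameter estimates.

    ``pi[l, k]`` is the probability of topic k under extended label l
    (zero outside the label's subset); ``theta[k, w]`` the probability
    of word w under topic k; ``psi_train[d, l]`` the training document's
    label weights (zero on inactive labels).
    """

    pi: np.ndarray  # (L', K)
    theta: np.ndarray  # (K, W)
    psi_train: np.ndarray  # (D, L')
    partition: TopicPartition
    hyper: Hyperparameters


@dataclass
class PredictionMatrix:
    """Per-protein label probabilities from fold-in prediction.

    ``scores[d, l]`` are renormalized over the L real labels (summing to
    1); ``background[d]`` is the raw posterior mass on the background
    label (``scores`` before renormalization sum with it to 1).
    ``empty_docs`` flags proteins with no in-vocabulary token, whose
    scores are the prior alone.
    """

    doc_ids: tuple[str, ...]
    label_ids: tuple[str, ...]
    scores: np.ndarray  # (D, L) renormalized
    background: np.ndarray  # (D,)
    empty_docs: np.ndarray  # (D,) bool


# ---------------------------------------------------------------------------
# token expansion and flattened candidate tables for the kernels


def expand_tokens(corpus: BagOfWordsCorpus) -> tuple[np.ndarray, np.ndarray]:
    """Unroll the count matrix into token arrays, document-major,
    words in vocabulary order within a document."""
    doc_idx, word_idx = np.nonzero(corpus.counts)
    reps = corpus.counts[doc_idx, word_idx]
    return np.repeat(doc_idx, reps).astype(np.int64), np.repeat(
        word_idx, reps
    ).astype(np.int64)


def _candidate_tables(
    labels: LabelMatrix, partition: TopicPartition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-document flattened (label, topic) candidate pairs.

    Returns ``cand_l``, ``cand_k`` and per-document offsets into them.
    Candidate order is: active labels ascending, topics in subset order.
    """
    cand_l: list[int] = []
    cand_k: list[int] = []
    offsets = np.zeros(labels.n_docs + 1, dtype=np.int64)
    for d in range(labels.n_docs):
        for l in labels.active_labels(d):
            for k in partition.subset_of(l):
                cand_l.append(l)
                cand_k.append(k)
        offsets[d + 1] = len(cand_l)
    return (
        np.array(cand_l, dtype=np.int64),
        np.array(cand_k, dtype=np.int64),
        offsets,
    )


@njit(cache=True)
def _train_sweep(
    doc_of,
    word_of,
    label_of,
    topic_of,
    N_dl,
    N_lk,
    N_kw,
    N_l,
    N_k,
    subset_size,
    cand_l,
    cand_k,
    cand_off,
    alpha,
    beta,
    lam,
    W,
    uniforms,
    buf,
):
    """One full Gibbs sweep over all tokens (counts updated in place)."""
    T = doc_of.shape[0]
    for t in range(T):
        d = doc_of[t]
        w = word_of[t]
        l0 = label_of[t]
        k0 = topic_of[t]
        N_dl[d, l0] -= 1
        N_lk[l0, k0] -= 1
        N_kw[k0, w] -= 1
        N_l[l0] -= 1
        N_k[k0] -= 1
        base = cand_off[d]
        ncand = cand_off[d + 1] - base
        total = 0.0
        for j in range(ncand):
            l = cand_l[base + j]
            k = cand_k[base + j]
            wgt = (
                (beta + N_dl[d, l])
                * (alpha + N_lk[l, k])
                / (alpha * subset_size[l] + N_l[l])
                * (lam + N_kw[k, w])
                / (lam * W + N_k[k])
            )
            total += wgt
            buf[j] = total
        u = uniforms[t] * total
        j = 0
        while j < ncand - 1 and buf[j] <= u:
            j += 1
        l1 = cand_l[base + j]
        k1 = cand_k[base + j]
        label_of[t] = l1
        topic_of[t] = k1
        N_dl[d, l1] += 1
        N_lk[l1, k1] += 1
        N_kw[k1, w] += 1
        N_l[l1] += 1
        N_k[k1] += 1


@njit(cache=True)
def _predict_sweep(
    doc_of,
    word_of,
    label_of,
    topic_of,
    N_dl,
    pi,
    theta,
    cand_l,
    cand_k,
    cand_off,
    beta,
    uniforms,
    buf,
):
    """Fold-in sweep: pi/theta frozen, only document label counts move."""
    T = doc_of.shape[0]
    for t in range(T):
        d = doc_of[t]
        w = word_of[t]
        N_dl[d, label_of[t]] -= 1
        base = cand_off[d]
        ncand = cand_off[d + 1] - base
        total = 0.0
        for j in range(ncand):
            l = cand_l[base + j]
            k = cand_k[base + j]
            wgt = (beta + N_dl[d, l]) * pi[l, k] * theta[k, w]
            total += wgt
            buf[j] = total
        u = uniforms[t] * total
        j = 0
        while j < ncand - 1 and buf[j] <= u:
            j += 1
        label_of[t] = cand_l[base + j]
        topic_of[t] = cand_k[base + j]
        N_dl[d, label_of[t]] += 1


# ---------------------------------------------------------------------------
# public operations


def init_state(
    corpus: BagOfWordsCorpus,
    labels: LabelMatrix,
    partition: TopicPartition,
    rng: np.random.Generator,
) -> GibbsState:
    """Random initial assignment: label uniform over the document's
    active extended labels, topic uniform over that label's subset."""
    if labels.n_docs != corpus.n_docs:
        raise ConfigurationError("label matrix and corpus disagree on D")
    doc_of, word_of = expand_tokens(corpus)
    label_of = np.empty_like(doc_of)
    topic_of = np.empty_like(doc_of)
    for d in range(corpus.n_docs):
        active = labels.active_labels(d)
        if active.size == 0:
            raise ConfigurationError(
                f"document {corpus.doc_ids[d]!r} has no active label"
            )
        tok = doc_of == d
        n = int(tok.sum())
        ls = active[rng.integers(0, active.size, size=n)]
        label_of[tok] = ls
        ks = np.empty(n, dtype=np.int64)
        for i, l in enumerate(ls):
            sub = partition.subset_of(int(l))
            ks[i] = sub[rng.integers(0, len(sub))]
        topic_of[tok] = ks
    return GibbsState(
        doc_of=doc_of,
        word_of=word_of,
        label_of=label_of,
        topic_of=topic_of,
        n_docs=corpus.n_docs,
        n_words=corpus.vocabulary.size,
        partition=partition,
    )


def training_conditional(
    state: GibbsState,
    d: int,
    w: int,
    hyper: Hyperparameters,
    partition: TopicPartition,
    labels: LabelMatrix,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Collapsed conditional over admissible (label, topic) pairs for a
    token of word ``w`` in document ``d``.

    The token being resampled must already be removed from all counts.
    Returns the candidate pairs and their normalized probabilities;
    pairs with an inadmissible label or an out-of-subset topic are not
    candidates (probability exactly zero).
    """
    N_l = state.N_l
    N_k = state.N_k
    sizes = partition.subset_sizes
    W = state.n_words
    pairs: list[tuple[int, int]] = []
    weights: list[float] = []
    for l in labels.active_labels(d):
        l = int(l)
        lab_fac = (hyper.beta + state.N_dl[d, l]) / (
            hyper.alpha * sizes[l] + N_l[l]
        )
        for k in partition.subset_of(l):
            wgt = (
                lab_fac
                * (hyper.alpha + state.N_lk[l, k])
                * (hyper.lam + state.N_kw[k, w])
                / (hyper.lam * W + N_k[k])
            )
            pairs.append((l, k))
            weights.append(wgt)
    probs = np.array(weights, dtype=np.float64)
    total = probs.sum()
    if not total > 0:
        raise InternalError("all-zero conditional weight vector")
    return pairs, probs / total


def gibbs_sweep(
    state: GibbsState,
    hyper: Hyperparameters,
    partition: TopicPartition,
    labels: LabelMatrix,
    rng: np.random.Generator,
    _tables=None,
) -> GibbsState:
    """One in-place sweep visiting every token in document-major order."""
    if _tables is None:
        _tables = _candidate_tables(labels, partition)
    cand_l, cand_k, cand_off = _tables
    buf = np.empty(int(np.diff(cand_off).max(initial=1)), dtype=np.float64)
    N_l = state.N_l.copy()
    N_k = state.N_k.copy()
    _train_sweep(
        state.doc_of,
        state.word_of,
        state.label_of,
        state.topic_of,
        state.N_dl,
        state.N_lk,
        state.N_kw,
        N_l,
        N_k,
        partition.subset_sizes,
        cand_l,
        cand_k,
        cand_off,
        hyper.alpha,
        hyper.beta,
        hyper.lam,
        state.n_words,
        rng.random(state.n_tokens),
        buf,
    )
    return state


def estimate_from_state(
    state: GibbsState,
    hyper: Hyperparameters,
    partition: TopicPartition,
    labels: LabelMatrix,
) -> ModelEstimate:
    """Posterior-mean point estimates from one state's counts.

    psi_dl = (beta + N_dl)/(beta·L_d + N_d) on active labels,
    pi_lk  = (alpha + N_lk)/(alpha·K_l + N_l) on the label's subset,
    theta_kw = (lambda + N_kw)/(lambda·W + N_k).
    """
    Lp = partition.n_extended
    K = partition.n_topics
    W = state.n_words
    sizes = partition.subset_sizes.astype(np.float64)
    pi = np.zeros((Lp, K))
    N_l = state.N_l.astype(np.float64)
    for l in range(Lp):
        sub = list(partition.subset_of(l))
        pi[l, sub] = (hyper.alpha + state.N_lk[l, sub]) / (
            hyper.alpha * sizes[l] + N_l[l]
        )
    theta = (hyper.lam + state.N_kw) / (
        hyper.lam * W + state.N_k[:, None].astype(np.float64)
    )
    active = labels.rows.astype(np.float64)
    L_d = active.sum(axis=1)
    N_d = state.N_d.astype(np.float64)
    psi = active * (hyper.beta + state.N_dl) / (
        hyper.beta * L_d + N_d
    )[:, None]
    return ModelEstimate(pi, theta, psi, partition, hyper)


def log_joint(
    state: GibbsState, hyper: Hyperparameters, labels: LabelMatrix
) -> float:
    """Collapsed log joint p(L, Z, W | Lambda, beta, alpha, lambda) up to
    the assignment-independent constant (log-Gamma form)."""
    part = state.partition
    a, b, lam = hyper.alpha, hyper.beta, hyper.lam
    W = state.n_words
    active = labels.rows.astype(bool)
    L_d = active.sum(axis=1).astype(np.float64)
    N_d = state.N_d.astype(np.float64)
    out = float(np.sum(gammaln(b * L_d) - gammaln(b * L_d + N_d)))
    out += float(np.sum(gammaln(b + state.N_dl[active]) - gammaln(b)))
    sizes = part.subset_sizes.astype(np.float64)
    N_l = state.N_l.astype(np.float64)
    out += float(np.sum(gammaln(a * sizes) - gammaln(a * sizes + N_l)))
    for l in range(part.n_extended):
        sub = list(part.subset_of(l))
        out += float(np.sum(gammaln(a + state.N_lk[l, sub]) - gammaln(a)))
    N_k = state.N_k.astype(np.float64)
    out += float(np.sum(gammaln(lam * W) - gammaln(lam * W + N_k)))
    out += float(np.sum(gammaln(lam + state.N_kw) - gammaln(lam)))
    return out


@dataclass
class TrainResult:
    """A trained model plus its final state and convergence trace."""

    estimate: ModelEstimate
    final_state: GibbsState
    log_joint_trace: list[tuple[int, float]] = field(default_factory=list)


def train(
    corpus: BagOfWordsCorpus,
    labels: LabelMatrix,
    partition: TopicPartition,
    hyper: Hyperparameters,
    schedule: SamplingSchedule,
) -> TrainResult:
    """Run the collapsed Gibbs sampler and average thinned estimates.

    The final estimate is the arithmetic mean of the per-state posterior
    means at the retained (post-burn-in, thinned) sweeps.  The collapsed
    log joint is logged every 100 sweeps as a convergence diagnostic.
    """
    if schedule.n_retained < 1:
        raise ConfigurationError("schedule retains no samples")
    rng = np.random.default_rng(schedule.seed)
    state = init_state(corpus, labels, partition, rng)
    tables = _candidate_tables(labels, partition)
    retained = set(schedule.retained_sweeps())
    acc: ModelEstimate | None = None
    n_acc = 0
    trace: list[tuple[int, float]] = []
    for sweep in range(1, schedule.iterations + 1):
        gibbs_sweep(state, hyper, partition, labels, rng, _tables=tables)
        if sweep % 100 == 0 or sweep == schedule.iterations:
            lj = log_joint(state, hyper, labels)
            trace.append((sweep, lj))
            logger.info("sweep %d  collapsed log-joint %.3f", sweep, lj)
        if sweep in retained:
            est = estimate_from_state(state, hyper, partition, labels)
            if acc is None:
                acc = est
            else:
                acc.pi += est.pi
                acc.theta += est.theta
                acc.psi_train += est.psi_train
            n_acc += 1
    assert acc is not None and n_acc == schedule.n_retained
    acc.pi /= n_acc
    acc.theta /= n_acc
    acc.psi_train /= n_acc
    return TrainResult(estimate=acc, final_state=state, log_joint_trace=trace)


def predict(
    new_corpus: BagOfWordsCorpus,
    model: ModelEstimate,
    schedule: SamplingSchedule,
    label_ids: tuple[str, ...],
) -> PredictionMatrix:
    """Fold-in prediction for unannotated proteins.

    Every extended label is admissible; trained pi and theta are frozen
    and only each document's label counts are resampled.  Per-document
    label weights psi are averaged over retained sweeps; real-label
    scores are reported renormalized without the background mass (also
    returned).  Proteins with no in-vocabulary token get prior-only
    (uniform) scores and are flagged.
    """
    part = model.partition
    Lp = part.n_extended
    L = len(label_ids)
    has_bg = part.n_background > 0
    if L + (1 if has_bg else 0) != Lp:
        raise ConfigurationError("label ids disagree with partition size")
    D = new_corpus.n_docs
    rng = np.random.default_rng(schedule.seed)
    doc_of, word_of = expand_tokens(new_corpus)
    T = doc_of.shape[0]
    # all labels admissible: one shared candidate table
    cand_l = np.concatenate(
        [np.full(len(part.subset_of(l)), l, dtype=np.int64) for l in range(Lp)]
    )
    cand_k = np.concatenate(
        [np.array(part.subset_of(l), dtype=np.int64) for l in range(Lp)]
    )
    per_doc = cand_l.shape[0]
    cand_l_full = np.tile(cand_l, D)
    cand_k_full = np.tile(cand_k, D)
    cand_off = np.arange(D + 1, dtype=np.int64) * per_doc
    label_of = np.empty(T, dtype=np.int64)
    topic_of = np.empty(T, dtype=np.int64)
    N_dl = np.zeros((D, Lp), dtype=np.int64)
    if T:
        picks = rng.integers(0, per_doc, size=T)
        label_of[:] = cand_l[picks]
        topic_of[:] = cand_k[picks]
        np.add.at(N_dl, (doc_of, label_of), 1)
    buf = np.empty(per_doc, dtype=np.float64)
    psi_acc = np.zeros((D, Lp))
    retained = set(schedule.retained_sweeps())
    n_acc = 0
    N_d = N_dl.sum(axis=1).astype(np.float64)
    for sweep in range(1, schedule.iterations + 1):
        if T:
            _predict_sweep(
                doc_of,
                word_of,
                label_of,
                topic_of,
                N_dl,
                model.pi,
                model.theta,
                cand_l_full,
                cand_k_full,
                cand_off,
                model.hyper.beta,
                rng.random(T),
                buf,
            )
        if sweep in retained:
            psi_acc += (model.hyper.beta + N_dl) / (
                model.hyper.beta * Lp + N_d
            )[:, None]
            n_acc += 1
    psi = psi_acc / max(n_acc, 1)
    empty = new_corpus.doc_totals == 0
    if has_bg:
        raw = psi[:, :L]
        background = psi[:, L]
    else:
        raw = psi
        background = np.zeros(D)
    denom = raw.sum(axis=1, keepdims=True)
    scores = np.where(denom > 0, raw / denom, 1.0 / L)
    return PredictionMatrix(
        doc_ids=new_corpus.doc_ids,
        label_ids=tuple(label_ids),
        scores=scores,
        background=background,
        empty_docs=empty,
    )


def binarize(pred: PredictionMatrix, threshold: float | None = None) -> list[set[str]]:
    """Threshold renormalized scores into predicted label sets.

    Default threshold is 1/L (the uniform baseline); scores exactly at
    the threshold are included.
    """
    L = len(pred.label_ids)
    tau = 1.0 / L if threshold is None else threshold
    if not 0 <= tau <= 1:
        raise ConfigurationError(f"threshold must be in [0, 1], got {tau}")
    out = []
    for row in pred.scores:
        out.append({pred.label_ids[j] for j in np.flatnonzero(row >= tau)})
    return out
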