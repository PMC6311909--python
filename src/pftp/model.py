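"""Core model structures: label space, topic partition, counts.

The model attaches to each of the L observed function labels (GO terms)
a disjoint subset of the K global topics, plus a background subset owned
by a latent "fake" label that is active in every protein.  The label
space is therefore extended to L+1; all internal indices are 0-based
(the background label is index L) while serialized topic indices are
1-based to match the conventional numbering with the background block
first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .errors import ConfigurationError, InputError, InternalError


@dataclass(frozen=True)
class LabelSpace:
    """Ordered universe of L observed labels plus the background label.

    ``background_index`` (== L) is the internal 0-based index of the
    latent background label; it never appears among the observed labels.
    When ``background=False`` the extended space is just the L observed
    labels (the Labeled-LDA degenerate configuration).
    """

    labels: tuple[str, ...]
    background: bool = True

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise InputError("duplicate label identifiers")
        if not self.labels:
            raise ConfigurationError("label space is empty")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def n_extended(self) -> int:
        return len(self.labels) + (1 if self.background else 0)

    @property
    def background_index(self) -> int | None:
        return len(self.labels) if self.background else None

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"unknown label id: {label}") from None


@dataclass
class LabelMatrix:
    """Binary admissibility matrix Lambda over the extended label space.

    Row d marks which extended labels may receive tokens of document d.
    With a background label the last column is identically 1.
    """

    space: LabelSpace
    rows: np.ndarray  # (D, L') uint8

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.uint8)
        if self.rows.ndim != 2 or self.rows.shape[1] != self.space.n_extended:
            raise InputError(
                f"label matrix has {self.rows.shape} shape, expected "
                f"(*, {self.space.n_extended})"
            )
        if not np.isin(self.rows, (0, 1)).all():
            raise InputError("label matrix entries must be 0/1")
        if self.space.background and not (self.rows[:, -1] == 1).all():
            raise InternalError("background column must be all ones")

    @property
    def n_docs(self) -> int:
        return self.rows.shape[0]

    def active_labels(self, d: int) -> np.ndarray:
        return np.flatnonzero(self.rows[d])


@dataclass(frozen=True)
class TopicPartition:
    """Disjoint assignment of the K global topics to extended labels.

    ``subsets[l]`` lists (0-based) topic indices owned by extended label
    ``l``; with a background label its subset is last in ``subsets`` and
    occupies the first ``n_background`` topic indices, so the background
    topic is number 1 in the 1-based layout.
    """

    n_topics: int
    subsets: tuple[tuple[int, ...], ...]
    n_background: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for sub in self.subsets:
            if not sub:
                raise ConfigurationError("every topic subset must be non-empty")
            if seen & set(sub):
                raise ConfigurationError("topic subsets overlap")
            seen |= set(sub)
        if seen != set(range(self.n_topics)):
            raise ConfigurationError(
                "topic subsets do not partition the global topic space"
            )

    @property
    def n_extended(self) -> int:
        return len(self.subsets)

    @property
    def subset_sizes(self) -> np.ndarray:
        return np.array([len(s) for s in self.subsets], dtype=np.int64)

    def subset_of(self, l: int) -> tuple[int, ...]:
        return self.subsets[l]

    def label_of_topic(self) -> np.ndarray:
        """Inverse map: topic index -> extended label index."""
        owner = np.empty(self.n_topics, dtype=np.int64)
        for l, sub in enumerate(self.subsets):
            owner[list(sub)] = l
        return owner


@dataclass(frozen=True)
class Hyperparameters:
    """Symmetric Dirichlet concentrations.

    alpha: per-topic concentration of each label's topic distribution
    (conventional default 50/K); beta: per-label concentration of each
    document's label weights; lam: per-word concentration of each topic's
    word distribution (conventional default 200/W).
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.lam) <= 0:
            raise ConfigurationError(
                f"hyperparameters must be > 0, got alpha={self.alpha}, "
                f"beta={self.beta}, lambda={self.lam}"
            )

    @staticmethod
    def auto(K: int, W: int, beta: float = 0.01) -> "Hyperparameters":
        """The conventional settings alpha = 50/K and lambda = 200/W."""
        return Hyperparameters(alpha=50.0 / K, beta=beta, lam=200.0 / W)


def make_partition(
    L: int, topics_per_label: int, background_topics: int = 1
) -> TopicPartition:
    """Contiguous topic partition: background block first, then m per label.

    K = m*L + B topics; background topics occupy 0..B-1 (1-based 1..B),
    label i owns B + i*m .. B + (i+1)*m - 1.  With ``background_topics=0``
    the partition has no background subset (and the model degenerates to
    Labeled-LDA when additionally m=1).
    """
    if L < 1:
        raise ConfigurationError(f"need at least one label, got L={L}")
    if topics_per_label < 1:
        raise ConfigurationError(
            f"topics per label must be >= 1, got {topics_per_label}"
        )
    if background_topics < 0:
        raise ConfigurationError("background topic count must be >= 0")
    B, m = background_topics, topics_per_label
    subsets = [tuple(range(B + i * m, B + (i + 1) * m)) for i in range(L)]
    if B > 0:
        subsets.append(tuple(range(B)))
    return TopicPartition(n_topics=m * L + B, subsets=tuple(subsets), n_background=B)


def build_label_matrix(
    annotations: dict[str, set[str]],
    doc_ids: tuple[str, ...] | list[str],
    space: LabelSpace,
    training: bool = True,
    allow_unlabeled: bool = False,
) -> LabelMatrix:
    """Binary label rows for ``doc_ids`` from per-protein annotation sets.

    In training mode a protein with no observed label is rejected (the
    model is supervised) unless ``allow_unlabeled`` lets it ride on the
    background label alone.  In prediction mode annotations are ignored
    and every extended label is admissible for every protein.
    """
    Lp = space.n_extended
    rows = np.zeros((len(doc_ids), Lp), dtype=np.uint8)
    if not training:
        rows[:] = 1
        return LabelMatrix(space, rows)
    for d, pid in enumerate(doc_ids):
        labs = annotations.get(pid, set())
        for lab in labs:
            rows[d, space.index(lab)] = 1
        if not labs:
            if not allow_unlabeled:
                raise InputError(
                    f"protein {pid!r} has no observed label in training mode"
                )
            warnings.warn(
                f"protein {pid!r} has no observed label; background-only row",
                stacklevel=2,
            )
        if space.background:
            rows[d, -1] = 1
        elif not labs:
            raise InputError(
                f"protein {pid!r} has no admissible label (background disabled)"
            )
    return LabelMatrix(space, rows)


@dataclass
class GibbsState:
    """Token-level (label, topic) assignments plus sufficient counts.

    Tokens are stored document-major: ``doc_of[t]``/``word_of[t]`` are
    fixed by the corpus, ``label_of[t]``/``topic_of[t]`` are the sampler's
    state.  The six count statistics are maintained incrementally and
    must always equal a recount from the token table.
    """

    doc_of: np.ndarray  # (T,) int64
    word_of: np.ndarray  # (T,) int64
    label_of: np.ndarray  # (T,) int64
    topic_of: np.ndarray  # (T,) int64
    n_docs: int
    n_words: int
    partition: TopicPartition
    N_dl: np.ndarray = field(default=None)
    N_lk: np.ndarray = field(default=None)
    N_kw: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.N_dl is None:
            self.N_dl, self.N_lk, self.N_kw = self.recount()

    @property
    def n_tokens(self) -> int:
        return self.doc_of.shape[0]

    @property
    def N_d(self) -> np.ndarray:
        return self.N_dl.sum(axis=1)

    @property
    def N_l(self) -> np.ndarray:
        return self.N_lk.sum(axis=1)

    @property
    def N_k(self) -> np.ndarray:
        return self.N_kw.sum(axis=1)

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Recompute all count matrices from the token table."""
        Lp = self.partition.n_extended
        K = self.partition.n_topics
        N_dl = np.zeros((self.n_docs, Lp), dtype=np.int64)
        N_lk = np.zeros((Lp, K), dtype=np.int64)
        N_kw = np.zeros((K, self.n_words), dtype=np.int64)
        np.add.at(N_dl, (self.doc_of, self.label_of), 1)
        np.add.at(N_lk, (self.label_of, self.topic_of), 1)
        np.add.at(N_kw, (self.topic_of, self.word_of), 1)
        return N_dl, N_lk, N_kw

    def validate(self, labels: LabelMatrix | None = None) -> None:
        """Check bookkeeping and support invariants; raise on violation."""
        N_dl, N_lk, N_kw = self.recount()
        if not (
            np.array_equal(N_dl, self.N_dl)
            and np.array_equal(N_lk, self.N_lk)
            and np.array_equal(N_kw, self.N_kw)
        ):
            raise InternalError("incremental counts disagree with recount")
        owner = self.partition.label_of_topic()
        if self.n_tokens and not np.array_equal(
            owner[self.topic_of], self.label_of
        ):
            raise InternalError("a token's topic lies outside its label's subset")
        if labels is not None and self.n_tokens:
            if not labels.rows[self.doc_of, self.label_of].all():
                raise InternalError("a token is assigned an inadmissible label")
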