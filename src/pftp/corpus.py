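"""Bag-of-words construction from protein sequences.

A protein sequence is treated as a text string over the 20-letter amino
acid alphabet.  Its "words" are amino acid blocks: length-k substrings
(k-mers) read with a sliding window.  A corpus of proteins becomes a
document-by-block occurrence-count matrix — the input of the topic model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError

#: The 20 standard amino acid one-letter codes.
AMINO_ACIDS = "GAVLIFPYSCMNQTDEKRHW"


@dataclass(frozen=True)
class Vocabulary:
    """Ordered set of amino acid blocks with a bijective index.

    Blocks are stored sorted; ``index(block)`` maps a block onto
    ``0..W-1``.  Reported/serialized indices are 1-based.
    """

    blocks: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.blocks)) != len(self.blocks):
            raise InputError("vocabulary contains duplicate blocks")
        if any(not b for b in self.blocks):
            raise InputError("vocabulary contains an empty block")
        object.__setattr__(self, "_index", {b: i for i, b in enumerate(self.blocks)})

    @property
    def size(self) -> int:
        return len(self.blocks)

    def index(self, block: str) -> int:
        return self._index[block]

    def __contains__(self, block: str) -> bool:
        return block in self._index

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class TokenizedProtein:
    """A protein reduced to its ordered list of amino acid blocks."""

    protein_id: str
    blocks: tuple[str, ...]


@dataclass
class BagOfWordsCorpus:
    """Documents (proteins) as raw occurrence counts over a fixed vocabulary.

    ``counts[d, w]`` is the number of times block ``w`` occurs in protein
    ``d``; ``doc_totals[d]`` is the in-vocabulary token count N_d.
    """

    vocabulary: Vocabulary
    doc_ids: tuple[str, ...]
    counts: np.ndarray  # (D, W) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.doc_ids), self.vocabulary.size):
            raise InputError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.doc_ids)} documents x {self.vocabulary.size} blocks"
            )
        if (self.counts < 0).any():
            raise InputError("negative count in bag-of-words matrix")

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def doc_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def tokenize_sequence(
    sequence: str,
    k: int = 2,
    step: int = 1,
    alphabet: str | None = AMINO_ACIDS,
) -> list[str]:
    """Cut a sequence into length-``k`` blocks with stride ``step``.

    Blocks are the windows ``sequence[i:i+k]`` for ``i = 0, step, 2*step, ...``
    while the window fits.  The sequence is upper-cased first.  When
    ``alphabet`` is given, blocks containing a letter outside it are
    dropped (e.g. ambiguity codes such as ``X``); pass ``alphabet=None``
    to keep every uppercase letter.

    Raises
    ------
    InputError
        If the sequence contains a non-letter character (position named)
        or ``k``/``step`` are not positive.
    """
    if k < 1:
        raise ConfigurationError(f"block length k must be >= 1, got {k}")
    if step < 1:
        raise ConfigurationError(f"stride must be >= 1, got {step}")
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if not ch.isalpha():
            raise InputError(f"non-letter character {ch!r} at position {pos}")
    allowed = set(alphabet.upper()) if alphabet is not None else None
    blocks = []
    for i in range(0, len(seq) - k + 1, step):
        block = seq[i : i + k]
        if allowed is not None and not set(block) <= allowed:
            continue
        blocks.append(block)
    return blocks


def tokenize_protein(
    protein_id: str,
    sequence: str,
    k: int = 2,
    step: int = 1,
    alphabet: str | None = AMINO_ACIDS,
    mixed_lengths: bool = False,
) -> TokenizedProtein:
    """Tokenize one protein; with ``mixed_lengths`` emit all lengths 1..k."""
    lengths = range(1, k + 1) if mixed_lengths else (k,)
    blocks: list[str] = []
    for length in lengths:
        blocks.extend(tokenize_sequence(sequence, length, step, alphabet))
    return TokenizedProtein(protein_id, tuple(blocks))


def build_vocabulary(
    tokenized: list[TokenizedProtein], min_count: int = 1
) -> Vocabulary:
    """Collect the block vocabulary, lexicographically sorted.

    Blocks whose total corpus count is below ``min_count`` are excluded.
    Deterministic for a given input.
    """
    if min_count < 1:
        raise ConfigurationError(f"min_count must be >= 1, got {min_count}")
    totals: Counter[str] = Counter()
    for doc in tokenized:
        totals.update(doc.blocks)
    kept = sorted(b for b, c in totals.items() if c >= min_count)
    if not kept:
        raise ConfigurationError(
            "no blocks survive the vocabulary threshold "
            f"(min_count={min_count}, {len(totals)} distinct blocks seen)"
        )
    return Vocabulary(tuple(kept))


def build_bow(
    tokenized: list[TokenizedProtein], vocab: Vocabulary
) -> BagOfWordsCorpus:
    """Count block occurrences per protein over ``vocab``.

    Blocks absent from the vocabulary are skipped (their tokens do not
    enter N_d).  Duplicate protein ids are rejected.
    """
    if vocab.size == 0:
        raise ConfigurationError("empty vocabulary")
    ids = [doc.protein_id for doc in tokenized]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate protein ids: {', '.join(dupes)}")
    counts = np.zeros((len(tokenized), vocab.size), dtype=np.int64)
    for d, doc in enumerate(tokenized):
        for block in doc.blocks:
            if block in vocab:
                counts[d, vocab.index(block)] += 1
    return BagOfWordsCorpus(vocab, tuple(ids), counts)
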