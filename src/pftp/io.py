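"""Readers and writers for the plain-text artifact formats.

Formats: FASTA (input sequences), two-column TSV (protein -> comma
separated GO terms), sparse triplet TSV + vocabulary list for the
bag-of-words, JSON for partition/config/report, a directory bundle
with full-precision text matrices for a trained model, and a TSV score
matrix.  Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .corpus import BagOfWordsCorpus, Vocabulary
from .errors import InputError
from .inference import ModelEstimate, PredictionMatrix
from .model import Hyperparameters, LabelSpace, TopicPartition

FLOAT_FMT = "%.17g"  # shortest round-trip representation for float64


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    The id is the first whitespace-delimited token of the header;
    wrapped lines are concatenated and '*' stop characters stripped.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).replace("*", "")))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def read_labels_tsv(path: str | Path, space: LabelSpace | None = None) -> dict[str, set[str]]:
    """Read `protein_id<TAB>GO:...,GO:...` lines into an annotation map.

    Labels are deduplicated per protein; with ``space`` given, unknown
    labels raise an error listing them.
    """
    annotations: dict[str, set[str]] = {}
    unknown: set[str] = set()
    known = set(space.labels) if space is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise InputError(f"{path}:{lineno}: malformed label line")
            pid, labs = parts
            if pid in annotations:
                raise InputError(f"{path}:{lineno}: duplicate protein {pid!r}")
            labels = {x for x in labs.split(",") if x}
            if not labels:
                raise InputError(f"{path}:{lineno}: blank label field")
            if known is not None:
                unknown |= labels - known
            annotations[pid] = labels
    if unknown:
        raise InputError(f"unknown labels: {', '.join(sorted(unknown))}")
    return annotations


def write_labels_tsv(path: str | Path, annotations: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for pid in sorted(annotations):
            fh.write(f"{pid}\t{','.join(sorted(annotations[pid]))}\n")


def write_label_universe(path: str | Path, space: LabelSpace) -> None:
    Path(path).write_text("".join(f"{l}\n" for l in space.labels))


def read_label_universe(path: str | Path, background: bool = True) -> LabelSpace:
    labels = tuple(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    return LabelSpace(labels=labels, background=background)


def write_bow(dir_path: str | Path, corpus: BagOfWordsCorpus) -> None:
    """Write a BoW as vocabulary list + (doc_id, block, count) triplets."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    (d / "vocabulary.txt").write_text(
        "".join(f"{b}\n" for b in corpus.vocabulary.blocks)
    )
    with open(d / "bow.tsv", "w") as fh:
        fh.write("protein_id\tblock\tcount\n")
        for i, pid in enumerate(corpus.doc_ids):
            for w in np.flatnonzero(corpus.counts[i]):
                fh.write(f"{pid}\t{corpus.vocabulary.blocks[w]}\t{corpus.counts[i, w]}\n")
        # documents with no in-vocabulary token still need a row to survive
        for i, pid in enumerate(corpus.doc_ids):
            if corpus.counts[i].sum() == 0:
                fh.write(f"{pid}\t-\t0\n")


def read_bow(dir_path: str | Path) -> BagOfWordsCorpus:
    d = Path(dir_path)
    vocab = Vocabulary(
        tuple(
            line.strip()
            for line in (d / "vocabulary.txt").read_text().splitlines()
            if line.strip()
        )
    )
    df = pd.read_csv(d / "bow.tsv", sep="\t", dtype={"protein_id": str})
    doc_ids: list[str] = []
    index: dict[str, int] = {}
    for pid in df["protein_id"]:
        if pid not in index:
            index[pid] = len(doc_ids)
            doc_ids.append(pid)
    counts = np.zeros((len(doc_ids), vocab.size), dtype=np.int64)
    for pid, block, count in df.itertuples(index=False):
        if count == 0:
            continue
        if block not in vocab:
            raise InputError(f"block {block!r} not in vocabulary")
        counts[index[pid], vocab.index(block)] = count
    return BagOfWordsCorpus(vocab, tuple(doc_ids), counts)


def vocabulary_hash(vocab: Vocabulary) -> str:
    h = hashlib.sha256()
    for b in vocab.blocks:
        h.update(b.encode())
        h.update(b"\n")
    return h.hexdigest()


def write_partition(path: str | Path, partition: TopicPartition, space: LabelSpace) -> None:
    """JSON map label id -> 1-based topic indices, plus "background"."""
    obj = {
        space.labels[l]: [k + 1 for k in partition.subset_of(l)]
        for l in range(space.n_labels)
    }
    if space.background:
        obj["background"] = [k + 1 for k in partition.subset_of(space.background_index)]
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_partition(path: str | Path, space: LabelSpace) -> TopicPartition:
    obj = json.loads(Path(path).read_text())
    subsets = [tuple(k - 1 for k in obj[lab]) for lab in space.labels]
    n_background = 0
    if "background" in obj:
        bg = tuple(k - 1 for k in obj["background"])
        subsets.append(bg)
        n_background = len(bg)
    n_topics = sum(len(s) for s in subsets)
    return TopicPartition(n_topics=n_topics, subsets=tuple(subsets), n_background=n_background)


def _write_matrix(path: Path, mat: np.ndarray) -> None:
    np.savetxt(path, mat, fmt=FLOAT_FMT, delimiter="\t")


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def save_model(dir_path: str | Path, model: ModelEstimate, space: LabelSpace,
               vocab: Vocabulary, schedule_meta: dict | None = None) -> None:
    """Persist a trained model as JSON metadata + text matrices."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "labels": list(space.labels),
        "background": space.background,
        "n_topics": model.partition.n_topics,
        "n_background": model.partition.n_background,
        "subsets": [list(s) for s in model.partition.subsets],
        "hyperparameters": {
            "alpha": model.hyper.alpha,
            "beta": model.hyper.beta,
            "lambda": model.hyper.lam,
        },
        "vocabulary_sha256": vocabulary_hash(vocab),
        "schedule": schedule_meta or {},
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    (d / "vocabulary.txt").write_text("".join(f"{b}\n" for b in vocab.blocks))
    _write_matrix(d / "pi.tsv", model.pi)
    _write_matrix(d / "theta.tsv", model.theta)
    _write_matrix(d / "psi_train.tsv", model.psi_train)


def load_model(dir_path: str | Path) -> tuple[ModelEstimate, LabelSpace, Vocabulary]:
    d = Path(dir_path)
    meta = json.loads((d / "meta.json").read_text())
    space = LabelSpace(tuple(meta["labels"]), background=meta["background"])
    partition = TopicPartition(
        n_topics=meta["n_topics"],
        subsets=tuple(tuple(s) for s in meta["subsets"]),
        n_background=meta["n_background"],
    )
    hyper = Hyperparameters(
        alpha=meta["hyperparameters"]["alpha"],
        beta=meta["hyperparameters"]["beta"],
        lam=meta["hyperparameters"]["lambda"],
    )
    vocab = Vocabulary(
        tuple(
            line.strip()
            for line in (d / "vocabulary.txt").read_text().splitlines()
            if line.strip()
        )
    )
    if vocabulary_hash(vocab) != meta["vocabulary_sha256"]:
        raise InputError("model bundle vocabulary hash mismatch")
    model = ModelEstimate(
        pi=_read_matrix(d / "pi.tsv"),
        theta=_read_matrix(d / "theta.tsv"),
        psi_train=_read_matrix(d / "psi_train.tsv"),
        partition=partition,
        hyper=hyper,
    )
    return model, space, vocab


def write_scores(path: str | Path, pred: PredictionMatrix) -> None:
    """Score matrix TSV: one row per protein, renormalized label columns
    plus the raw background mass and an empty-document flag."""
    df = pd.DataFrame(pred.scores, columns=list(pred.label_ids))
    df.insert(0, "protein_id", list(pred.doc_ids))
    df["__background__"] = pred.background
    df["__empty__"] = pred.empty_docs.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    label_cols = [c for c in df.columns if c not in ("protein_id", "__background__", "__empty__")]
    return (
        tuple(df["protein_id"]),
        tuple(label_cols),
        df[label_cols].to_numpy(dtype=float),
    )


def write_report(path: str | Path, report_dict: dict) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=1, sort_keys=True) + "\n")


def write_config(dir_path: str | Path, config: dict) -> str:
    """Serialize the run configuration for provenance; returns its hash."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    text = json.dumps(config, indent=1, sort_keys=True) + "\n"
    (d / "config.json").write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
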