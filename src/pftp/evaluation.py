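"""Multi-label evaluation of prediction scores against true label sets.

Six criteria: Hamming loss (on binarized predictions), One-Error and
Average Precision (on label rankings), and three precision-recall-curve
areas — pooled over all (protein, label) pairs, macro-averaged per
label, and frequency-weighted per label.  Ranking ties are broken
deterministically by label index; PR areas use an exhaustive threshold
sweep with trapezoidal integration over recall, the first curve point's
precision extended back to recall zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """The six metric values plus the binarization threshold used."""

    hamming_loss: float
    one_error: float
    average_precision: float
    au_prc_pooled: float
    auprc_macro: float
    auprc_weighted: float
    threshold: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _check_alignment(truth: list[set[int]], scores: np.ndarray) -> None:
    if len(truth) != scores.shape[0]:
        raise InputError(
            f"{len(truth)} truth rows vs {scores.shape[0]} score rows"
        )


def hamming_loss(
    truth: list[set[int]], predicted: list[set[int]], n_labels: int
) -> float:
    """Mean size of the symmetric difference, normalized by D·L."""
    if n_labels == 0:
        raise ConfigurationError("hamming loss undefined for zero labels")
    if len(truth) != len(predicted):
        raise InputError("truth and prediction lengths differ")
    total = sum(len(y ^ yhat) for y, yhat in zip(truth, predicted))
    return total / (len(truth) * n_labels)


def _ranking(scores_row: np.ndarray) -> np.ndarray:
    """rank[l] = 1-based rank of label l, descending score, ties by index."""
    L = scores_row.shape[0]
    order = np.lexsort((np.arange(L), -scores_row))
    rank = np.empty(L, dtype=np.int64)
    rank[order] = np.arange(1, L + 1)
    return rank


def one_error(truth: list[set[int]], scores: np.ndarray) -> float:
    """Fraction of proteins whose top-ranked label is not a true label.

    Proteins with an empty true set are excluded (with a logged count).
    """
    _check_alignment(truth, scores)
    errors = 0
    n = 0
    skipped = 0
    for y, row in zip(truth, scores):
        if not y:
            skipped += 1
            continue
        top = int(np.lexsort((np.arange(row.shape[0]), -row))[0])
        errors += top not in y
        n += 1
    if skipped:
        logger.warning("one_error: %d proteins with empty true set excluded", skipped)
    if n == 0:
        raise InputError("no protein has a non-empty true label set")
    return errors / n


def average_precision(truth: list[set[int]], scores: np.ndarray) -> float:
    """Label-ranking average precision.

    Per protein: mean over true labels y of the fraction of labels
    ranked at or above y that are themselves true; then mean over
    proteins.  Empty true sets are excluded as in :func:`one_error`.
    """
    _check_alignment(truth, scores)
    vals = []
    skipped = 0
    for y, row in zip(truth, scores):
        if not y:
            skipped += 1
            continue
        rank = _ranking(row)
        acc = 0.0
        for label in y:
            r = rank[label]
            acc += sum(1 for other in y if rank[other] <= r) / r
        vals.append(acc / len(y))
    if skipped:
        logger.warning(
            "average_precision: %d proteins with empty true set excluded", skipped
        )
    if not vals:
        raise InputError("no protein has a non-empty true label set")
    return float(np.mean(vals))


def _pr_area(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Area under the PR curve from an exhaustive threshold sweep.

    One point per distinct score value (predict positive iff score >=
    threshold), traversed from the highest threshold down; trapezoid
    over recall with the first point's precision carried to recall 0.
    """
    P = int(y_true.sum())
    if P == 0:
        raise InputError("PR area undefined without positives")
    thresholds = np.unique(y_score)[::-1]
    recalls = [0.0]
    precisions: list[float] = []
    for tau in thresholds:
        pred = y_score >= tau
        tp = int((pred & (y_true == 1)).sum())
        precisions_at = tp / int(pred.sum())
        if not precisions:
            precisions.append(precisions_at)  # recall-0 anchor
        recalls.append(tp / P)
        precisions.append(precisions_at)
    return float(np.trapezoid(precisions, recalls))


def pr_area_pooled(truth: list[set[int]], scores: np.ndarray) -> float:
    """PR area with all (protein, label) pairs pooled under one sweep."""
    _check_alignment(truth, scores)
    D, L = scores.shape
    y_true = np.zeros((D, L), dtype=np.int64)
    for d, y in enumerate(truth):
        y_true[d, list(y)] = 1
    return _pr_area(y_true.ravel(), scores.ravel())


def pr_area_per_label(
    truth: list[set[int]], scores: np.ndarray
) -> tuple[dict[int, float], float, float]:
    """Per-label PR areas plus their macro and frequency-weighted means.

    Labels with no positive protein have an undefined PR curve; they are
    excluded from both averages and counted in a logged warning.
    """
    _check_alignment(truth, scores)
    D, L = scores.shape
    y_true = np.zeros((D, L), dtype=np.int64)
    for d, y in enumerate(truth):
        y_true[d, list(y)] = 1
    areas: dict[int, float] = {}
    freqs: dict[int, int] = {}
    skipped = 0
    for l in range(L):
        n_pos = int(y_true[:, l].sum())
        if n_pos == 0:
            skipped += 1
            continue
        areas[l] = _pr_area(y_true[:, l], scores[:, l])
        freqs[l] = n_pos
    if skipped:
        logger.warning(
            "pr_area_per_label: %d labels with zero positives excluded", skipped
        )
    if not areas:
        raise InputError("no label has a positive protein")
    macro = float(np.mean(list(areas.values())))
    wtot = sum(freqs.values())
    weighted = float(sum(areas[l] * freqs[l] for l in areas) / wtot)
    return areas, macro, weighted


def evaluate(
    truth: list[set[int]],
    scores: np.ndarray,
    threshold: float | None = None,
    predicted: list[set[int]] | None = None,
) -> EvaluationReport:
    """Compute the full six-metric report.

    ``predicted`` defaults to thresholding each score row at
    ``threshold`` (default 1/L, ties included).
    """
    _check_alignment(truth, scores)
    L = scores.shape[1]
    tau = (1.0 / L) if threshold is None else threshold
    if predicted is None:
        predicted = [set(np.flatnonzero(row >= tau)) for row in scores]
    _, macro, weighted = pr_area_per_label(truth, scores)
    return EvaluationReport(
        hamming_loss=hamming_loss(truth, predicted, L),
        one_error=one_error(truth, scores),
        average_precision=average_precision(truth, scores),
        au_prc_pooled=pr_area_pooled(truth, scores),
        auprc_macro=macro,
        auprc_weighted=weighted,
        threshold=tau,
    )
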