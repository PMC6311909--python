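"""Independent brute-force oracles used only by the tests.

Everything here is deliberately written with naive loops, straight from
the definitions, and shares no code with the package implementation:
the collapsed joint in log-Gamma form, conditionals obtained by scoring
every candidate completion of that joint, exhaustive enumeration of all
admissible assignment configurations, a stand-alone Labeled-LDA sampler
(the one-topic-per-label degenerate model), and direct-definition
multi-label metrics.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def oracle_log_joint(doc_of, word_of, l_assign, z_assign, lam_rows, subsets,
                     alpha, beta, lam, W):
    """Collapsed log joint of a full assignment, by direct counting.

    ``lam_rows`` is the binary admissibility matrix; ``subsets[l]`` the
    topic indices owned by extended label l.  Topic support is each
    label's own subset (the partition would be vacuous otherwise), so
    the label-topic block uses alpha * |subset(l)| in its denominator.
    """
    D = lam_rows.shape[0]
    Lp = lam_rows.shape[1]
    K = sum(len(s) for s in subsets)
    T = len(doc_of)
    N_dl = [[0] * Lp for _ in range(D)]
    N_lk = [[0] * K for _ in range(Lp)]
    N_kw = [[0] * W for _ in range(K)]
    for t in range(T):
        N_dl[doc_of[t]][l_assign[t]] += 1
        N_lk[l_assign[t]][z_assign[t]] += 1
        N_kw[z_assign[t]][word_of[t]] += 1
    lg = math.lgamma
    out = 0.0
    for d in range(D):
        L_d = sum(lam_rows[d])
        N_d = sum(N_dl[d])
        out += lg(beta * L_d) - lg(beta * L_d + N_d)
        for l in range(Lp):
            if lam_rows[d][l]:
                out += lg(beta + N_dl[d][l]) - lg(beta)
    for l in range(Lp):
        K_l = len(subsets[l])
        N_l = sum(N_lk[l])
        out += lg(alpha * K_l) - lg(alpha * K_l + N_l)
        for k in subsets[l]:
            out += lg(alpha + N_lk[l][k]) - lg(alpha)
    for k in range(K):
        N_k = sum(N_kw[k])
        out += lg(lam * W) - lg(lam * W + N_k)
        for w in range(W):
            out += lg(lam + N_kw[k][w]) - lg(lam)
    return out


def oracle_conditional(doc_of, word_of, l_assign, z_assign, t, lam_rows,
                       subsets, alpha, beta, lam, W):
    """Conditional for token t by scoring every candidate completion.

    Returns (candidates, probabilities); candidate order is active
    labels ascending, topics in subset order.
    """
    d = doc_of[t]
    cands = []
    logps = []
    for l in range(lam_rows.shape[1]):
        if not lam_rows[d][l]:
            continue
        for k in subsets[l]:
            la = list(l_assign)
            za = list(z_assign)
            la[t], za[t] = l, k
            cands.append((l, k))
            logps.append(
                oracle_log_joint(doc_of, word_of, la, za, lam_rows, subsets,
                                 alpha, beta, lam, W)
            )
    logps = np.array(logps)
    p = np.exp(logps - logps.max())
    return cands, p / p.sum()


def enumerate_state_distribution(doc_of, word_of, lam_rows, subsets, alpha,
                                 beta, lam, W):
    """Exact distribution over all admissible (L, Z) configurations."""
    T = len(doc_of)
    per_token = []
    for t in range(T):
        opts = []
        for l in range(lam_rows.shape[1]):
            if lam_rows[doc_of[t]][l]:
                for k in subsets[l]:
                    opts.append((l, k))
        per_token.append(opts)
    configs = []
    logps = []
    for combo in product(*per_token):
        la = [c[0] for c in combo]
        za = [c[1] for c in combo]
        configs.append(tuple(combo))
        logps.append(
            oracle_log_joint(doc_of, word_of, la, za, lam_rows, subsets,
                             alpha, beta, lam, W)
        )
    logps = np.array(logps)
    p = np.exp(logps - logps.max())
    return configs, p / p.sum()


class LabeledLDA:
    """Stand-alone collapsed-Gibbs Labeled-LDA: one topic per label.

    Token conditional: p(l) ∝ (beta + N_dl) (lam + N_lw) / (lam W + N_l),
    restricted to the document's observed labels.
    """

    def __init__(self, doc_of, word_of, lam_rows, L, W, alpha, beta, lam):
        self.doc_of = list(doc_of)
        self.word_of = list(word_of)
        self.lam_rows = lam_rows
        self.L, self.W = L, W
        self.alpha, self.beta, self.lam = alpha, beta, lam
        D = lam_rows.shape[0]
        self.assign = [0] * len(doc_of)
        self.N_dl = [[0] * L for _ in range(D)]
        self.N_lw = [[0] * W for _ in range(L)]
        self.N_l = [0] * L
        self.N_d = [0] * D

    def set_assignments(self, labels):
        D = self.lam_rows.shape[0]
        self.N_dl = [[0] * self.L for _ in range(D)]
        self.N_lw = [[0] * self.W for _ in range(self.L)]
        self.N_l = [0] * self.L
        self.N_d = [0] * D
        self.assign = list(labels)
        for t, l in enumerate(self.assign):
            d, w = self.doc_of[t], self.word_of[t]
            self.N_dl[d][l] += 1
            self.N_lw[l][w] += 1
            self.N_l[l] += 1
            self.N_d[d] += 1

    def conditional(self, t):
        """Weights for token t with its assignment already removed."""
        d, w = self.doc_of[t], self.word_of[t]
        labs, weights = [], []
        for l in range(self.L):
            if not self.lam_rows[d][l]:
                continue
            wgt = (
                (self.beta + self.N_dl[d][l])
                * (self.lam + self.N_lw[l][w])
                / (self.lam * self.W + self.N_l[l])
            )
            labs.append(l)
            weights.append(wgt)
        total = sum(weights)
        return labs, [x / total for x in weights]

    def sweep(self, uniforms):
        for t in range(len(self.assign)):
            d, w, l0 = self.doc_of[t], self.word_of[t], self.assign[t]
            self.N_dl[d][l0] -= 1
            self.N_lw[l0][w] -= 1
            self.N_l[l0] -= 1
            labs, probs = self.conditional(t)
            u = uniforms[t]
            acc = 0.0
            j = 0
            for j in range(len(labs)):
                acc += probs[j]
                if u < acc or j == len(labs) - 1:
                    break
            l1 = labs[j]
            self.assign[t] = l1
            self.N_dl[d][l1] += 1
            self.N_lw[l1][w] += 1
            self.N_l[l1] += 1

    def estimates(self):
        """Posterior-mean psi (active labels) and per-label word dists."""
        D = self.lam_rows.shape[0]
        psi = np.zeros((D, self.L))
        for d in range(D):
            L_d = sum(self.lam_rows[d])
            for l in range(self.L):
                if self.lam_rows[d][l]:
                    psi[d, l] = (self.beta + self.N_dl[d][l]) / (
                        self.beta * L_d + self.N_d[d]
                    )
        phi = np.zeros((self.L, self.W))
        for l in range(self.L):
            for w in range(self.W):
                phi[l, w] = (self.lam + self.N_lw[l][w]) / (
                    self.lam * self.W + self.N_l[l]
                )
        return psi, phi


# ---------------------------------------------------------------------------
# direct-definition multi-label metrics


def naive_hamming_loss(truth, predicted, L):
    total = 0
    for y, yhat in zip(truth, predicted):
        for l in range(L):
            if (l in y) != (l in yhat):
                total += 1
    return total / (len(truth) * L)


def _naive_rank(row, label):
    """1-based rank: higher score first, ties by smaller index."""
    r = 0
    for l in range(len(row)):
        if row[l] > row[label] or (row[l] == row[label] and l <= label):
            r += 1
    return r


def naive_one_error(truth, scores):
    errors, n = 0, 0
    for y, row in zip(truth, scores):
        if not y:
            continue
        top = min(range(len(row)), key=lambda l: (-row[l], l))
        errors += top not in y
        n += 1
    return errors / n


def naive_average_precision(truth, scores):
    vals = []
    for y, row in zip(truth, scores):
        if not y:
            continue
        acc = 0.0
        for label in y:
            r = _naive_rank(row, label)
            better = sum(1 for other in y if _naive_rank(row, other) <= r)
            acc += better / r
        vals.append(acc / len(y))
    return sum(vals) / len(vals)


def naive_pr_area(y_true, y_score):
    """Threshold sweep + trapezoid, first precision carried to recall 0."""
    P = sum(y_true)
    thresholds = sorted(set(y_score), reverse=True)
    points = []
    for tau in thresholds:
        tp = sum(1 for t, s in zip(y_true, y_score) if s >= tau and t)
        npred = sum(1 for s in y_score if s >= tau)
        points.append((tp / P, tp / npred))
    points = [(0.0, points[0][1])] + points
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * (p1 + p0) / 2.0
    return area


def naive_pr_pooled(truth, scores):
    D, L = scores.shape
    y_true = [1 if l in truth[d] else 0 for d in range(D) for l in range(L)]
    y_score = [scores[d][l] for d in range(D) for l in range(L)]
    return naive_pr_area(y_true, y_score)


def naive_pr_per_label(truth, scores):
    D, L = scores.shape
    areas, freqs = {}, {}
    for l in range(L):
        y_true = [1 if l in truth[d] else 0 for d in range(D)]
        if sum(y_true) == 0:
            continue
        areas[l] = naive_pr_area(y_true, [scores[d][l] for d in range(D)])
        freqs[l] = sum(y_true)
    macro = sum(areas.values()) / len(areas)
    weighted = sum(areas[l] * freqs[l] for l in areas) / sum(freqs.values())
    return areas, macro, weighted
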