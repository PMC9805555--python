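"""Independent reference implementations used only by tests.

Every function here recomputes a quantity by the most transparent route
available — full-batch gradient descent, exhaustive pair counting, explicit
hypergeometric enumeration, naive double loops — deliberately sharing no
code with the library paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm


def softmax_penalized_fit(X, y, S, C=1.0, max_iter=200_000, gtol=1e-10):
    """Full-batch gradient descent on the symmetric-softmax multinomial
    negative log-likelihood with penalty (1/(2C))*||W||^2 on non-intercept
    coefficients.  X carries the constant-1 intercept as its last column."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, d = X.shape
    W = np.zeros((S, d))
    Y = np.zeros((n, S))
    Y[np.arange(n), y - 1] = 1.0
    penalize = np.ones(d)
    penalize[-1] = 0.0
    step = 1.0 / (0.5 * np.linalg.norm(X, 2) ** 2 + 1.0 / C)
    for _ in range(max_iter):
        Z = X @ W.T
        Z -= Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        grad = (P - Y).T @ X + (1.0 / C) * W * penalize
        W -= step * grad
        if np.abs(grad).max() < gtol:
            break
    return W


def softmax_probs(W, X):
    Z = np.asarray(X, float) @ W.T
    Z -= Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    return P / P.sum(axis=1, keepdims=True)


def pairwise_auroc(scores, labels):
    """O(M^2) tie-aware AUROC: fraction of (positive, negative) pairs where
    the positive outranks the negative, ties counting one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels != 0]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def pairwise_u(x, y):
    """Brute-force Mann-Whitney U1 over all (x_i, y_j) pairs."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mwu_binary_p(a, n1, b, n2):
    """Two-sided Mann-Whitney p for binary indicators from counts alone:
    brute-force U, tie-corrected normal approximation, continuity
    correction, two-sided on the larger of U1/U2."""
    x = np.r_[np.ones(a), np.zeros(n1 - a)]
    y = np.r_[np.ones(b), np.zeros(n2 - b)]
    u1 = pairwise_u(x, y)
    n = n1 + n2
    t1, t0 = a + b, n - (a + b)
    if t1 == 0 or t0 == 0:
        return 1.0
    tie = (t1**3 - t1) + (t0**3 - t0)
    s2 = n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1)))
    if s2 <= 0:
        return 1.0
    u = max(u1, n1 * n2 - u1)
    z = (u - n1 * n2 / 2 - 0.5) / math.sqrt(s2)
    return min(2 * norm.sf(z), 1.0)


def fisher_two_sided(a, n1, b, n2):
    """Two-sided Fisher exact p for the 2x2 table [[a, n1-a], [b, n2-b]] by
    explicit hypergeometric enumeration: sum the probabilities of all tables
    with the same margins that are no more likely than the observed one."""
    k = a + b  # total successes; a ~ Hypergeom(n1+n2, n1, k)
    lo, hi = max(0, k - n2), min(n1, k)
    def pmf(j):
        return (math.comb(n1, j) * math.comb(n2, k - j)) / math.comb(n1 + n2, k)
    p_obs = pmf(a)
    return min(sum(pmf(j) for j in range(lo, hi + 1) if pmf(j) <= p_obs * (1 + 1e-12)), 1.0)


def tally_base_count(group):
    """Naive double-loop per-bin state frequency tally."""
    G = group.index.n_bins
    S = group.scheme.S
    out = np.zeros((G, S))
    for member in group.members:
        for i in range(G):
            out[i, member.states[i] - 1] += 1
    return out / group.N


def per_bin_mode(group):
    """Most frequent state per bin, ties to the lowest state index."""
    G = group.index.n_bins
    S = group.scheme.S
    out = np.zeros(G, dtype=int)
    for i in range(G):
        counts = [0] * (S + 1)
        for member in group.members:
            counts[member.states[i]] += 1
        out[i] = max(range(1, S + 1), key=lambda s: (counts[s], -s))
    return out


def rank_then_pearson(x, y):
    """Spearman correlation as Pearson on average ranks."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
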