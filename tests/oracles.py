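"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a statistic from first principles (explicit
loops, direct formulas, exhaustive enumeration or grid search) without
touching the implementation path it checks.
"""

from __future__ import annotations

import numpy as np


def anova_icc_oracle(x, y):
    """One-way ANOVA decomposition by explicit loops; returns
    (icc, ms_between, ms_within) for k = 2 measurements per subject."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    k = 2
    grand = sum(x + y) / (n * k)
    ssb = 0.0
    ssw = 0.0
    for xi, yi in zip(x, y):
        mi = (xi + yi) / 2.0
        ssb += k * (mi - grand) ** 2
        ssw += (xi - mi) ** 2 + (yi - mi) ** 2
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + msw), msb, msw


def brute_force_auc(gold, test):
    """Exhaustive O(N^2) pair enumeration of the concordance AUC."""
    total = 0.0
    pairs = 0
    n = len(gold)
    for i in range(n):
        for j in range(i + 1, n):
            if gold[i] == gold[j]:
                continue
            pairs += 1
            if test[i] == test[j]:
                total += 0.5
            elif (test[i] > test[j]) == (gold[i] > gold[j]):
                total += 1.0
    if pairs == 0:
        raise ZeroDivisionError("no informative pairs")
    return total / pairs, pairs


def spearman_no_ties_oracle(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)), valid only without ties."""
    n = len(x)
    rank_x = [sorted(x).index(v) + 1 for v in x]
    rank_y = [sorted(y).index(v) + 1 for v in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rank_x, rank_y))
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def kappa_oracle(table):
    """Direct p_o/p_e computation with explicit sums."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p_o = sum(table[i, i] for i in range(table.shape[0])) / n
    p_e = 0.0
    for i in range(table.shape[0]):
        p_e += (table[i, :].sum() / n) * (table[:, i].sum() / n)
    return (p_o - p_e) / (1.0 - p_e)


def weighted_kappa_oracle(table, quadratic=False):
    """Sum-over-cells weighted formula with explicit loops."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    n = table.sum()
    num = 0.0
    den = 0.0
    for i in range(k):
        for j in range(k):
            w = (abs(i - j) / (k - 1)) ** (2 if quadratic else 1)
            num += w * table[i, j] / n
            den += w * (table[i, :].sum() / n) * (table[:, j].sum() / n)
    return 1.0 - num / den


def delta_grid_oracle(counts, n_iter=40, pts=41):
    """ML grid search for the exchangeable recognition model.

    The model's expected 2x2 table is p12 = p21 = h, p11 = pi1 - h,
    p22 = (1 - pi1) - h with representability h <= pi1 (1 - pi1).
    Phase A refines a (pi1, h) grid to the likelihood maximum.  Phase B
    resolves the non-identified recognition split: Delta = 1 - (A + B)
    maximized over A in (h, pi1] with B = h A/(A - h) <= 1 - pi1, by
    1-d grid refinement.
    """
    counts = np.asarray(counts, dtype=float)
    x11, x12, x21, x22 = counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]

    def loglik(pi1, h):
        p11 = pi1 - h
        p22 = 1.0 - pi1 - h
        bad = (p11 < 0) | (p22 < 0) | (h < 0) | (h > pi1 * (1 - pi1) + 1e-15)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.zeros(np.broadcast(pi1, h).shape)
            for c, p in ((x11, p11), (x22, p22), (x12 + x21, h)):
                if c > 0:
                    v = v + c * np.log(np.where(~bad & (p > 0), p, np.nan))
        return np.where(np.isnan(v) | bad, -np.inf, v)

    center = np.array([0.5, 0.25])
    width = np.array([0.5, 0.25])
    for _ in range(n_iter):
        pi_ax = np.clip(np.linspace(center[0] - width[0], center[0] + width[0], pts),
                        1e-9, 1 - 1e-9)
        h_ax = np.clip(np.linspace(center[1] - width[1], center[1] + width[1], pts),
                       0.0, 0.25)
        grid_pi, grid_h = np.meshgrid(pi_ax, h_ax, indexing="ij")
        ll = loglik(grid_pi, grid_h)
        i = np.unravel_index(np.argmax(ll), ll.shape)
        center = np.array([pi_ax[i[0]], h_ax[i[1]]])
        width = width * 0.65

    pi1, h = center
    pi2 = 1.0 - pi1
    if h <= 1e-12:
        return 1.0
    lo, hi = h * (1 + 1e-12), pi1
    best_s = np.inf
    for _ in range(n_iter):
        a = np.linspace(lo, hi, 2001)
        b = h * a / (a - h)
        s = np.where(b <= pi2 + 1e-15, a + b, np.inf)
        j = int(np.argmin(s))
        best_s = min(best_s, s[j])
        span = (hi - lo) / 2000
        lo = max(h * (1 + 1e-12), a[j] - 2 * span)
        hi = min(pi1, a[j] + 2 * span)
    return 1.0 - best_s if np.isfinite(best_s) else 0.0


def rss_f_oracle(y, X_full, X_reduced):
    """Nested-model F from explicit least-squares residual sums."""
    y = np.asarray(y, dtype=float)

    def rss(X):
        X = np.asarray(X, dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss_f, p_full = rss(X_full)
    rss_r, p_red = rss(X_reduced)
    df1 = p_full - p_red
    df2 = len(y) - p_full
    return ((rss_r - rss_f) / df1) / (rss_f / df2), df1, df2
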