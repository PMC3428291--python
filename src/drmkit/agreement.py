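"""Categorical test-retest agreement: kappa, weighted kappa, Delta.

Cohen's kappa corrects observed agreement for the agreement expected
from the marginal distributions; it is the standard measure for 2x2
test-retest tables but degrades badly when the margins are strongly
unbalanced.  For 3-point ordinal items the weighted kappa credits
near-misses (linear disagreement weights by default).

The Delta coefficient takes a model-based route that is robust to
marginal imbalance.  Each recorded answer is modelled as either a
genuine recognition of the respondent's category (probability
``delta_i`` for category i) or a random guess from a guessing
distribution q.  For a test-retest design the two administrations are
exchangeable, which restricts the model to symmetric expected tables.
Delta is the overall proportion of genuinely (not-by-chance) concordant
answers, Delta = sum_i pi_i * delta_i.

The reported estimate solves the moment equations of that model on the
symmetrized table: with pi_i the symmetrized margins and m the common
off-diagonal proportion,

    delta_i = 1 - 2 m / pi_i,        Delta = sum_i pi_i delta_i = 2 p_o - 1.

Whenever both delta_i are non-negative this is exactly the
maximum-likelihood fit with the non-identified recognition/guessing
split resolved at the supremum of Delta (the least chance-attribution;
the ML expected table is the symmetrized observed table, and the fibre
of parameter points reproducing it is one-dimensional).  When observed
agreement falls below its chance floor the moment solution continues
smoothly into negative delta_i — read, as with kappa, as
worse-than-chance agreement rather than as probabilities.

Goodness of fit is the Pearson chi-square of the observed counts
against the fitted expected table (1 df): under exchangeable
administrations the off-diagonal cells share one expected value, and
large asymmetry signals that the recognition model does not hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reliability import DegenerateSampleError


@dataclass(frozen=True)
class AgreementTable:
    """K x K cross-classification of test (rows) vs retest (columns)."""

    counts: np.ndarray
    labels: tuple

    @classmethod
    def from_counts(cls, counts, labels=None) -> "AgreementTable":
        arr = np.asarray(counts, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("agreement table must be square")
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("agreement table must hold non-negative integer counts")
        if arr.sum() < 1:
            raise ValueError("agreement table is empty")
        if labels is None:
            labels = tuple(range(arr.shape[0]))
        return cls(counts=np.round(arr), labels=tuple(labels))

    @classmethod
    def from_answers(cls, test, retest, labels=None) -> "AgreementTable":
        test = np.asarray(test)
        retest = np.asarray(retest)
        if labels is None:
            labels = tuple(sorted(set(test) | set(retest)))
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)))
        for a, b in zip(test, retest):
            counts[index[a], index[b]] += 1
        return cls(counts=counts, labels=tuple(labels))

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weighted: bool
    weight_scheme: str | None
    p_observed: float
    p_expected: float


@dataclass(frozen=True)
class DeltaResult:
    delta: float
    per_category_deltas: tuple
    pi: tuple
    gof_chi2: float
    gof_df: int
    gof_p: float
    expected: np.ndarray


def _coerce_table(table) -> AgreementTable:
    if isinstance(table, AgreementTable):
        return table
    return AgreementTable.from_counts(table)


# ---------------------------------------------------------------------------
# kappa


def cohen_kappa(table) -> KappaResult:
    """Unweighted Cohen's kappa = (p_o - p_e) / (1 - p_e)."""
    tab = _coerce_table(table)
    p = tab.counts / tab.n
    p_o = float(np.trace(p))
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    p_e = float(rows @ cols)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateSampleError("chance agreement is 1: kappa undefined")
    return KappaResult(
        kappa=float((p_o - p_e) / (1 - p_e)), weighted=False, weight_scheme=None,
        p_observed=p_o, p_expected=p_e,
    )


def weighted_kappa(table, scheme: str = "linear") -> KappaResult:
    """Weighted kappa for ordinal categories.

    kappa_w = 1 - sum(w * p_o) / sum(w * p_e) with disagreement weights
    w_ij = |i-j|/(K-1) ("linear", default) or (i-j)^2/(K-1)^2
    ("quadratic").
    """
    tab = _coerce_table(table)
    k = tab.counts.shape[0]
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    if scheme == "linear":
        w = dist
    elif scheme == "quadratic":
        w = dist**2
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    p = tab.counts / tab.n
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    expected = np.outer(rows, cols)
    denom = float((w * expected).sum())
    if denom <= 1e-12:
        raise DegenerateSampleError("chance agreement is 1: weighted kappa undefined")
    kappa = 1.0 - float((w * p).sum()) / denom
    return KappaResult(
        kappa=kappa, weighted=True, weight_scheme=scheme,
        p_observed=float(np.trace(p)), p_expected=float(np.trace(expected)),
    )


# ---------------------------------------------------------------------------
# Delta (2x2 recognition model)


def delta_2x2(table) -> DeltaResult:
    """Fit the exchangeable recognition model to a 2x2 test-retest table.

    Returns the overall Delta (total proportion of answers concordant
    not by chance, in [-1, 1]), the per-category recognition indices,
    and a 1-df Pearson chi-square goodness-of-fit test of the fitted
    model against the observed table.
    """
    tab = _coerce_table(table)
    counts = tab.counts
    if counts.shape != (2, 2):
        raise ValueError("delta_2x2 requires a 2x2 table")
    n = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    margins = (rows + cols) / (2 * n)
    if margins[0] <= 0 or margins[1] <= 0:
        raise DegenerateSampleError(
            "a category is never used in either wave: Delta model inestimable"
        )

    m = (counts[0, 1] + counts[1, 0]) / (2 * n)  # symmetrized off-diagonal
    s11 = counts[0, 0] / n
    s22 = counts[1, 1] / n
    pi1, pi2 = s11 + m, s22 + m
    d1 = 1.0 - 2.0 * m / pi1
    d2 = 1.0 - 2.0 * m / pi2
    delta = float(pi1 * d1 + pi2 * d2)  # = 2 p_o - 1

    expected = np.array([[s11, m], [m, s22]])
    exp_counts = expected * n
    mask = exp_counts > 0
    gof_chi2 = float((((counts - exp_counts) ** 2)[mask] / exp_counts[mask]).sum())
    gof_df = 1
    gof_p = float(stats.chi2.sf(gof_chi2, gof_df)) if gof_chi2 > 0 else 1.0
    return DeltaResult(
        delta=delta, per_category_deltas=(float(d1), float(d2)),
        pi=(float(pi1), float(pi2)),
        gof_chi2=gof_chi2, gof_df=gof_df, gof_p=gof_p, expected=expected,
    )
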