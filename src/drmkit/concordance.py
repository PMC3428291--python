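"""Nonparametric ROC-type accuracy with a continuous gold standard.

When the criterion measure is continuous (here: affect scored from the
full-day DRM) the usual binary-gold-standard AUC generalizes to a
pairwise concordance U-statistic (Obuchowski): over all subject pairs
whose gold values differ, a pair scores 1 if the test measure orders it
the same way as the gold measure, 0.5 if the test values tie, and 0 if
it orders it the opposite way.  The AUC is the mean pair score: the
probability that of two randomly chosen subjects, the one with the
higher gold value also has the higher test value.

Pairs exactly tied on the gold standard carry no ordering information
and are excluded from the denominator; ``n_pairs_used`` records how
many pairs remain.  The standard error is the delete-one jackknife over
subjects, which matches the U-statistic component-variance estimator
asymptotically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reliability import DegenerateSampleError


@dataclass(frozen=True)
class PairedContinuousScores:
    """Aligned continuous gold-standard and test values per subject."""

    ids: tuple
    gold: np.ndarray
    test: np.ndarray

    @classmethod
    def from_arrays(cls, gold, test, ids=None) -> "PairedContinuousScores":
        gold = np.asarray(gold, dtype=float)
        test = np.asarray(test, dtype=float)
        if gold.shape != test.shape or gold.ndim != 1:
            raise ValueError("gold and test must be aligned 1-d arrays")
        keep = np.isfinite(gold) & np.isfinite(test)
        gold, test = gold[keep], test[keep]
        if ids is None:
            ids = tuple(range(len(gold)))
        else:
            ids = tuple(np.asarray(ids)[keep])
        return cls(ids=ids, gold=gold, test=test)

    def __len__(self) -> int:
        return len(self.gold)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float | None
    n: int
    n_pairs_used: int


def _coerce_scores(scores, test=None) -> PairedContinuousScores:
    if isinstance(scores, PairedContinuousScores):
        return scores
    return PairedContinuousScores.from_arrays(scores, test)


def _pair_sums(gold: np.ndarray, test: np.ndarray,
               block: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject sums of pair scores and pair counts (gold ties excluded).

    O(N^2) broadcast kernel evaluated in row blocks so memory stays
    O(block * N).
    """
    n = len(gold)
    row_scores = np.empty(n)
    row_pairs = np.empty(n)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        sg = np.sign(gold[lo:hi, None] - gold[None, :])
        st = np.sign(test[lo:hi, None] - test[None, :])
        informative = sg != 0
        score = np.where(sg == st, 1.0, np.where(st == 0, 0.5, 0.0))
        score[~informative] = 0.0
        idx = np.arange(lo, hi)
        score[idx - lo, idx] = 0.0
        informative[idx - lo, idx] = False
        row_scores[lo:hi] = score.sum(axis=1)
        row_pairs[lo:hi] = informative.sum(axis=1)
    return row_scores, row_pairs


def obuchowski_auc(scores, test=None, with_se: bool = True) -> AUCResult:
    """Pairwise-concordance AUC for a continuous gold standard.

    ``with_se=False`` skips the jackknife (used by the jackknife
    replicates themselves).
    """
    sc = _coerce_scores(scores, test)
    n = len(sc)
    if n < 2:
        raise DegenerateSampleError("need at least 2 subjects")
    row_scores, row_pairs = _pair_sums(sc.gold, sc.test)
    total_pairs = row_pairs.sum() / 2.0
    if total_pairs == 0:
        raise DegenerateSampleError("gold standard degenerate: all values tied")
    total_score = row_scores.sum() / 2.0
    auc = float(total_score / total_pairs)
    se = None
    if with_se and n >= 3:
        try:
            se = auc_standard_error(sc, _precomputed=(row_scores, row_pairs))
        except DegenerateSampleError:
            se = None  # a leave-one-out replicate loses all informative pairs
    return AUCResult(auc=auc, se=se, n=n, n_pairs_used=int(total_pairs))


def auc_standard_error(scores, test=None, _precomputed=None) -> float:
    """Delete-one jackknife standard error of the concordance AUC.

    Each leave-one-out estimate is obtained from the per-subject pair
    sums, so the jackknife costs no more than the point estimate.
    """
    sc = _coerce_scores(scores, test)
    n = len(sc)
    if n < 3:
        raise DegenerateSampleError("jackknife needs at least 3 subjects")
    if _precomputed is None:
        row_scores, row_pairs = _pair_sums(sc.gold, sc.test)
    else:
        row_scores, row_pairs = _precomputed
    total_score = row_scores.sum() / 2.0
    total_pairs = row_pairs.sum() / 2.0
    if total_pairs == 0:
        raise DegenerateSampleError("gold standard degenerate: all values tied")
    loo_pairs = total_pairs - row_pairs
    if np.any(loo_pairs == 0):
        raise DegenerateSampleError("a jackknife replicate has no informative pairs")
    loo_auc = (total_score - row_scores) / loo_pairs
    mean_loo = loo_auc.mean()
    var_jack = (n - 1) / n * np.sum((loo_auc - mean_loo) ** 2)
    return float(np.sqrt(var_jack))


def ustat_component_se(scores, test=None) -> float:
    """U-statistic structural-components variance estimate (cross-check).

    Treats the per-subject mean pair score as the estimated structural
    component V_i and uses var(AUC) ~ var(V_i) * 4 / n (two-sample-free
    one-population form with kernel order 2).
    """
    sc = _coerce_scores(scores, test)
    n = len(sc)
    if n < 3:
        raise DegenerateSampleError("need at least 3 subjects")
    row_scores, row_pairs = _pair_sums(sc.gold, sc.test)
    if np.any(row_pairs == 0):
        row_pairs = np.where(row_pairs == 0, 1.0, row_pairs)
    v = row_scores / row_pairs
    return float(np.sqrt(4.0 * np.var(v, ddof=1) / n))
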