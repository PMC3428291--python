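"""Test-retest reliability and effect-size statistics.

Implements the continuous-measure half of the validation battery:

* one-way random-effects, single-measure intraclass correlation (ICC)
  with an F-pivot confidence interval (Rosner's approach) and
  Landis-Koch qualitative banding;
* paired t tests with Cohen's d corrected for paired designs
  (Dunlap et al.: d = t * sqrt(2(1 - r)/n), r the test-retest Pearson
  correlation), so large-sample t statistics are not read as effects;
* Pearson correlations with Fisher-z confidence intervals and Spearman
  rank correlations;
* group-difference tests with descriptive effect sizes: chi-square with
  Cramer's V, one-way ANOVA with Cohen's f, unpaired t with Hedges' g.

The one-way ICC treats test and retest as interchangeable measurements
of the same subject: ICC = (MSB - MSW) / (MSB + (k-1) MSW) with k = 2.
It is bounded above by 1; sampling noise can drive the estimate below 0,
in which case it is reported as computed but banded as "poor".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DRMError


class DegenerateSampleError(DRMError):
    """Raised when a statistic is undefined for the given sample."""


@dataclass(frozen=True)
class PairedSample:
    """Aligned test/retest values for the same subjects."""

    ids: tuple
    x: np.ndarray
    y: np.ndarray

    @classmethod
    def from_arrays(cls, x, y, ids=None) -> "PairedSample":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be aligned 1-d arrays")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if ids is None:
            ids = tuple(range(len(x)))
        else:
            ids = tuple(np.asarray(ids)[keep])
        return cls(ids=ids, x=x, y=y)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    ms_between: float
    ms_within: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    d: float
    significant: bool

    @property
    def d_reported(self) -> float | None:
        """Effect size shown only for significant tests (verbose layers may show all)."""
        return self.d if self.significant else None


@dataclass(frozen=True)
class CorrResult:
    r: float
    ci_low: float | None
    ci_high: float | None
    n: int
    kind: str = "pearson"


def _coerce_pairs(pairs, y=None) -> PairedSample:
    if isinstance(pairs, PairedSample):
        return pairs
    return PairedSample.from_arrays(pairs, y)


# ---------------------------------------------------------------------------
# ICC


def landis_koch_band(icc: float) -> str:
    """Qualitative agreement label for a reliability coefficient.

    Right-closed 0.2-wide intervals; estimates at or below 0 are "poor".
    """
    if icc > 1:
        raise ValueError("reliability coefficients cannot exceed 1")
    if icc <= 0.2:
        return "poor"
    if icc <= 0.4:
        return "fair"
    if icc <= 0.6:
        return "moderate"
    if icc <= 0.8:
        return "substantial"
    return "almost perfect"


def icc_oneway(pairs, y=None, alpha: float = 0.05) -> ICCResult:
    """One-way random-effects, single-measure ICC for test/retest pairs.

    The one-way ANOVA decomposition with subjects as groups and k = 2
    measurements gives ICC = (MSB - MSW) / (MSB + MSW).  The confidence
    interval inverts the F = MSB/MSW pivot with df (n-1, n):
    bounds (F/F_u - 1)/(F/F_u + 1) and (F*F_l - 1)/(F*F_l + 1).
    """
    sample = _coerce_pairs(pairs, y)
    n = len(sample)
    if n < 3:
        raise DegenerateSampleError(f"need at least 3 pairs, got {n}")
    data = np.column_stack([sample.x, sample.y])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    ss_between = k * np.sum((subj_means - grand) ** 2)
    ss_within = np.sum((data - subj_means[:, None]) ** 2)
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    if ms_between == 0 and ms_within == 0:
        raise DegenerateSampleError("degenerate sample: zero total variance")
    if ms_within == 0:
        icc, ci_low, ci_high = 1.0, 1.0, 1.0
    else:
        icc = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
        f0 = ms_between / ms_within
        df1, df2 = n - 1, n * (k - 1)
        f_upper = stats.f.ppf(1 - alpha / 2, df1, df2)
        f_lower = stats.f.ppf(1 - alpha / 2, df2, df1)
        fl = f0 / f_upper
        fu = f0 * f_lower
        ci_low = (fl - 1) / (fl + (k - 1))
        ci_high = (fu - 1) / (fu + (k - 1))
    return ICCResult(
        icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high),
        band=landis_koch_band(float(icc)),
        ms_between=float(ms_between), ms_within=float(ms_within), n=n,
    )


# ---------------------------------------------------------------------------
# paired t with Dunlap-corrected d


def paired_t_dunlap(pairs, y=None, alpha: float = 0.05) -> PairedTestResult:
    """Paired t test with the paired-design-corrected Cohen's d.

    d = t * sqrt(2 (1 - r) / n), where r is the Pearson correlation
    between the two waves; this avoids the inflation of difference-score
    standardization when the waves are correlated.
    """
    sample = _coerce_pairs(pairs, y)
    n = len(sample)
    if n < 3:
        raise DegenerateSampleError(f"need at least 3 pairs, got {n}")
    diff = sample.x - sample.y
    if diff.std() == 0 and diff[0] != 0:
        raise DegenerateSampleError("zero variance of differences: t undefined")
    if np.all(diff == 0):
        t_stat, p = 0.0, 1.0
        r = 1.0
    else:
        t_stat, p = stats.ttest_rel(sample.x, sample.y)
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(sample.x, sample.y)[0, 1])
        if not np.isfinite(r):
            r = 0.0
    d = float(t_stat) * float(np.sqrt(2.0 * (1.0 - r) / n))
    return PairedTestResult(
        t=float(t_stat), df=n - 1, p=float(p), mean_diff=float(diff.mean()),
        d=float(d), significant=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# correlations


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(r) ± z_{1-α/2}/sqrt(n-3))."""
    if n < 4:
        raise DegenerateSampleError("Fisher CI needs n >= 4")
    if abs(r) >= 1.0:  # z diverges; the interval collapses to the endpoint
        return float(r), float(r)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_fisher_ci(x, y=None, alpha: float = 0.05) -> CorrResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    sample = _coerce_pairs(x, y)
    n = len(sample)
    if n < 4:
        raise DegenerateSampleError(f"need at least 4 pairs, got {n}")
    if np.std(sample.x) == 0 or np.std(sample.y) == 0:
        raise DegenerateSampleError("constant input: correlation undefined")
    r = float(stats.pearsonr(sample.x, sample.y).statistic)
    lo, hi = fisher_ci(r, n, alpha)
    return CorrResult(r=r, ci_low=lo, ci_high=hi, n=n, kind="pearson")


def spearman_rho(x, y=None) -> CorrResult:
    """Spearman rank correlation (Pearson on average ranks)."""
    sample = _coerce_pairs(x, y)
    n = len(sample)
    if n < 3:
        raise DegenerateSampleError(f"need at least 3 pairs, got {n}")
    rx = stats.rankdata(sample.x)
    ry = stats.rankdata(sample.y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise DegenerateSampleError("constant ranks: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return CorrResult(r=rho, ci_low=None, ci_high=None, n=n, kind="spearman")


# ---------------------------------------------------------------------------
# group-difference tests with descriptive effect sizes


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: tuple
    p: float
    effect_size: float
    effect_name: str


def chi2_cramers_v(table) -> GroupTestResult:
    """Chi-square independence test with Cramer's V = sqrt(chi2/(n (m-1)))."""
    table = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    expected = res.expected_freq
    if np.any(expected == 0):
        raise DegenerateSampleError("expected cell count of zero")
    n = table.sum()
    m = min(table.shape) - 1
    v = float(np.sqrt(res.statistic / (n * m)))
    return GroupTestResult(
        statistic=float(res.statistic), df=(int(res.dof),), p=float(res.pvalue),
        effect_size=v, effect_name="cramers_v",
    )


def anova_cohens_f(*groups) -> GroupTestResult:
    """One-way ANOVA with Cohen's f = sqrt(eta^2 / (1 - eta^2))."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    f_stat, p = stats.f_oneway(*groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = sum(((g - grand) ** 2).sum() for g in groups)
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    f_effect = float(np.sqrt(eta2 / (1 - eta2))) if eta2 < 1 else np.inf
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return GroupTestResult(
        statistic=float(f_stat), df=(df1, df2), p=float(p),
        effect_size=f_effect, effect_name="cohens_f",
    )


def ttest_hedges_g(a, b) -> GroupTestResult:
    """Unpaired t test with Hedges' g (small-sample-corrected d)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t_stat, p = stats.ttest_ind(a, b)
    na, nb = len(a), len(b)
    dof = na + nb - 2
    pooled_sd = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof)
    if pooled_sd == 0:
        raise DegenerateSampleError("zero pooled variance")
    d = (a.mean() - b.mean()) / pooled_sd
    correction = 1 - 3 / (4 * dof - 1)
    return GroupTestResult(
        statistic=float(t_stat), df=(dof,), p=float(p),
        effect_size=float(d * correction), effect_name="hedges_g",
    )


def group_difference_tests(data, kind: str = "auto") -> GroupTestResult:
    """Dispatch to the appropriate set-comparison test.

    ``kind`` is "chi2" (contingency table of counts, chi-square +
    Cramer's V), "anova" (sequence of samples, Cohen's f), "ttest"
    (two samples, Hedges' g), or "auto": a rectangular integer array is
    taken as a contingency table, otherwise the data are treated as a
    sequence of samples (t test when there are exactly two).
    """
    if kind == "chi2":
        return chi2_cramers_v(data)
    if kind == "ttest":
        return ttest_hedges_g(*data)
    if kind == "anova":
        return anova_cohens_f(*data)
    if kind != "auto":
        raise ValueError(f"unknown kind {kind!r}")
    try:
        arr = np.asarray(data, dtype=float)
    except (TypeError, ValueError):
        arr = None
    if arr is not None and arr.ndim == 2 and np.allclose(arr, np.round(arr)) and arr.min() >= 0:
        return chi2_cramers_v(arr)
    groups = list(data)
    if len(groups) == 2:
        return ttest_hedges_g(*groups)
    return anova_cohens_f(*groups)
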