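"""Linear model of net affect on demographics with interaction pruning.

The sociodemographic analysis regresses baseline net affect on three
binary predictors — education (0 = less than primary school, 1 =
primary completed or more), setting (0 = rural, 1 = urban) and
household income (0 = lower two quintiles, 1 = upper three) — with sex
(0 = female, 1 = male) and age as covariates.  An initial model adds
all pairwise interactions among the four binary predictors; a nested
ANOVA F test asks whether the interactions jointly explain additional
variance, and a single pruning pass drops the non-significant
interactions to give the final model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import DRMError

DEFAULT_MAIN_EFFECTS = ("education01", "setting01", "income01")
DEFAULT_COVARIATES = ("sex", "age")
CATEGORICAL_PREDICTORS = ("education01", "setting01", "income01", "sex")


def default_interactions() -> tuple[tuple[str, str], ...]:
    """All pairwise interactions among the four binary predictors."""
    preds = CATEGORICAL_PREDICTORS
    return tuple(
        (preds[i], preds[j]) for i in range(len(preds)) for j in range(i + 1, len(preds))
    )


@dataclass(frozen=True)
class DesignSpec:
    """Columns and interaction terms of a net-affect regression."""

    response: str = "net"
    main_effects: tuple = DEFAULT_MAIN_EFFECTS
    covariates: tuple = DEFAULT_COVARIATES
    interactions: tuple = field(default_factory=default_interactions)

    @property
    def terms(self) -> tuple[str, ...]:
        inter = tuple(f"{a}:{b}" for a, b in self.interactions)
        return tuple(self.main_effects) + tuple(self.covariates) + inter

    def reduced(self) -> "DesignSpec":
        return replace(self, interactions=())


@dataclass
class ModelFit:
    """OLS fit summary with the pieces the analysis tables report."""

    design: DesignSpec
    terms: tuple
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    f_statistic: float
    f_df: tuple
    f_pvalue: float
    r_squared: float
    adj_r_squared: float
    rss: float
    df_resid: int
    nobs: int
    resid: np.ndarray
    exog: np.ndarray

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )


def build_design_matrix(design: DesignSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    cols = {"const": np.ones(len(data))}
    for term in design.main_effects + design.covariates:
        cols[term] = data[term].to_numpy(dtype=float)
    for a, b in design.interactions:
        cols[f"{a}:{b}"] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=data.index)
    y = data[design.response].astype(float)
    return X, y


def fit_linear_model(design: DesignSpec, data: pd.DataFrame) -> ModelFit:
    """Fit the specified OLS model; raises on rank-deficient designs."""
    X, y = build_design_matrix(design, data)
    if len(data) <= X.shape[1]:
        raise DRMError(f"n = {len(data)} too small for {X.shape[1]} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns for the error message
        aliased = []
        keep: list[str] = []
        for col in X.columns:
            trial = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(col)
            else:
                aliased.append(col)
        raise DRMError(f"rank-deficient design; aliased terms: {aliased}")
    res = sm.OLS(y, X).fit()
    return ModelFit(
        design=design,
        terms=tuple(X.columns),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        f_statistic=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        rss=float(res.ssr),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        resid=np.asarray(res.resid),
        exog=X.to_numpy(),
    )


@dataclass(frozen=True)
class NestedFResult:
    f: float
    df1: int
    df2: int
    p: float


def nested_f_test(full: ModelFit, reduced: ModelFit) -> NestedFResult:
    """ANOVA comparison of nested OLS fits on the same data.

    F = [(RSS_r - RSS_f)/df1] / [RSS_f/df2].
    """
    if full.nobs != reduced.nobs:
        raise DRMError("models were fitted on different data")
    if not set(reduced.terms) <= set(full.terms):
        raise DRMError("models are not nested")
    df1 = len(full.terms) - len(reduced.terms)
    if df1 == 0:
        return NestedFResult(f=0.0, df1=0, df2=full.df_resid, p=1.0)
    df2 = full.df_resid
    f = ((reduced.rss - full.rss) / df1) / (full.rss / df2)
    f = max(f, 0.0)
    return NestedFResult(f=float(f), df1=df1, df2=df2, p=float(stats.f.sf(f, df1, df2)))


def prune_to_final_model(full_fit: ModelFit, alpha: float = 0.05) -> DesignSpec:
    """Single-pass pruning: keep main effects and covariates, drop all
    interaction terms not significant at ``alpha`` in the initial fit."""
    design = full_fit.design
    kept = tuple(
        (a, b)
        for a, b in design.interactions
        if float(full_fit.pvalues[f"{a}:{b}"]) < alpha
    )
    return replace(design, interactions=kept)
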