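"""Orchestration of the full abbreviated-DRM validation analysis.

Given a study (real or synthetic) with a short-set test wave and a
FULL-day retest wave, produce the complete battery of report tables:

* sample description by set with set-difference tests (chi-square /
  ANOVA) and effect sizes;
* per-set and pooled test-retest comparison — each short set is paired
  with the slice of the FULL retest covering the same part of the day —
  with means, paired t, corrected d, and one-way ICC with CI;
* ICC subgroup table by education / income / setting;
* concordance (AUC) tables: pooled short-version scores against the
  FULL retest, and, within the retest, each part of the day against the
  full day;
* per-activity affect profile with ranking stability;
* net-affect regression with interactions, nested F test and pruning;
* supplementary-question agreement battery (Delta, kappa, weighted
  kappa).

The pipeline only calls module-level operations; every number in the
JSON summary is recomputable from them directly.  All row exclusions
are logged with counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activities as activities_mod
from . import agreement as agreement_mod
from . import concordance as concordance_mod
from . import reliability as reliability_mod
from . import regression as regression_mod
from .core import (
    PERIODS,
    SET_PERIOD,
    Study,
    score_episode_frame,
    score_segment_frame,
    split_full_frame,
)
from .reliability import DegenerateSampleError

logger = logging.getLogger("drmkit.pipeline")

MEASURES = ("net", "pa", "na", "u_index")


@dataclass
class RunConfig:
    """Knobs of a validation run."""

    alpha: float = 0.05
    kappa_scheme: str = "linear"
    min_activity_pct: float = 5.0
    respondent_level_activities: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_activity_pct <= 100:
            raise ValueError("min_activity_pct must be a percentage")


@dataclass
class ValidationReport:
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    partial: bool = False

    def to_json(self) -> str:
        return json.dumps(_plain(self.summary), sort_keys=True, indent=1)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False, lineterminator="\n")
        (outdir / "summary.json").write_text(self.to_json() + "\n")


def _plain(obj):
    """Recursively convert to JSON-serializable plain Python values."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    return obj


# ---------------------------------------------------------------------------
# scoring and wave matching


def score_study(study: Study) -> pd.DataFrame:
    """Respondent-wave affect summaries for episode and segment records."""
    parts = []
    if len(study.episodes):
        parts.append(score_episode_frame(study.episodes))
    if len(study.segments):
        parts.append(score_segment_frame(study.segments))
    if not parts:
        raise ValueError("study has no records to score")
    return pd.concat(parts, ignore_index=True).sort_values(
        ["respondent_id", "wave"], kind="stable"
    ).reset_index(drop=True)


def _retest_slices(study: Study) -> dict[str, pd.DataFrame]:
    """Score the FULL retest wave by part of day and for the whole day."""
    full = study.episodes.query("wave == 'retest' and set == 'FULL'")
    out = {"global": score_episode_frame(full)}
    if len(full):
        split = split_full_frame(full)
        for period in PERIODS:
            out[period] = score_episode_frame(split.query("period == @period"))
    else:
        for period in PERIODS:
            out[period] = out["global"]
    return out


def _matched_pairs(study: Study, scores: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-set paired test/retest measures, matched on respondent id.

    Sets A/B/C pair against the same part of day in the FULL retest;
    set D pairs against the whole retest day.
    """
    slices = _retest_slices(study)
    test = scores.query("wave == 'test'").set_index("respondent_id")
    pairs = {}
    for set_name in ("A", "B", "C", "D"):
        t = test.query("set == @set_name")
        period = SET_PERIOD.get(set_name)
        r = (slices[period] if period else slices["global"]).set_index("respondent_id")
        joined = t.join(r, how="inner", lsuffix="_test", rsuffix="_retest")
        pairs[set_name] = joined
        dropped = len(t) - len(joined)
        if dropped:
            logger.info("set %s: %d respondents without a matched retest excluded",
                        set_name, dropped)
    return pairs


def pooled_measure_icc(study: Study, measure: str = "net", alpha: float = 0.05
                       ) -> reliability_mod.ICCResult:
    """Pooled test-retest ICC for one measure, skipping the full battery.

    Matches each short set against its FULL-retest slice exactly as the
    test-retest table does, then computes the one-way ICC over the
    concatenated per-set pairs.  Used for large-n recovery checks where
    running every table would be wasteful.
    """
    scores = score_study(study)
    pairs = _matched_pairs(study, scores)
    xs, ys = [], []
    for set_name, joined in pairs.items():
        if measure == "u_index" and set_name == "D":
            continue
        sample = _measure_pairs(joined, measure)
        xs.append(sample.x)
        ys.append(sample.y)
    pooled = reliability_mod.PairedSample.from_arrays(np.concatenate(xs), np.concatenate(ys))
    return reliability_mod.icc_oneway(pooled, alpha=alpha)


# ---------------------------------------------------------------------------
# table builders


def _sample_description(study: Study, alpha: float) -> tuple[pd.DataFrame, dict]:
    resp = study.respondents
    rows, stats = [], {}
    by_set = {s: resp.query("set_assignment == @s") for s in "ABCD"}
    counts = {s: len(df) for s, df in by_set.items()}

    def add(variable, kind, result):
        sig = result.p < alpha
        rows.append({
            "variable": variable, "test": kind, "statistic": result.statistic,
            "p": result.p, "effect_size": result.effect_size if sig else np.nan,
            "effect_name": result.effect_name if sig else "",
        })
        stats[variable] = {"statistic": result.statistic, "p": result.p,
                           "effect_size": result.effect_size,
                           "effect_name": result.effect_name}

    for var in ("sex", "education01", "setting01", "income_quintile"):
        table = pd.crosstab(resp["set_assignment"], resp[var]).to_numpy()
        add(var, "chi2", reliability_mod.chi2_cramers_v(table))
    marital = pd.crosstab(resp["set_assignment"], resp["marital"]).to_numpy()
    add("marital", "chi2", reliability_mod.chi2_cramers_v(marital))
    add("age", "anova",
        reliability_mod.anova_cohens_f(*[df["age"].to_numpy() for df in by_set.values()]))
    stats["set_counts"] = counts
    stats["set_shares"] = {s: c / len(resp) for s, c in counts.items()}
    return pd.DataFrame(rows), stats


def _measure_pairs(joined: pd.DataFrame, measure: str) -> reliability_mod.PairedSample:
    x = joined[f"{measure}_test"]
    y = joined[f"{measure}_retest"]
    return reliability_mod.PairedSample.from_arrays(x, y, ids=joined.index)


def _test_retest_table(pairs: dict, alpha: float) -> tuple[pd.DataFrame, dict]:
    rows, stats = [], {}
    blocks = list(pairs.items())
    pooled = {m: [] for m in MEASURES}
    for set_name, joined in blocks:
        for measure in MEASURES:
            if measure == "u_index" and set_name == "D":
                continue
            sample = _measure_pairs(joined, measure)
            pooled[measure].append(sample)
            rows.append(_reliability_row(set_name, measure, sample, alpha, stats))
    for measure in MEASURES:
        if not pooled[measure]:
            continue
        x = np.concatenate([s.x for s in pooled[measure]])
        y = np.concatenate([s.y for s in pooled[measure]])
        sample = reliability_mod.PairedSample.from_arrays(x, y)
        rows.append(_reliability_row("pooled", measure, sample, alpha, stats))
    return pd.DataFrame(rows), stats


def _reliability_row(set_name, measure, sample, alpha, stats) -> dict:
    row = {"set": set_name, "measure": measure, "n": len(sample)}
    try:
        tt = reliability_mod.paired_t_dunlap(sample, alpha=alpha)
        icc = reliability_mod.icc_oneway(sample, alpha=alpha)
    except DegenerateSampleError as err:
        logger.info("set %s measure %s: %s", set_name, measure, err)
        row.update(mean_test=np.nan, sd_test=np.nan, mean_retest=np.nan,
                   sd_retest=np.nan, t=np.nan, p=np.nan, d=np.nan, icc=np.nan,
                   icc_low=np.nan, icc_high=np.nan, band="")
        return row
    row.update(
        mean_test=sample.x.mean(), sd_test=sample.x.std(ddof=1),
        mean_retest=sample.y.mean(), sd_retest=sample.y.std(ddof=1),
        t=tt.t, p=tt.p, d=tt.d if tt.significant else np.nan,
        icc=icc.icc, icc_low=icc.ci_low, icc_high=icc.ci_high, band=icc.band,
    )
    stats[f"{set_name}.{measure}"] = {
        "n": len(sample), "t": tt.t, "p": tt.p, "d": tt.d,
        "significant": tt.significant, "icc": icc.icc,
        "icc_ci": [icc.ci_low, icc.ci_high], "band": icc.band,
        "mean_test": float(sample.x.mean()), "mean_retest": float(sample.y.mean()),
    }
    return row


def _subgroup_icc_table(pairs: dict, respondents: pd.DataFrame, alpha: float
                        ) -> tuple[pd.DataFrame, dict]:
    resp = respondents.set_index("respondent_id")
    all_joined = pd.concat(pairs.values())
    rows, stats = [], {}
    for var in ("education01", "income01", "setting01"):
        groups = resp.loc[resp.index.intersection(all_joined.index), var]
        for level in (0, 1):
            members = groups.index[groups == level]
            sub = all_joined.loc[all_joined.index.isin(members)]
            for measure in MEASURES:
                sample = _measure_pairs(sub, measure)
                if len(sample) < 3:
                    continue
                try:
                    icc = reliability_mod.icc_oneway(sample, alpha=alpha)
                except DegenerateSampleError:
                    continue
                rows.append({
                    "variable": var, "level": level, "measure": measure,
                    "n": len(sample), "icc": icc.icc,
                    "icc_low": icc.ci_low, "icc_high": icc.ci_high, "band": icc.band,
                })
                stats[f"{var}={level}.{measure}"] = {
                    "n": len(sample), "icc": icc.icc,
                    "icc_ci": [icc.ci_low, icc.ci_high],
                }
    return pd.DataFrame(rows), stats


def _auc_tables(study: Study, scores: pd.DataFrame, pairs: dict
                ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    stats = {}

    # (a) short-version scores at test vs FULL whole-day retest scores
    retest_global = _retest_slices(study)["global"].set_index("respondent_id")
    test = scores.query("wave == 'test'").set_index("respondent_id")
    rows_a = []
    for label, sets in (("ABC", ("A", "B", "C")), ("D", ("D",))):
        t = test.loc[test["set"].isin(sets)]
        joined = t.join(retest_global, how="inner", lsuffix="_test", rsuffix="_retest")
        for measure in MEASURES:
            if measure == "u_index" and label == "D":
                continue
            sc = concordance_mod.PairedContinuousScores.from_arrays(
                joined[f"{measure}_retest"], joined[f"{measure}_test"], ids=joined.index
            )
            try:
                res = concordance_mod.obuchowski_auc(sc)
            except DegenerateSampleError as err:
                logger.info("AUC %s/%s skipped: %s", label, measure, err)
                continue
            rows_a.append({"comparison": label, "measure": measure, "n": res.n,
                           "auc": res.auc, "se": res.se})
            stats[f"short_vs_full.{label}.{measure}"] = {
                "auc": res.auc, "se": res.se, "n": res.n,
                "n_pairs_used": res.n_pairs_used,
            }

    # (b) within-retest: each part of the day vs the full day
    slices = _retest_slices(study)
    full = slices["global"].set_index("respondent_id")
    rows_b = []
    pooled: dict[str, list] = {m: [] for m in MEASURES}
    for period in PERIODS:
        part = slices[period].set_index("respondent_id")
        joined = part.join(full, how="inner", lsuffix="_part", rsuffix="_full")
        for measure in MEASURES:
            gold = joined[f"{measure}_full"]
            testv = joined[f"{measure}_part"]
            keep = gold.notna() & testv.notna()
            pooled[measure].append((gold[keep].to_numpy(), testv[keep].to_numpy()))
            sc = concordance_mod.PairedContinuousScores.from_arrays(gold, testv)
            try:
                res = concordance_mod.obuchowski_auc(sc)
            except DegenerateSampleError as err:
                logger.info("AUC slice %s/%s skipped: %s", period, measure, err)
                continue
            rows_b.append({"period": period, "measure": measure, "n": res.n,
                           "auc": res.auc, "se": res.se})
            stats[f"slice_vs_full.{period}.{measure}"] = {
                "auc": res.auc, "se": res.se, "n": res.n,
            }
    for measure in MEASURES:
        if not pooled[measure]:
            continue
        gold = np.concatenate([g for g, _ in pooled[measure]])
        testv = np.concatenate([t for _, t in pooled[measure]])
        try:
            res = concordance_mod.obuchowski_auc(
                concordance_mod.PairedContinuousScores.from_arrays(gold, testv)
            )
        except DegenerateSampleError:
            continue
        rows_b.append({"period": "global", "measure": measure, "n": res.n,
                       "auc": res.auc, "se": res.se})
        stats[f"slice_vs_full.global.{measure}"] = {
            "auc": res.auc, "se": res.se, "n": res.n,
        }
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b), stats


def _activity_tables(study: Study, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    abc = study.episodes.loc[
        ((study.episodes["wave"] == "test") & study.episodes["set"].isin(["A", "B", "C"]))
        | ((study.episodes["wave"] == "retest") & (study.episodes["set"] == "FULL"))
    ]
    table = activities_mod.activity_table(abc)
    stats: dict = {"n_activities": len(table)}
    try:
        ranked = activities_mod.rank_and_correlate(table, min_pct=config.min_activity_pct)
    except Exception as err:  # fewer than 3 activities above threshold
        logger.info("ranking skipped: %s", err)
        return table, stats
    sp = ranked["spearman"]
    pe = ranked["pearson_of_means"]
    stats.update({
        "spearman_rankings": sp.r,
        "pearson_of_means": pe.r,
        "pearson_of_means_ci": [pe.ci_low, pe.ci_high],
        "n_ranked": ranked["n_activities"],
    })
    if ranked["n_activities"] >= 4:
        lo, hi = reliability_mod.fisher_ci(sp.r, sp.n)
        stats["spearman_ci"] = [lo, hi]
    return table, stats


def _regression_tables(study: Study, scores: pd.DataFrame, alpha: float
                       ) -> tuple[pd.DataFrame, dict]:
    test = scores.query("wave == 'test'")[["respondent_id", "net"]]
    data = test.merge(study.respondents, on="respondent_id", how="inner").dropna(subset=["net"])
    design = regression_mod.DesignSpec()
    initial = regression_mod.fit_linear_model(design, data)
    reduced = regression_mod.fit_linear_model(design.reduced(), data)
    nested = regression_mod.nested_f_test(initial, reduced)
    final_design = regression_mod.prune_to_final_model(initial, alpha=alpha)
    final = regression_mod.fit_linear_model(final_design, data)
    table = final.coefficient_table().reset_index(names="term")
    stats = {
        "n": initial.nobs,
        "initial": {"f": initial.f_statistic, "f_df": list(initial.f_df),
                    "p": initial.f_pvalue, "adj_r2": initial.adj_r_squared},
        "nested_f": {"f": nested.f, "df": [nested.df1, nested.df2], "p": nested.p},
        "final": {
            "f": final.f_statistic, "f_df": list(final.f_df), "p": final.f_pvalue,
            "adj_r2": final.adj_r_squared,
            "terms": list(final.terms),
            "coefficients": {t: float(final.params[t]) for t in final.terms},
            "pvalues": {t: float(final.pvalues[t]) for t in final.terms},
        },
        "retained_interactions": [f"{a}:{b}" for a, b in final_design.interactions],
    }
    return table, stats


def _agreement_tables(supplementary: pd.DataFrame, config: RunConfig
                      ) -> tuple[pd.DataFrame, dict]:
    rows, stats = [], {}
    for item, grp in supplementary.groupby("item", sort=True):
        complete = grp.dropna(subset=["test", "retest"])
        if not len(complete):
            continue
        kind = grp["kind"].iloc[0]
        labels = (0, 1) if kind == "binary" else (0, 1, 2)
        table = agreement_mod.AgreementTable.from_answers(
            complete["test"].astype(int), complete["retest"].astype(int), labels=labels
        )
        row = {"item": item, "kind": kind, "n": int(table.n)}
        entry: dict = {"n": int(table.n)}
        try:
            kappa = agreement_mod.cohen_kappa(table)
            row["kappa"] = kappa.kappa
            entry["kappa"] = kappa.kappa
        except DegenerateSampleError as err:
            logger.info("item %s: %s", item, err)
            row["kappa"] = np.nan
        if kind == "binary":
            try:
                delta = agreement_mod.delta_2x2(table)
                row.update(delta=delta.delta, gof_p=delta.gof_p)
                entry.update(delta=delta.delta, gof_chi2=delta.gof_chi2,
                             gof_p=delta.gof_p,
                             per_category_deltas=list(delta.per_category_deltas))
            except DegenerateSampleError as err:
                logger.info("item %s: %s", item, err)
                row.update(delta=np.nan, gof_p=np.nan)
            row["weighted_kappa"] = np.nan
        else:
            wk = agreement_mod.weighted_kappa(table, scheme=config.kappa_scheme)
            row.update(weighted_kappa=wk.kappa, delta=np.nan, gof_p=np.nan)
            entry.update(weighted_kappa=wk.kappa, weight_scheme=config.kappa_scheme)
        rows.append(row)
        stats[item] = entry
    return pd.DataFrame(rows), stats


# ---------------------------------------------------------------------------
# entry point


def run_validation(
    study: Study,
    supplementary: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> ValidationReport:
    """Run the full validation battery on a scored study."""
    config = config or RunConfig()
    report = ValidationReport()
    alpha = config.alpha
    summary: dict = {"alpha": alpha}

    scores = score_study(study)
    report.tables["scores"] = scores
    has_retest = bool((scores["wave"] == "retest").any())
    report.partial = not has_retest

    table1, stats1 = _sample_description(study, alpha)
    report.tables["sample_description"] = table1
    summary["sample"] = stats1

    if has_retest:
        pairs = _matched_pairs(study, scores)
        table2, stats2 = _test_retest_table(pairs, alpha)
        report.tables["test_retest"] = table2
        summary["test_retest"] = stats2

        tableS1, statsS1 = _subgroup_icc_table(pairs, study.respondents, alpha)
        report.tables["icc_subgroups"] = tableS1
        summary["icc_subgroups"] = statsS1

        auc_a, auc_b, stats_auc = _auc_tables(study, scores, pairs)
        report.tables["auc_short_vs_full"] = auc_a
        report.tables["auc_slices"] = auc_b
        summary["auc"] = stats_auc

        act_table, act_stats = _activity_tables(study, config)
        report.tables["activity_profile"] = act_table
        summary["activities"] = act_stats

        # negative affect vs U-index association at each wave (sets A-C)
        na_u = {}
        abc = scores.loc[scores["set"].isin(["A", "B", "C", "FULL"])]
        for wave in ("test", "retest"):
            sub = abc.query("wave == @wave").dropna(subset=["na", "u_index"])
            if len(sub) >= 4:
                corr = reliability_mod.pearson_fisher_ci(sub["na"], sub["u_index"])
                na_u[wave] = {"r": corr.r, "ci": [corr.ci_low, corr.ci_high], "n": corr.n}
        summary["na_vs_uindex"] = na_u
    else:
        logger.warning("no retest wave found: reliability sections skipped")

    tableS2, statsS2 = _regression_tables(study, scores, alpha)
    report.tables["regression"] = tableS2
    summary["regression"] = statsS2

    if supplementary is not None and len(supplementary) and has_retest:
        tableS3, statsS3 = _agreement_tables(supplementary, config)
        report.tables["supplementary_agreement"] = tableS3
        summary["supplementary_agreement"] = statsS3

    summary["partial"] = report.partial
    report.summary = summary
    return report


def render_tables(report: ValidationReport) -> str:
    """Plain-text rendering of all report tables."""
    chunks = []
    for name, table in report.tables.items():
        chunks.append(f"== {name} ==")
        chunks.append(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        chunks.append("")
    return "\n".join(chunks)
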