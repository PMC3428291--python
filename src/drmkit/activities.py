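"""Per-activity affect profiling and temporal stability.

For each activity in the catalog, over respondents with episode-based
records in both waves: the percent of respondents reporting it in each
wave, the duration-weighted mean net affect associated with it, and the
test-retest stability of the activity's affect — a per-activity Pearson
correlation over respondents who reported the activity in both waves,
plus ranking stability (Spearman) and a Pearson correlation of the
activity means across waves.  An episode listing several activities
contributes its full duration and affect to each listed activity, so
reporting percentages may sum past 100%.

Only activities reported at baseline by at least 5% of the sample enter
the ranking (inclusive threshold, baseline percentage only); the rest
are listed separately.  Segment-based (set D) records carry no
episode-linked affect and are excluded from affect profiling; a flag
lets their activity mentions count toward reporting percentages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import is_known_activity
from .core import DRMError, NEGATIVE_ITEMS, POSITIVE_ITEMS, drop_incomplete
from .reliability import DegenerateSampleError, pearson_fisher_ci, spearman_rho

TABLE_COLUMNS = [
    "activity", "pct_test", "mean_net_test", "se_test",
    "pct_retest", "mean_net_retest", "se_retest",
    "n_both", "r", "r_ci_low", "r_ci_high",
]


def _exploded_scores(episodes: pd.DataFrame) -> pd.DataFrame:
    df, _ = drop_incomplete(episodes)
    df = df.copy()
    neg = df[list(NEGATIVE_ITEMS)].to_numpy(dtype=float)
    pos = df[list(POSITIVE_ITEMS)].to_numpy(dtype=float)
    df["net"] = pos.mean(axis=1) - neg.mean(axis=1)
    df["dur"] = (df["end_min"] - df["start_min"]).astype(float)
    df["activity"] = df["activities"].str.split(";")
    out = df[["respondent_id", "wave", "activity", "net", "dur"]].explode("activity")
    bad = out.loc[~out["activity"].map(is_known_activity)]
    if len(bad):
        raise DRMError(f"unknown activity code {bad['activity'].iloc[0]!r}")
    return out


def _weighted_stats(group: pd.DataFrame) -> tuple[float, float]:
    w = group["dur"].to_numpy()
    x = group["net"].to_numpy()
    total = w.sum()
    mean = float((w * x).sum() / total)
    se = float(np.sqrt((w**2 * (x - mean) ** 2).sum()) / total)
    return mean, se


def activity_table(
    episodes: pd.DataFrame,
    segments: pd.DataFrame | None = None,
    require_both_waves: bool = True,
    segments_count_toward_pct: bool = False,
) -> pd.DataFrame:
    """Per-activity affect profile across the test and retest waves.

    ``episodes`` holds episode rows for both waves.  When
    ``require_both_waves`` is set (the default) the sample is restricted
    to respondents with episode records in both waves, matching how the
    published profile conditions on completers.
    """
    ex = _exploded_scores(episodes)
    by_wave = {w: set(ex.loc[ex["wave"] == w, "respondent_id"]) for w in ("test", "retest")}
    if require_both_waves:
        sample = by_wave["test"] & by_wave["retest"]
        ex = ex.loc[ex["respondent_id"].isin(sample)]
    else:
        sample = by_wave["test"] | by_wave["retest"]
    n_sample = len(sample)
    if n_sample == 0:
        raise DRMError("no respondents with episode records in the requested waves")

    seg_mentions: dict[tuple[str, str], set] = {}
    if segments is not None and segments_count_toward_pct and len(segments):
        seg = segments.copy()
        seg["activity"] = seg["activities"].str.split(";")
        seg = seg.explode("activity")
        seg = seg.loc[seg["activity"].astype(str) != ""]
        for (wave, act), grp in seg.groupby(["wave", "activity"]):
            seg_mentions[(wave, str(act))] = set(grp["respondent_id"])

    # respondent-level aggregates per activity and wave (for the r column)
    resp_level = (
        ex.assign(wnet=lambda d: d["net"] * d["dur"])
        .groupby(["activity", "wave", "respondent_id"], sort=True)
        .agg(wnet=("wnet", "sum"), dur=("dur", "sum"))
        .assign(net=lambda d: d["wnet"] / d["dur"])
        .reset_index()
    )

    rows = []
    for activity, grp in ex.groupby("activity", sort=True):
        row: dict = {"activity": activity}
        for wave in ("test", "retest"):
            sub = grp.loc[grp["wave"] == wave]
            reporters = set(sub["respondent_id"]) | seg_mentions.get((wave, activity), set())
            if len(sub):
                mean, se = _weighted_stats(sub)
            else:
                mean, se = np.nan, np.nan
            row[f"pct_{wave}"] = 100.0 * len(reporters) / n_sample
            row[f"mean_net_{wave}"] = mean
            row[f"se_{wave}"] = se
        both = resp_level.loc[resp_level["activity"] == activity]
        wide = both.pivot(index="respondent_id", columns="wave", values="net")
        if "test" in wide.columns and "retest" in wide.columns:
            paired = wide.dropna(subset=["test", "retest"])
        else:
            paired = wide.iloc[:0]
        row["n_both"] = len(paired)
        row["r"] = row["r_ci_low"] = row["r_ci_high"] = np.nan
        if len(paired) >= 4:
            try:
                corr = pearson_fisher_ci(paired["test"], paired["retest"])
                row.update(r=corr.r, r_ci_low=corr.ci_low, r_ci_high=corr.ci_high)
            except DegenerateSampleError:
                pass
        elif len(paired) == 3:
            sd = paired.std(ddof=0)
            if sd["test"] > 0 and sd["retest"] > 0:
                row["r"] = float(np.corrcoef(paired["test"], paired["retest"])[0, 1])
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def rank_and_correlate(table: pd.DataFrame, min_pct: float = 5.0) -> dict:
    """Ranking stability of per-activity affect between waves.

    Filters to activities reported at baseline by at least ``min_pct``
    percent of the sample (inclusive), ranks by test-wave mean net
    affect (ties broken by activity code for a deterministic listing),
    and reports the Spearman correlation between the wave rankings and
    the Pearson correlation (with Fisher-z CI) of the mean net affect
    values across activities.
    """
    kept = table.loc[table["pct_test"] >= min_pct].copy()
    kept = kept.dropna(subset=["mean_net_test", "mean_net_retest"])
    if len(kept) < 3:
        raise DRMError(
            f"only {len(kept)} activities pass the {min_pct}% baseline filter; need >= 3"
        )
    kept = kept.sort_values(
        ["mean_net_test", "activity"], ascending=[False, True]
    ).reset_index(drop=True)
    kept["rank_test"] = np.arange(1, len(kept) + 1)
    kept["rank_retest"] = (
        kept["mean_net_retest"].rank(ascending=False, method="average")
    )
    spearman = spearman_rho(kept["mean_net_test"], kept["mean_net_retest"])
    if len(kept) >= 4:
        pearson = pearson_fisher_ci(kept["mean_net_test"], kept["mean_net_retest"])
    else:  # three activities: correlation defined, Fisher CI is not
        from .reliability import CorrResult

        r = float(np.corrcoef(kept["mean_net_test"], kept["mean_net_retest"])[0, 1])
        pearson = CorrResult(r=r, ci_low=None, ci_high=None, n=len(kept))
    per_activity = kept.set_index("activity")[["n_both", "r", "r_ci_low", "r_ci_high"]]
    return {
        "ranking": kept,
        "spearman": spearman,
        "pearson_of_means": pearson,
        "per_activity_r": per_activity,
        "n_activities": len(kept),
    }
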