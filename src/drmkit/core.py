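"""Data model, affect scoring and delimited-text I/O for abbreviated DRM studies.

The Day Reconstruction Method (DRM) asks a respondent to reconstruct the
previous day as a sequence of episodes, each with a time interval, one or
more activities, companions, and seven affect ratings on a 1..3 scale
(five negative items, two positive items).  The abbreviated instrument
randomizes each respondent to one of four sets:

* sets A, B, C — episode-by-episode reconstruction of the morning,
  afternoon, or evening respectively;
* set D — one coarse affect block per part of the day (morning,
  afternoon, evening), with no durations;
* FULL — the original full-day instrument, used at the retest wave.

Scoring follows the instrument's rules: positive affect (PA) is the mean
of calm/relaxed and enjoyment, negative affect (NA) the mean of the five
negative items, net affect PA − NA (range −2..2).  For episode-based sets
the respondent summary weights episodes by duration, and the U-index is
the proportion of reported time in episodes whose highest-rated feeling
is negative.  Set D is scored as an unweighted mean over its segments and
has no U-index (durations were not collected).

Period boundaries: morning runs from wake-up to noon, afternoon from
noon to 18:00, evening from 18:00 onward.  Episodes straddling a boundary
are split with durations prorated.  Intervals are half-open [start, end)
in minutes since midnight, so abutting episodes never double-count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import is_known_activity

logger = logging.getLogger("drmkit")

NEGATIVE_ITEMS = ("worried", "rushed", "irritated_angry", "depressed", "tense_stressed")
POSITIVE_ITEMS = ("calm_relaxed", "enjoyment")
RATING_ITEMS = NEGATIVE_ITEMS + POSITIVE_ITEMS

WAVES = ("test", "retest")
EPISODE_SETS = ("A", "B", "C", "FULL")
ALL_SETS = ("A", "B", "C", "D", "FULL")
PERIODS = ("morning", "afternoon", "evening")

#: minutes since midnight delimiting the parts of the day
NOON_MIN = 12 * 60
EVENING_MIN = 18 * 60

SET_PERIOD = {"A": "morning", "B": "afternoon", "C": "evening"}

EPISODE_COLUMNS = [
    "respondent_id", "wave", "set", "period", "start_min", "end_min",
    "activities", "companions", *RATING_ITEMS,
]
SEGMENT_COLUMNS = ["respondent_id", "wave", "period", "activities", "companions", *RATING_ITEMS]
RESPONDENT_COLUMNS = [
    "respondent_id", "sex", "age", "education_raw", "education01", "marital",
    "setting01", "income_quintile", "income01", "set_assignment",
]


class DRMError(Exception):
    """Base class for drmkit errors."""


class ValidationError(DRMError):
    """Raised when a record or table violates the data contract."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class AffectRatings:
    """The seven affect item ratings for one episode or segment (1..3 each)."""

    worried: int
    rushed: int
    irritated_angry: int
    depressed: int
    tense_stressed: int
    calm_relaxed: int
    enjoyment: int

    def __post_init__(self) -> None:
        for item in RATING_ITEMS:
            value = getattr(self, item)
            if value not in (1, 2, 3):
                raise ValidationError(f"rating {item!r} must be in {{1, 2, 3}}, got {value!r}")

    def negatives(self) -> tuple[int, ...]:
        return tuple(getattr(self, item) for item in NEGATIVE_ITEMS)

    def positives(self) -> tuple[int, ...]:
        return tuple(getattr(self, item) for item in POSITIVE_ITEMS)


@dataclass(frozen=True)
class EpisodeRecord:
    """One reconstructed episode: interval, activities, companions, ratings."""

    respondent_id: str
    wave: str
    period: str
    start_min: int
    end_min: int
    activities: frozenset[str]
    companions: frozenset[str]
    ratings: AffectRatings | None

    def __post_init__(self) -> None:
        if self.wave not in WAVES:
            raise ValidationError(f"unknown wave {self.wave!r}")
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if self.end_min <= self.start_min:
            raise ValidationError(
                f"episode interval [{self.start_min}, {self.end_min}) must have positive duration"
            )
        if not self.activities:
            raise ValidationError("episode must list at least one activity")
        for code in self.activities:
            if not is_known_activity(code):
                raise ValidationError(f"unknown activity code {code!r}")

    @property
    def duration(self) -> int:
        return self.end_min - self.start_min


@dataclass(frozen=True)
class SegmentReport:
    """One coarse part-of-day affect block (set D): no durations."""

    respondent_id: str
    wave: str
    period: str
    activities: frozenset[str]
    companions: frozenset[str]
    ratings: AffectRatings | None

    def __post_init__(self) -> None:
        if self.wave not in WAVES:
            raise ValidationError(f"unknown wave {self.wave!r}")
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        for code in self.activities:
            if not is_known_activity(code):
                raise ValidationError(f"unknown activity code {code!r}")


@dataclass
class RespondentWave:
    """One respondent's report for one wave under one set assignment."""

    respondent_id: str
    wave: str
    set_assignment: str
    episodes: list[EpisodeRecord] = field(default_factory=list)
    segments: list[SegmentReport] = field(default_factory=list)
    demographics: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if self.set_assignment not in ALL_SETS:
            raise ValidationError(f"unknown set {self.set_assignment!r}")
        if self.episodes and self.segments:
            raise ValidationError("a wave may not mix episode and segment reports")
        if self.set_assignment == "D" and self.episodes:
            raise ValidationError("set D waves carry segments, not episodes")
        if self.set_assignment in EPISODE_SETS and self.segments:
            raise ValidationError(f"set {self.set_assignment} waves carry episodes, not segments")
        if self.set_assignment in SET_PERIOD:
            expect = SET_PERIOD[self.set_assignment]
            for ep in self.episodes:
                if ep.period != expect:
                    raise ValidationError(
                        f"set {self.set_assignment} episode in period {ep.period!r}; expected {expect!r}"
                    )


@dataclass(frozen=True)
class AffectSummary:
    """Duration-weighted (or, for set D, raw) affect summary for one wave."""

    pa: float
    na: float
    net: float
    u_index: float | None
    total_minutes: float | None
    n_scored: int
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# episode-level scoring


def _as_ratings(ratings: AffectRatings | Mapping[str, int]) -> AffectRatings:
    if isinstance(ratings, AffectRatings):
        return ratings
    return AffectRatings(**{item: ratings[item] for item in RATING_ITEMS})


def episode_positive_affect(ratings: AffectRatings | Mapping[str, int]) -> float:
    """Positive affect: mean of calm/relaxed and enjoyment."""
    r = _as_ratings(ratings)
    return float(np.mean(r.positives()))


def episode_negative_affect(ratings: AffectRatings | Mapping[str, int]) -> float:
    """Negative affect: mean of the five negative items."""
    r = _as_ratings(ratings)
    return float(np.mean(r.negatives()))


def episode_net_affect(ratings: AffectRatings | Mapping[str, int]) -> float:
    """Net affect = positive affect − negative affect, in [−2, 2]."""
    r = _as_ratings(ratings)
    return episode_positive_affect(r) - episode_negative_affect(r)


def episode_is_unpleasant(ratings: AffectRatings | Mapping[str, int]) -> bool:
    """True when the highest-rated feeling is a negative one.

    Ties between the strongest negative and strongest positive item count
    as *not* unpleasant (strict inequality).
    """
    r = _as_ratings(ratings)
    return max(r.negatives()) > max(r.positives())


def enumerate_net_affect_range() -> tuple[float, float, int]:
    """Exhaustively enumerate all 3^7 rating combinations.

    Returns (min net affect, max net affect, number of combinations).
    """
    lo, hi = np.inf, -np.inf
    count = 0
    for combo in itertools.product((1, 2, 3), repeat=len(RATING_ITEMS)):
        ratings = AffectRatings(**dict(zip(RATING_ITEMS, combo)))
        net = episode_net_affect(ratings)
        lo = min(lo, net)
        hi = max(hi, net)
        count += 1
    return float(lo), float(hi), count


# ---------------------------------------------------------------------------
# wave-level scoring


def score_wave(wave: RespondentWave) -> AffectSummary:
    """Score one respondent-wave into an :class:`AffectSummary`.

    Episode-based sets (A/B/C/FULL) are duration-weighted and carry a
    U-index; set D is the unweighted mean over segments with no U-index.
    Reports with a missing ratings block are dropped with a warning.
    """
    if wave.set_assignment == "D":
        reports: Sequence = wave.segments
    else:
        reports = wave.episodes
    if not reports:
        raise ValidationError(f"wave {wave.respondent_id}/{wave.wave} has no reports to score")

    complete = [rep for rep in reports if rep.ratings is not None]
    dropped = len(reports) - len(complete)
    if dropped:
        logger.warning(
            "respondent %s wave %s: dropped %d of %d reports with incomplete ratings",
            wave.respondent_id, wave.wave, dropped, len(reports),
        )
    if not complete:
        raise ValidationError(
            f"wave {wave.respondent_id}/{wave.wave} has no complete ratings blocks"
        )

    pa = np.array([episode_positive_affect(rep.ratings) for rep in complete])
    na = np.array([episode_negative_affect(rep.ratings) for rep in complete])

    if wave.set_assignment == "D":
        return AffectSummary(
            pa=float(pa.mean()), na=float(na.mean()), net=float((pa - na).mean()),
            u_index=None, total_minutes=None, n_scored=len(complete), n_dropped=dropped,
        )

    minutes = np.array([rep.duration for rep in complete], dtype=float)
    total = minutes.sum()
    unpleasant = np.array([episode_is_unpleasant(rep.ratings) for rep in complete])
    return AffectSummary(
        pa=float(np.average(pa, weights=minutes)),
        na=float(np.average(na, weights=minutes)),
        net=float(np.average(pa - na, weights=minutes)),
        u_index=float(minutes[unpleasant].sum() / total),
        total_minutes=float(total),
        n_scored=len(complete),
        n_dropped=dropped,
    )


def _period_of_minute(minute: float) -> str:
    if minute < NOON_MIN:
        return "morning"
    if minute < EVENING_MIN:
        return "afternoon"
    return "evening"


def _split_episode(ep: EpisodeRecord) -> list[EpisodeRecord]:
    """Split an episode at the noon/18:00 boundaries, prorating durations."""
    cuts = [b for b in (NOON_MIN, EVENING_MIN) if ep.start_min < b < ep.end_min]
    if not cuts:
        period = _period_of_minute(ep.start_min)
        if ep.period == period:
            return [ep]
        return [replace(ep, period=period)]
    bounds = [ep.start_min, *cuts, ep.end_min]
    return [
        replace(ep, start_min=a, end_min=b, period=_period_of_minute(a))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def slice_full_wave(wave: RespondentWave, period: str) -> RespondentWave:
    """Restrict a FULL wave to one part of the day.

    Episodes straddling a period boundary are split and their durations
    prorated, so slices of a full day partition its reported time.  The
    result may be empty (no episodes in the requested period); callers
    exclude empty slices from paired analyses.
    """
    if wave.set_assignment != "FULL":
        raise ValidationError("slice_full_wave applies to FULL waves only")
    if period not in PERIODS:
        raise ValidationError(f"unknown period {period!r}")
    pieces = [p for ep in wave.episodes for p in _split_episode(ep) if p.period == period]
    return RespondentWave(
        respondent_id=wave.respondent_id,
        wave=wave.wave,
        set_assignment="FULL",
        episodes=pieces,
        demographics=wave.demographics,
    )


# ---------------------------------------------------------------------------
# study container and vectorized scoring


@dataclass
class Study:
    """In-memory DRM study: episode, segment and respondent tables.

    ``episodes`` and ``segments`` hold one row per report with the seven
    rating columns; ``respondents`` holds demographics and the test-wave
    set assignment.  Activities/companions are semicolon-joined codes.
    """

    episodes: pd.DataFrame
    segments: pd.DataFrame
    respondents: pd.DataFrame

    def copy(self) -> "Study":
        return Study(self.episodes.copy(), self.segments.copy(), self.respondents.copy())


def _check_ratings_frame(df: pd.DataFrame, name: str) -> None:
    for item in RATING_ITEMS:
        col = df[item]
        bad = col.dropna()[~col.dropna().isin([1, 2, 3])]
        if len(bad):
            row = int(bad.index[0])
            raise ValidationError(
                f"{name} row {row}: rating {item!r} = {bad.iloc[0]!r} outside {{1, 2, 3}}"
            )


def _check_activities(df: pd.DataFrame, name: str, allow_empty: bool = False) -> None:
    for row, joined in df["activities"].items():
        if pd.isna(joined) or joined == "":
            if allow_empty:
                continue
            raise ValidationError(f"{name} row {row}: empty activity list")
        for code in str(joined).split(";"):
            if not is_known_activity(code):
                raise ValidationError(f"{name} row {row}: unknown activity code {code!r}")


def validate_study(study: Study) -> None:
    """Validate study tables; raises :class:`ValidationError` citing rows."""
    ep = study.episodes
    if len(ep):
        missing = [c for c in EPISODE_COLUMNS if c not in ep.columns]
        if missing:
            raise ValidationError(f"episodes table missing columns {missing}")
        bad_wave = ep.loc[~ep["wave"].isin(WAVES)]
        if len(bad_wave):
            raise ValidationError(f"episodes row {bad_wave.index[0]}: unknown wave")
        bad_set = ep.loc[~ep["set"].isin(EPISODE_SETS)]
        if len(bad_set):
            raise ValidationError(f"episodes row {bad_set.index[0]}: set must be A/B/C/FULL")
        bad_iv = ep.loc[ep["end_min"] <= ep["start_min"]]
        if len(bad_iv):
            raise ValidationError(
                f"episodes row {bad_iv.index[0]}: malformed interval "
                f"[{bad_iv['start_min'].iloc[0]}, {bad_iv['end_min'].iloc[0]})"
            )
        dup = ep.duplicated(subset=["respondent_id", "wave", "start_min"], keep=False)
        if dup.any():
            raise ValidationError(
                f"episodes row {ep.index[dup][1]}: duplicate (respondent, wave, start) key"
            )
        _check_ratings_frame(ep, "episodes")
        _check_activities(ep, "episodes")
    seg = study.segments
    if len(seg):
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise ValidationError(f"segments table missing columns {missing}")
        dup = seg.duplicated(subset=["respondent_id", "wave", "period"], keep=False)
        if dup.any():
            raise ValidationError(
                f"segments row {seg.index[dup][1]}: more than one segment per "
                "(respondent, wave, period)"
            )
        _check_ratings_frame(seg, "segments")
        _check_activities(seg, "segments", allow_empty=True)
    resp = study.respondents
    if resp["respondent_id"].duplicated().any():
        raise ValidationError("respondents table has duplicate respondent ids")


def _frame_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Attach pa/na/net/unpleasant columns computed from the rating columns."""
    out = df.copy()
    neg = out[list(NEGATIVE_ITEMS)].to_numpy(dtype=float)
    pos = out[list(POSITIVE_ITEMS)].to_numpy(dtype=float)
    out["pa"] = pos.mean(axis=1)
    out["na"] = neg.mean(axis=1)
    out["net"] = out["pa"] - out["na"]
    out["unpleasant"] = neg.max(axis=1) > pos.max(axis=1)
    return out


def drop_incomplete(df: pd.DataFrame, name: str = "episodes") -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing rating; returns (kept, n_dropped)."""
    complete = df[list(RATING_ITEMS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with incomplete ratings", name, n_dropped)
    return df.loc[complete], n_dropped


def score_episode_frame(episodes: pd.DataFrame) -> pd.DataFrame:
    """Duration-weighted summaries per (respondent, wave) from an episode table.

    Returns one row per respondent-wave with pa, na, net, u_index and
    total_min.  Rows with incomplete ratings are dropped first.
    """
    kept, _ = drop_incomplete(episodes)
    if not len(kept):
        return pd.DataFrame(
            columns=["respondent_id", "wave", "set", "pa", "na", "net", "u_index", "total_min"]
        )
    sc = _frame_scores(kept)
    sc["dur"] = (sc["end_min"] - sc["start_min"]).astype(float)
    for col in ("pa", "na", "net"):
        sc[f"w_{col}"] = sc[col] * sc["dur"]
    sc["w_unpl"] = sc["unpleasant"] * sc["dur"]
    g = sc.groupby(["respondent_id", "wave", "set"], sort=True).agg(
        total_min=("dur", "sum"),
        w_pa=("w_pa", "sum"),
        w_na=("w_na", "sum"),
        w_net=("w_net", "sum"),
        w_unpl=("w_unpl", "sum"),
    )
    out = pd.DataFrame(
        {
            "pa": g["w_pa"] / g["total_min"],
            "na": g["w_na"] / g["total_min"],
            "net": g["w_net"] / g["total_min"],
            "u_index": g["w_unpl"] / g["total_min"],
            "total_min": g["total_min"],
        }
    ).reset_index()
    return out


def score_segment_frame(segments: pd.DataFrame) -> pd.DataFrame:
    """Unweighted (raw) summaries per (respondent, wave) for set D segments."""
    kept, _ = drop_incomplete(segments, "segments")
    if not len(kept):
        return pd.DataFrame(columns=["respondent_id", "wave", "set", "pa", "na", "net", "u_index"])
    sc = _frame_scores(kept)
    g = sc.groupby(["respondent_id", "wave"], sort=True)[["pa", "na", "net"]].mean()
    out = g.reset_index()
    out.insert(2, "set", "D")
    out["u_index"] = np.nan
    out["total_min"] = np.nan
    return out


def split_full_frame(episodes: pd.DataFrame) -> pd.DataFrame:
    """Split episode rows at the noon/18:00 boundaries (vectorized).

    Returns a table whose rows each lie entirely within one period, with
    the ``period`` column recomputed.  Used to slice FULL-day records.
    """
    parts = []
    df = episodes
    for lo, hi, period in (
        (None, NOON_MIN, "morning"),
        (NOON_MIN, EVENING_MIN, "afternoon"),
        (EVENING_MIN, None, "evening"),
    ):
        start = df["start_min"].clip(lower=lo) if lo is not None else df["start_min"]
        end = df["end_min"].clip(upper=hi) if hi is not None else df["end_min"]
        keep = end > start
        piece = df.loc[keep].copy()
        piece["start_min"] = start[keep]
        piece["end_min"] = end[keep]
        piece["period"] = period
        parts.append(piece)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_study(study: Study, path: str | Path) -> None:
    """Write episodes.csv / segments.csv / respondents.csv into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ep = study.episodes.reindex(columns=EPISODE_COLUMNS)
    seg = study.segments.reindex(columns=SEGMENT_COLUMNS)
    resp = study.respondents.reindex(columns=RESPONDENT_COLUMNS)
    ep.to_csv(path / "episodes.csv", index=False, lineterminator="\n")
    seg.to_csv(path / "segments.csv", index=False, lineterminator="\n")
    resp.to_csv(path / "respondents.csv", index=False, lineterminator="\n")


_RATING_DTYPES = {item: "Int64" for item in RATING_ITEMS}


def read_study(path: str | Path, validate: bool = True) -> Study:
    """Read a study directory written by :func:`write_study`.

    Tolerates CRLF line endings and quoted activity lists (standard CSV
    dialect handling).  Raises :class:`ValidationError` on malformed rows.
    """
    path = Path(path)
    episodes = pd.read_csv(path / "episodes.csv", dtype={"respondent_id": str, **_RATING_DTYPES})
    segments = pd.read_csv(path / "segments.csv", dtype={"respondent_id": str, **_RATING_DTYPES})
    respondents = pd.read_csv(path / "respondents.csv", dtype={"respondent_id": str})
    for df in (episodes, segments):
        for col in ("activities", "companions"):
            if col in df.columns:
                df[col] = df[col].fillna("")
    study = Study(episodes, segments, respondents)
    if validate:
        validate_study(study)
    return study


# ---------------------------------------------------------------------------
# object/frame bridging helpers (typed API over the tabular store)


def wave_from_frames(study: Study, respondent_id: str, wave: str) -> RespondentWave:
    """Materialize one respondent-wave as typed records."""
    resp = study.respondents.set_index("respondent_id")
    demo = resp.loc[respondent_id].to_dict() if respondent_id in resp.index else None
    ep_rows = study.episodes.query("respondent_id == @respondent_id and wave == @wave")
    if len(ep_rows):
        set_assignment = ep_rows["set"].iloc[0]
        episodes = [
            EpisodeRecord(
                respondent_id=respondent_id,
                wave=wave,
                period=row.period,
                start_min=int(row.start_min),
                end_min=int(row.end_min),
                activities=frozenset(str(row.activities).split(";")),
                companions=frozenset(
                    c for c in str(row.companions).split(";") if c
                ),
                ratings=_row_ratings(row),
            )
            for row in ep_rows.itertuples()
        ]
        return RespondentWave(respondent_id, wave, set_assignment, episodes=episodes,
                              demographics=demo)
    seg_rows = study.segments.query("respondent_id == @respondent_id and wave == @wave")
    if not len(seg_rows):
        raise ValidationError(f"no records for respondent {respondent_id!r} wave {wave!r}")
    segments = [
        SegmentReport(
            respondent_id=respondent_id,
            wave=wave,
            period=row.period,
            activities=frozenset(a for a in str(row.activities).split(";") if a),
            companions=frozenset(c for c in str(row.companions).split(";") if c),
            ratings=_row_ratings(row),
        )
        for row in seg_rows.itertuples()
    ]
    return RespondentWave(respondent_id, wave, "D", segments=segments, demographics=demo)


def _row_ratings(row) -> AffectRatings | None:
    values = {item: getattr(row, item) for item in RATING_ITEMS}
    if any(pd.isna(v) for v in values.values()):
        return None
    return AffectRatings(**{k: int(v) for k, v in values.items()})
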