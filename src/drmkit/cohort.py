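"""Synthetic abbreviated-DRM cohort generator with known ground truth.

Emulates the validation study design: every respondent is randomized to
one short set (A/B/C/D) at the test wave and re-interviewed with the
FULL day instrument one week later, with a small number of retest
dropouts.  Affect is generated from a latent Gaussian model,

    latent = mu0 + x'beta + trait_i + wave_noise_iw
             + activity_offset + episode_noise,

where ``trait`` is the stable between-person component (variance
``sigma2_between``) and ``wave_noise`` the day-to-day component
(variance ``sigma2_within``).  The seven 1..3 item ratings are produced
by thresholding the latent value plus item-specific noise: positive
items increase with latent affect, negative items decrease.  The
default thresholds are calibrated so the marginal positive/negative
affect means sit near 2.2 and 1.15, the levels typical of this
population; they live in the config, not in code.

Demographic marginals default to the study population (53% female,
mean age 57, half with no formal education, 56% urban, uniform income
quintiles), and activity reporting weights and affect offsets come from
the versioned activity catalog.

Supplementary questions use a stable-answer/flip model: each respondent
holds a stable true answer, and the answer recorded at each wave
independently flips with an item-specific probability (3-point items
move to one of the other categories uniformly).  The symmetric per-wave
noise keeps the waves exchangeable, as the Delta model assumes; for a
balanced binary item the downstream kappa is (1 - 2*flip)^2.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import load_catalog
from .core import RATING_ITEMS, NEGATIVE_ITEMS, POSITIVE_ITEMS, Study, ValidationError

COMPANION_CODES = ("alone", "spouse", "family", "friends", "coworkers")
COMPANION_WEIGHTS = (0.25, 0.2, 0.35, 0.12, 0.08)

#: education levels (index = education_raw); first two code education01 = 0
EDUCATION_PROBS = (0.509, 0.068, 0.149, 0.096, 0.050, 0.077, 0.051)

DEFAULT_BETAS = {
    "sex": 0.25,
    "income01": 0.45,
    "setting01": 0.25,
    "education01": 0.30,
    "age": -0.002,
    "education01:sex": -0.40,
    "income01:sex": -0.40,
}

#: (name, prevalence of "yes", per-wave flip probability) for the
#: dichotomous day-feeling questions; names beyond the instrument's
#: published examples are artifact-defined.
DEFAULT_BINARY_ITEMS = (
    ("worried", 0.35, 0.10),
    ("sleepy", 0.45, 0.08),
    ("bored", 0.30, 0.08),
    ("smiled", 0.75, 0.10),
    ("physical_pain", 0.40, 0.10),
    ("headache", 0.30, 0.09),
    ("calm", 0.70, 0.06),
    ("stressed", 0.25, 0.06),
    ("angry", 0.20, 0.06),
    ("depressed", 0.15, 0.05),
    ("enjoyed_life", 0.72, 0.06),
    ("well_rested", 0.60, 0.07),
    ("lonely", 0.18, 0.05),
    ("energetic", 0.55, 0.07),
)

#: (name, category probabilities for worse/same/better, per-wave flip)
DEFAULT_TRIPLE_ITEMS = (
    ("mood_vs_others", (0.20, 0.50, 0.30), 0.05),
    ("anxiety_vs_others", (0.20, 0.55, 0.25), 0.04),
)


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic abbreviated-DRM study."""

    n_respondents: int = 1560
    seed: int = 0

    # design
    set_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    dropout_rate: float = 22 / 1560

    # demographics
    p_female: float = 0.531
    age_mean: float = 57.1
    age_sd: float = 17.6
    age_range: tuple = (18, 95)
    education_probs: tuple = EDUCATION_PROBS
    p_urban: float = 0.556
    p_married: float = 0.731

    # latent affect model
    mu0: float = 0.0
    sigma2_between: float = 0.25
    sigma2_within: float = 0.25
    sigma2_episode: float = 0.30
    sigma2_item: float = 0.50
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    # latent offsets are attenuated ~0.6x by item thresholding; 1.6 makes
    # the observed per-activity mean spread match the catalog's offsets
    activity_offset_scale: float = 1.6
    activity_offsets: dict = field(default_factory=dict)  # per-code overrides

    # thresholds on (latent + item noise); positive items increasing,
    # negative items decreasing in latent affect
    pos_cuts: tuple = (-0.98, 1.14)
    neg_cuts: tuple = (0.98, 1.25)

    # episode model
    episodes_per_period: tuple = (2, 4)
    min_episode_min: int = 5
    p_second_activity: float = 0.12
    # daily routine: each respondent keeps a stable set of habitual
    # activities drawn once and reused in both waves, reproducing the
    # above-independence test/retest reporter overlap seen in real data
    habit_k: int = 4
    habit_prob: float = 0.5
    wake_mean: float = 360.0
    wake_sd: float = 30.0
    sleep_mean: float = 1350.0
    sleep_sd: float = 45.0

    # supplementary questions
    binary_items: tuple = DEFAULT_BINARY_ITEMS
    triple_items: tuple = DEFAULT_TRIPLE_ITEMS

    def validate(self) -> None:
        if self.n_respondents < 1:
            raise ValidationError("n_respondents must be positive")
        probs = np.asarray(self.set_probs, dtype=float)
        if len(probs) != 4 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("set_probs must be 4 non-negative values summing to 1")
        for name in ("dropout_rate", "p_female", "p_urban", "p_married",
                     "activity_offset_scale"):
            v = getattr(self, name)
            if not 0 <= v <= 1 and name != "activity_offset_scale":
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma2_between", "sigma2_within", "sigma2_episode", "sigma2_item"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        lo, hi = self.episodes_per_period
        if not (1 <= lo <= hi):
            raise ValidationError("episodes_per_period must be an increasing pair >= 1")
        unknown = [c for c in self.activity_offsets if c not in load_catalog()]
        if unknown:
            raise ValidationError(f"activity_offsets for unknown codes: {unknown}")
        for _, prev, flip in self.binary_items:
            if not (0 <= prev <= 1 and 0 <= flip <= 1):
                raise ValidationError("binary item probabilities must be in [0, 1]")
        for _, cat_probs, flip in self.triple_items:
            p = np.asarray(cat_probs, dtype=float)
            if len(p) != 3 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValidationError("3-point item probabilities must be a simplex of 3")
            if not 0 <= flip <= 1:
                raise ValidationError("flip probability must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["betas"] = dict(self.betas)
        return d


@dataclass
class SimulatedStudy:
    """A generated study plus the latent ground truth that produced it."""

    study: Study
    supplementary: pd.DataFrame
    ground_truth: dict


# ---------------------------------------------------------------------------
# helpers


def _demographics(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_respondents
    width = max(5, len(str(n)))
    ids = np.array([f"R{i:0{width}d}" for i in range(1, n + 1)])
    sex = (rng.random(n) >= cfg.p_female).astype(int)  # 1 = male
    age = np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd, n)), *cfg.age_range).astype(int)
    edu_probs = np.asarray(cfg.education_probs, dtype=float)
    edu_probs = edu_probs / edu_probs.sum()
    education_raw = rng.choice(len(edu_probs), size=n, p=edu_probs)
    education01 = (education_raw >= 2).astype(int)
    marital = np.where(rng.random(n) < cfg.p_married, "married", "other")
    setting01 = (rng.random(n) < cfg.p_urban).astype(int)
    income_quintile = rng.integers(1, 6, size=n)
    income01 = (income_quintile >= 3).astype(int)
    set_assignment = rng.choice(list("ABCD"), size=n, p=np.asarray(cfg.set_probs))
    return pd.DataFrame(
        {
            "respondent_id": ids,
            "sex": sex,
            "age": age,
            "education_raw": education_raw,
            "education01": education01,
            "marital": marital,
            "setting01": setting01,
            "income_quintile": income_quintile,
            "income01": income01,
            "set_assignment": set_assignment,
        }
    )


def _linear_predictor(cfg: CohortConfig, demo: pd.DataFrame) -> np.ndarray:
    xb = np.zeros(len(demo))
    for term, beta in cfg.betas.items():
        if beta == 0:
            continue
        if ":" in term:
            a, b = term.split(":")
            xb += beta * demo[a].to_numpy(float) * demo[b].to_numpy(float)
        elif term == "age":
            xb += beta * (demo["age"].to_numpy(float) - cfg.age_mean)
        else:
            xb += beta * demo[term].to_numpy(float)
    return xb


_PERIOD_BOUNDS = {"morning": (None, 720), "afternoon": (720, 1080), "evening": (1080, None)}


def _draw_ratings(cfg: CohortConfig, latent: np.ndarray, rng: np.random.Generator) -> dict:
    """Threshold latent affect (+ item noise) into the seven 1..3 items."""
    sd = np.sqrt(cfg.sigma2_item)
    cols = {}
    for item in NEGATIVE_ITEMS:
        z = -latent + rng.normal(0.0, sd, size=len(latent))
        cols[item] = 1 + (z > cfg.neg_cuts[0]).astype(int) + (z > cfg.neg_cuts[1]).astype(int)
    for item in POSITIVE_ITEMS:
        z = latent + rng.normal(0.0, sd, size=len(latent))
        cols[item] = 1 + (z > cfg.pos_cuts[0]).astype(int) + (z > cfg.pos_cuts[1]).astype(int)
    return cols


def _habitual_sets(cfg: CohortConfig, rng: np.random.Generator,
                   n: int, weights: np.ndarray) -> np.ndarray:
    """Per-respondent habitual activities: weighted top-k without
    replacement via the Gumbel-max trick."""
    scores = np.log(weights)[None, :] + rng.gumbel(size=(n, len(weights)))
    return np.argsort(-scores, axis=1)[:, : cfg.habit_k]


def _draw_activities(cfg: CohortConfig, rng: np.random.Generator,
                     resp: np.ndarray, habitual: np.ndarray,
                     codes: np.ndarray, weights: np.ndarray,
                     offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Activity code strings (possibly two, ';'-joined) and mean offsets."""
    n = len(resp)
    from_habit = rng.random(n) < cfg.habit_prob
    habit_pick = habitual[resp, rng.integers(0, habitual.shape[1], size=n)]
    global_pick = rng.choice(len(codes), size=n, p=weights)
    first = np.where(from_habit, habit_pick, global_pick)
    second = rng.choice(len(codes), size=n, p=weights)
    has_second = (rng.random(n) < cfg.p_second_activity) & (second != first)
    joined = np.where(
        has_second,
        np.char.add(np.char.add(codes[first], ";"), codes[second]),
        codes[first],
    )
    offset = np.where(has_second, (offsets[first] + offsets[second]) / 2.0, offsets[first])
    return joined, offset * cfg.activity_offset_scale


def _episode_block(
    cfg: CohortConfig,
    rng: np.random.Generator,
    resp_idx: np.ndarray,
    periods: np.ndarray,
    win_start: np.ndarray,
    win_end: np.ndarray,
    base_latent: np.ndarray,
    habitual: np.ndarray,
    codes: np.ndarray,
    weights: np.ndarray,
    offsets: np.ndarray,
) -> dict:
    """Generate episodes for a batch of (respondent, period) windows.

    Episode minute durations are a fixed minimum plus a multinomial
    split of the remaining window, so episodes exactly tile each window.
    """
    m = len(resp_idx)
    lo, hi = cfg.episodes_per_period
    k = rng.integers(lo, hi + 1, size=m)
    kmax = hi
    span = (win_end - win_start).astype(int)
    extra = span - cfg.min_episode_min * k

    shares = rng.gamma(2.0, 1.0, size=(m, kmax))
    mask = np.arange(kmax)[None, :] < k[:, None]
    shares = np.where(mask, shares, 0.0)
    shares /= shares.sum(axis=1, keepdims=True)
    counts = rng.multinomial(extra, shares)
    durations = np.where(mask, counts + cfg.min_episode_min, 0)

    ends_mat = win_start[:, None] + np.cumsum(durations, axis=1)
    starts_mat = ends_mat - durations

    flat = mask.ravel()
    row = np.repeat(np.arange(m), kmax)[flat]
    resp = resp_idx[row]
    n_ep = len(row)
    act, act_offset = _draw_activities(cfg, rng, resp, habitual, codes, weights, offsets)
    latent = (
        base_latent[resp]
        + act_offset
        + rng.normal(0.0, np.sqrt(cfg.sigma2_episode), size=n_ep)
    )
    companions = rng.choice(COMPANION_CODES, size=n_ep, p=COMPANION_WEIGHTS)
    block = {
        "resp_idx": resp,
        "period": periods[row],
        "start_min": starts_mat.ravel()[flat].astype(int),
        "end_min": ends_mat.ravel()[flat].astype(int),
        "activities": act,
        "companions": companions,
    }
    block.update(_draw_ratings(cfg, latent, rng))
    return block


# ---------------------------------------------------------------------------
# main entry points


def generate_study(config: CohortConfig, waves: tuple = ("test", "retest")) -> SimulatedStudy:
    """Generate a full synthetic study (deterministic given config.seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    demo = _demographics(config, rng)
    ids = demo["respondent_id"].to_numpy()
    xb = _linear_predictor(config, demo)
    trait = rng.normal(0.0, np.sqrt(config.sigma2_between), size=n)

    catalog = load_catalog()
    codes = np.array(list(catalog))
    weights = np.array([e.weight_pct for e in catalog.values()], dtype=float)
    weights = weights / weights.sum()
    offsets = np.array(
        [config.activity_offsets.get(c, e.net_offset) for c, e in catalog.items()],
        dtype=float,
    )

    habitual = _habitual_sets(config, rng, n, weights)
    n_dropout = int(round(config.dropout_rate * n))
    dropouts = set(rng.choice(n, size=n_dropout, replace=False).tolist()) if n_dropout else set()

    sets = demo["set_assignment"].to_numpy()
    episode_frames = []
    segment_frames = []

    for wave in waves:
        wave_noise = rng.normal(0.0, np.sqrt(config.sigma2_within), size=n)
        base = config.mu0 + xb + trait + wave_noise
        wake = np.clip(
            np.round(rng.normal(config.wake_mean, config.wake_sd, size=n)), 240, 600
        ).astype(int)
        sleep = np.clip(
            np.round(rng.normal(config.sleep_mean, config.sleep_sd, size=n)), 1140, 1439
        ).astype(int)

        if wave == "test":
            active = np.arange(n)
            wave_sets = sets
        else:
            active = np.array([i for i in range(n) if i not in dropouts], dtype=int)
            wave_sets = np.full(n, "FULL")

        # episode-based records
        period_set = {"morning": "A", "afternoon": "B", "evening": "C"}
        windows_idx, windows_period, w_start, w_end = [], [], [], []
        for period, (b_lo, b_hi) in _PERIOD_BOUNDS.items():
            if wave == "test":
                in_scope = active[sets[active] == period_set[period]]
            else:
                in_scope = active
            if not len(in_scope):
                continue
            start = wake[in_scope] if b_lo is None else np.full(len(in_scope), b_lo)
            end = sleep[in_scope] if b_hi is None else np.full(len(in_scope), b_hi)
            windows_idx.append(in_scope)
            windows_period.append(np.full(len(in_scope), period))
            w_start.append(start)
            w_end.append(end)
        if windows_idx:
            resp_idx = np.concatenate(windows_idx)
            block = _episode_block(
                config, rng, resp_idx, np.concatenate(windows_period),
                np.concatenate(w_start), np.concatenate(w_end),
                base, habitual, codes, weights, offsets,
            )
            frame = pd.DataFrame(block)
            ridx = frame.pop("resp_idx").to_numpy()
            frame.insert(0, "respondent_id", ids[ridx])
            frame.insert(1, "wave", wave)
            frame.insert(2, "set", wave_sets[ridx])
            episode_frames.append(frame)

        # segment-based records (set D, test wave only)
        if wave == "test":
            d_idx = active[sets[active] == "D"]
            if len(d_idx):
                rep = np.repeat(d_idx, 3)
                seg_period = np.tile(np.array(list(_PERIOD_BOUNDS)), len(d_idx))
                act, act_offset = _draw_activities(
                    config, rng, rep, habitual, codes, weights, offsets
                )
                latent = (
                    base[rep] + act_offset
                    + rng.normal(0.0, np.sqrt(config.sigma2_episode), size=len(rep))
                )
                seg = {
                    "respondent_id": ids[rep],
                    "wave": wave,
                    "period": seg_period,
                    "activities": act,
                    "companions": rng.choice(COMPANION_CODES, size=len(rep),
                                             p=COMPANION_WEIGHTS),
                }
                seg.update(_draw_ratings(config, latent, rng))
                segment_frames.append(pd.DataFrame(seg))

    episodes = (
        pd.concat(episode_frames, ignore_index=True)
        if episode_frames
        else pd.DataFrame(columns=["respondent_id", "wave", "set", "period",
                                   "start_min", "end_min", "activities",
                                   "companions", *RATING_ITEMS])
    )
    segments = (
        pd.concat(segment_frames, ignore_index=True)
        if segment_frames
        else pd.DataFrame(columns=["respondent_id", "wave", "period", "activities",
                                   "companions", *RATING_ITEMS])
    )

    supplementary = generate_supplementary(config, rng=rng, ids=ids, dropouts=dropouts)

    ground_truth = {
        "config": config.to_dict(),
        "trait": dict(zip(ids.tolist(), trait.tolist())),
        "linear_predictor": dict(zip(ids.tolist(), xb.tolist())),
        "dropout_ids": sorted(ids[i] for i in dropouts),
    }
    study = Study(episodes=episodes, segments=segments, respondents=demo)
    return SimulatedStudy(study=study, supplementary=supplementary, ground_truth=ground_truth)


def generate_supplementary(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    ids: np.ndarray | None = None,
    dropouts: set | None = None,
) -> pd.DataFrame:
    """Generate test/retest supplementary answers (long format).

    Each respondent holds a stable true answer (drawn with the item's
    prevalence); the answer recorded at *each* wave independently flips
    with the item's flip probability (for 3-point items, moves to one
    of the other two categories uniformly).  Symmetric per-wave noise
    keeps the two waves exchangeable — margins agree and the expected
    agreement table is symmetric, as the Delta model assumes.  For a
    balanced binary item the downstream kappa is (1 - 2*flip)^2 in
    expectation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_respondents
    if ids is None:
        width = max(5, len(str(n)))
        ids = np.array([f"R{i:0{width}d}" for i in range(1, n + 1)])
    dropouts = dropouts or set()
    drop_mask = np.zeros(n, dtype=bool)
    for i in dropouts:
        drop_mask[i] = True

    frames = []
    for name, prevalence, flip in config.binary_items:
        true = (rng.random(n) < prevalence).astype(int)
        test = np.where(rng.random(n) < flip, 1 - true, true)
        retest = np.where(rng.random(n) < flip, 1 - true, true).astype(float)
        retest[drop_mask] = np.nan
        frames.append(pd.DataFrame({
            "respondent_id": ids, "item": name, "kind": "binary",
            "test": test.astype(float), "retest": retest,
        }))
    for name, cat_probs, flip in config.triple_items:
        true = rng.choice(3, size=n, p=np.asarray(cat_probs, dtype=float))
        answers = []
        for _ in range(2):  # move to one of the other two categories
            shift = rng.integers(1, 3, size=n)
            answers.append(np.where(rng.random(n) < flip, (true + shift) % 3, true))
        test, retest = answers[0], answers[1].astype(float)
        retest[drop_mask] = np.nan
        frames.append(pd.DataFrame({
            "respondent_id": ids, "item": name, "kind": "triple",
            "test": test.astype(float), "retest": retest,
        }))
    return pd.concat(frames, ignore_index=True)
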