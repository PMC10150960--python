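"""Event representation: one labeled hypoglycemia episode -> 83 numeric features.

Each filtered episode is summarized by demographics, temporal encodings, the
PCHIP-interpolated blood-glucose trajectory in a 6-hour window around the
event, the nearest SMBG readings / insulin doses / carb intakes before and
after the event (doses and amounts centered on subject-specific 3-month
means), the most recent bolus-advisor record, 3-month summary statistics of
the glucose / insulin / carb series, and quiz-engagement statistics.

Missingness is explicit: a feature that cannot be computed (no advisor
record in the lookback, no prior hyperglycemic reading, ...) is NaN in the
output, and downstream consumers treat NaN as "missing", never as a number.

Time-of-day encodings: a single float in [0, 1] suffers a midnight boundary
artifact (23:55 vs 00:05), so the canonical vector instead carries the
absolute hour-offsets from noon (``cos_tod``) and from midnight
(``sin_tod``) — despite the trigonometric-looking names these are plain
absolute offsets, bounded by 12 h. The raw ``tod`` float is kept available
outside the canonical 83 for single-variable statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .diary import Diary, HypoEpisode, filter_label_episodes

__all__ = [
    "WindowConfig",
    "SubjectBaselines",
    "FEATURE_REGISTRY",
    "EXTRA_FEATURES",
    "represent_event",
    "featurize_cohort",
    "temporal_features",
    "interp_bg_features",
    "neighbor_bg_features",
    "intake_context_features",
    "advisor_features",
    "longterm_signal_stats",
    "quiz_engagement_features",
    "compute_baselines",
]

_EPOCH = datetime(1970, 1, 1)


def _hours(ts: datetime) -> float:
    return (ts - _EPOCH).total_seconds() / 3600.0


@dataclass(frozen=True)
class WindowConfig:
    """Windowing and threshold parameters for feature extraction."""

    interp_half_window_h: float = 3.0  # the 6-hour episode window is +/- 3 h
    longterm_window_days: float = 90.0  # "3 months"
    hyper_threshold: float = 10.0  # mmol/L, > is hyperglycemia (not defined
    # in the source analysis; configurable)
    target_low: float = 4.0  # in-target band [4, 10] mmol/L
    target_high: float = 10.0
    hypo_threshold: float = 4.0  # mmol/L, < is hypoglycemia
    advisor_lookback_h: float = 6.0
    resample_step_min: float = 5.0
    wake_cutoff_h: float = 4.5  # first reading "after 4:30"
    slope_max_gap_h: float = 6.0  # consecutive-reading slopes with larger
    # gaps are overnight artifacts and excluded

    def __post_init__(self) -> None:
        if self.interp_half_window_h <= 0:
            raise ValueError("interpolation half-window must be positive")
        if not (self.hypo_threshold <= self.target_low <= self.target_high <= self.hyper_threshold):
            raise ValueError("in-target band must lie between hypo and hyper thresholds")


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY_SPEC: list[tuple[str, str]] = (
    [(n, "demographics") for n in ("age", "gender", "y_w_diab")]
    + [(n, "temporal") for n in ("cos_tod", "sin_tod", "wake_up_offset", "is_bday")]
    + [
        (f"bgi_{n}", "interp_bg")
        for n in ("mean", "std", "range", "min", "max", "slope", "skew", "kurt")
    ]
    + [(f"pre_{n}", "neighbor_bg") for n in ("g_val", "g_offset", "H_offset", "h_offset", "t_offset")]
    + [(f"post_{n}", "neighbor_bg") for n in ("g_val", "g_offset", "H_offset", "h_offset", "t_offset")]
    + [(n, "qa_intake") for n in ("pre_ins_dosage", "pre_ins_offset", "post_ins_dosage", "post_ins_offset")]
    + [(n, "basal_intake") for n in ("pre_bas_dosage", "pre_bas_offset", "post_bas_dosage", "post_bas_offset")]
    + [(n, "food_intake") for n in ("pre_car_dosage", "pre_car_offset", "post_car_dosage", "post_car_offset")]
    + [
        (n, "advisor")
        for n in ("ba_food_ins", "ba_corr_ins", "ba_total_ins", "ba_diff", "ba_meal_rise", "ba_has_excercise")
    ]
    + [
        (f"glu_{n}", "longterm_bg")
        for n in ("mean", "std", "range", "max", "min", "mean_x", "skew", "kurt")
    ]
    + [(n, "longterm_bg") for n in ("neg_slopes_mean", "pos_slopes_mean")]
    + [
        (f"ins_{n}", "longterm_qa")
        for n in ("mean", "std", "range", "max", "min", "mean_x", "skew", "kurt")
    ]
    + [
        (f"bas_{n}", "longterm_basal")
        for n in ("mean", "std", "range", "max", "min", "mean_x", "skew", "kurt")
    ]
    + [
        (f"car_{n}", "longterm_carb")
        for n in ("mean", "std", "range", "max", "min", "mean_x", "skew", "kurt")
    ]
    + [
        (f"cnc_{n}", "quiz")
        for n in ("ansnum", "daysnum", "points_avg", "points_std", "dist_avg", "dist_std")
    ]
)

#: Canonical ordered names of the 83-slot event representation.
FEATURE_REGISTRY: list[str] = [name for name, _ in _REGISTRY_SPEC]
FEATURE_GROUPS: dict[str, str] = dict(_REGISTRY_SPEC)

assert len(FEATURE_REGISTRY) == 83, "canonical registry must have exactly 83 slots"
assert len(set(FEATURE_REGISTRY)) == 83

#: Features carried alongside but outside the canonical 83: the raw
#: single-float time of day, and three advisor settings that appear in the
#: single-variable analysis only.
EXTRA_FEATURES: list[str] = ["tod", "ba_iob", "ba_allowed_bgv", "ba_carb_cu"]

#: Advisor-derived columns (excluded from multiple regression/classification
#: designs to preserve sample size).
ADVISOR_FEATURES: list[str] = [
    "ba_food_ins", "ba_corr_ins", "ba_total_ins", "ba_diff",
    "ba_meal_rise", "ba_has_excercise", "ba_iob", "ba_allowed_bgv", "ba_carb_cu",
]


# ---------------------------------------------------------------------------
# Small statistical helpers (population-moment conventions)
# ---------------------------------------------------------------------------


def _moment_stats(x: np.ndarray) -> tuple[float, float, float, float]:
    """(population SD, skewness g1, excess kurtosis g2, range). Skew/kurt are
    NaN for constant samples (zero second moment)."""
    m = float(np.mean(x))
    d = x - m
    m2 = float(np.mean(d**2))
    sd = float(np.sqrt(m2))
    rng = float(np.max(x) - np.min(x))
    if m2 <= 0:
        return sd, np.nan, np.nan, rng
    g1 = float(np.mean(d**3) / m2**1.5)
    g2 = float(np.mean(d**4) / m2**2 - 3.0)
    return sd, g1, g2, rng


def _mean_crossing_rate(x: np.ndarray) -> float:
    """(# sign changes of consecutive x_t - mean) / (# samples)."""
    s = np.sign(x - np.mean(x))
    changes = int(np.sum(s[:-1] * s[1:] < 0))
    return changes / len(x)


# ---------------------------------------------------------------------------
# Cached array view of a diary
# ---------------------------------------------------------------------------


class _DiaryArrays:
    """Sorted numpy arrays of a diary's series, keyed on object identity."""

    def __init__(self, diary: Diary) -> None:
        self.read_t = np.array([_hours(r.timestamp) for r in diary.readings])
        self.read_v = np.array([r.value for r in diary.readings])
        self.qa_t = np.array([d.timestamp for d in diary.qa_doses], dtype="datetime64[s]").astype(float) / 3600.0 if diary.qa_doses else np.empty(0)
        self.qa_v = np.array([d.units for d in diary.qa_doses])
        self.bas_t = np.array([d.timestamp for d in diary.basal_doses], dtype="datetime64[s]").astype(float) / 3600.0 if diary.basal_doses else np.empty(0)
        self.bas_v = np.array([d.units for d in diary.basal_doses])
        self.car_t = np.array([c.timestamp for c in diary.carbs], dtype="datetime64[s]").astype(float) / 3600.0 if diary.carbs else np.empty(0)
        self.car_v = np.array([c.grams for c in diary.carbs])
        self.adv_t = np.array([_hours(a.timestamp) for a in diary.advisor_records])
        self.advisor_records = diary.advisor_records
        self.quiz_t = np.array([_hours(q.timestamp) for q in diary.quiz_answers])
        self.quiz_points = np.array([q.points for q in diary.quiz_answers])
        self.quiz_session = np.array([q.session_id for q in diary.quiz_answers])
        self.quiz_day = np.array([q.timestamp.date().toordinal() for q in diary.quiz_answers])


_ARRAY_CACHE: dict[int, tuple[Diary, _DiaryArrays]] = {}


def _arrays(diary: Diary) -> _DiaryArrays:
    key = id(diary)
    hit = _ARRAY_CACHE.get(key)
    if hit is not None and hit[0] is diary:
        return hit[1]
    arr = _DiaryArrays(diary)
    if len(_ARRAY_CACHE) > 128:
        _ARRAY_CACHE.clear()
    _ARRAY_CACHE[key] = (diary, arr)
    return arr


def _window(t: np.ndarray, lo: float, hi: float) -> slice:
    """Index slice of sorted times within [lo, hi)."""
    return slice(np.searchsorted(t, lo, "left"), np.searchsorted(t, hi, "left"))


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectBaselines:
    """Subject-specific 3-month means computed strictly before the episode."""

    qa_mean: float  # NaN if no QA dose in the window
    basal_mean: float
    carb_mean: float
    wake_median_h: float  # median time-of-day of each day's first reading >= 04:30


def compute_baselines(diary: Diary, t_event: datetime, config: WindowConfig = WindowConfig()) -> SubjectBaselines:
    a = _arrays(diary)
    te = _hours(t_event)
    lo = te - config.longterm_window_days * 24.0

    def mean_of(t: np.ndarray, v: np.ndarray) -> float:
        s = _window(t, lo, te)
        return float(np.mean(v[s])) if s.stop > s.start else np.nan

    # per-day first reading at/after 04:30 within the lookback
    s = _window(a.read_t, lo, te)
    wake = np.nan
    if s.stop > s.start:
        t = a.read_t[s]
        tod = t % 24.0
        ok = tod >= config.wake_cutoff_h
        if ok.any():
            days = np.floor(t[ok] / 24.0).astype(int)
            firsts = pd.Series(tod[ok]).groupby(days).min()
            wake = float(firsts.median())
    return SubjectBaselines(
        qa_mean=mean_of(a.qa_t, a.qa_v),
        basal_mean=mean_of(a.bas_t, a.bas_v),
        carb_mean=mean_of(a.car_t, a.car_v),
        wake_median_h=wake,
    )


# ---------------------------------------------------------------------------
# Feature groups
# ---------------------------------------------------------------------------


def temporal_features(
    episode: HypoEpisode, diary: Diary, baselines: SubjectBaselines, config: WindowConfig = WindowConfig()
) -> dict[str, float]:
    """tod (extra), cos_tod, sin_tod, wake_up_offset, is_bday.

    cos_tod = absolute hour-offset from noon; sin_tod = absolute hour-offset
    from midnight (both <= 12 h). wake_up_offset = episode-day first-reading
    time-of-day minus the subject's usual (90-day median) one; positive means
    the day started later than usual.
    """
    ts = episode.timestamp
    t_h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    out = {
        "tod": t_h / 24.0,
        "cos_tod": abs(t_h - 12.0),
        "sin_tod": min(t_h, 24.0 - t_h),
        "is_bday": 1.0 if ts.weekday() < 5 else 0.0,
    }
    a = _arrays(diary)
    te = _hours(ts)
    day_start = te - t_h
    s = _window(a.read_t, day_start + config.wake_cutoff_h, te + 1e-9)
    if s.stop > s.start and np.isfinite(baselines.wake_median_h):
        first_tod = float(a.read_t[s.start] % 24.0)
        out["wake_up_offset"] = first_tod - baselines.wake_median_h
    else:
        out["wake_up_offset"] = np.nan
    return out


def interp_bg_features(
    episode: HypoEpisode, diary: Diary, config: WindowConfig = WindowConfig()
) -> dict[str, float]:
    """Shape statistics of the PCHIP-interpolated BG curve in the +/-3 h
    window around the episode, resampled on a 5-minute grid.

    The monotonicity-preserving interpolant reproduces the readings exactly;
    2 knots degrade to a line, 1 knot to a constant."""
    a = _arrays(diary)
    te = _hours(episode.timestamp)
    s = _window(a.read_t, te - config.interp_half_window_h, te + config.interp_half_window_h + 1e-9)
    t, v = a.read_t[s], a.read_v[s]
    names = ["mean", "std", "range", "min", "max", "slope", "skew", "kurt"]
    if len(t) == 0:
        return {f"bgi_{n}": np.nan for n in names}
    # merge duplicate-time knots (mean value) to keep PCHIP well-posed
    if len(t) > 1:
        tu, inv = np.unique(t, return_inverse=True)
        vu = np.bincount(inv, weights=v) / np.bincount(inv)
        t, v = tu, vu
    if len(t) == 1:
        x = v
        slope = 0.0
    else:
        step = config.resample_step_min / 60.0
        grid = np.arange(t[0], t[-1] + 1e-12, step)
        if grid[-1] < t[-1] - 1e-12:
            grid = np.append(grid, t[-1])
        if len(grid) < 2:
            grid = np.array([t[0], t[-1]])
        x = (np.interp(grid, t, v) if len(t) == 2 else PchipInterpolator(t, v)(grid))
        slope = float(np.polyfit(grid - grid[0], x, 1)[0])
    sd, g1, g2, rng = _moment_stats(x)
    return {
        "bgi_mean": float(np.mean(x)),
        "bgi_std": sd if len(t) > 1 else 0.0,
        "bgi_range": rng if len(t) > 1 else 0.0,
        "bgi_min": float(np.min(x)),
        "bgi_max": float(np.max(x)),
        "bgi_slope": slope,
        "bgi_skew": g1,
        "bgi_kurt": g2,
    }


def neighbor_bg_features(
    episode: HypoEpisode, diary: Diary, config: WindowConfig = WindowConfig()
) -> dict[str, float]:
    """Nearest SMBG readings strictly before/after the episode, overall and
    by glycemic state (hyper / hypo / in-target); offsets in hours, >= 0."""
    a = _arrays(diary)
    te = _hours(episode.timestamp)
    out: dict[str, float] = {}
    for prefix, mask_side in (("pre", a.read_t < te - 1e-9), ("post", a.read_t > te + 1e-9)):
        t, v = a.read_t[mask_side], a.read_v[mask_side]

        def nearest(sel: np.ndarray) -> tuple[float, float]:
            if not sel.any():
                return np.nan, np.nan
            tt, vv = t[sel], v[sel]
            i = -1 if prefix == "pre" else 0
            return float(vv[i]), abs(float(tt[i]) - te)

        g_val, g_off = nearest(np.ones(len(t), dtype=bool))
        _, H_off = nearest(v > config.hyper_threshold)
        _, h_off = nearest(v < config.hypo_threshold)
        _, t_off = nearest((v >= config.target_low) & (v <= config.target_high))
        out[f"{prefix}_g_val"] = g_val
        out[f"{prefix}_g_offset"] = g_off
        out[f"{prefix}_H_offset"] = H_off
        out[f"{prefix}_h_offset"] = h_off
        out[f"{prefix}_t_offset"] = t_off
    return out


def intake_context_features(
    episode: HypoEpisode, diary: Diary, baselines: SubjectBaselines
) -> dict[str, float]:
    """Nearest QA / basal / carb record before and after the episode.
    Dose and amount values are centered on the subject's 3-month mean of the
    same signal; offsets are hours to/from the event."""
    a = _arrays(diary)
    te = _hours(episode.timestamp)
    out: dict[str, float] = {}
    for key, t, v, mean in (
        ("ins", a.qa_t, a.qa_v, baselines.qa_mean),
        ("bas", a.bas_t, a.bas_v, baselines.basal_mean),
        ("car", a.car_t, a.car_v, baselines.carb_mean),
    ):
        i_pre = int(np.searchsorted(t, te - 1e-9, "left")) - 1
        i_post = int(np.searchsorted(t, te + 1e-9, "right"))
        if i_pre >= 0:
            out[f"pre_{key}_dosage"] = float(v[i_pre]) - mean if np.isfinite(mean) else np.nan
            out[f"pre_{key}_offset"] = te - float(t[i_pre])
        else:
            out[f"pre_{key}_dosage"] = np.nan
            out[f"pre_{key}_offset"] = np.nan
        if i_post < len(t):
            out[f"post_{key}_dosage"] = float(v[i_post]) - mean if np.isfinite(mean) else np.nan
            out[f"post_{key}_offset"] = float(t[i_post]) - te
        else:
            out[f"post_{key}_dosage"] = np.nan
            out[f"post_{key}_offset"] = np.nan
    return out


def advisor_features(
    episode: HypoEpisode, diary: Diary, config: WindowConfig = WindowConfig()
) -> dict[str, float]:
    """Most recent bolus-advisor record within the lookback window before the
    episode; all nine values missing when no record exists."""
    a = _arrays(diary)
    te = _hours(episode.timestamp)
    s = _window(a.adv_t, te - config.advisor_lookback_h, te + 1e-9)
    names = ADVISOR_FEATURES
    if s.stop <= s.start:
        return {n: np.nan for n in names}
    records = a.advisor_records[s.start : s.stop]
    rec = records[-1]

    def opt(x) -> float:
        return np.nan if x is None else float(x)

    total, logged = opt(rec.total_ins), opt(rec.logged_intake)
    return {
        "ba_food_ins": opt(rec.food_ins),
        "ba_corr_ins": opt(rec.corr_ins),
        "ba_total_ins": total,
        "ba_diff": total - logged if np.isfinite(total) and np.isfinite(logged) else np.nan,
        "ba_meal_rise": opt(rec.meal_rise),
        "ba_has_excercise": 1.0 if any(r.exercise_tag for r in records) else 0.0,
        "ba_iob": opt(rec.iob),
        "ba_allowed_bgv": opt(rec.allowed_bgv),
        "ba_carb_cu": opt(rec.carb_cu),
    }


def longterm_signal_stats(
    t: np.ndarray,
    v: np.ndarray,
    t_event_h: float,
    prefix: str,
    config: WindowConfig = WindowConfig(),
    with_slopes: bool = False,
) -> dict[str, float]:
    """Summary statistics of one signal over [t_event - 90 d, t_event):
    mean, population SD, range, max, min, mean-crossing rate, skewness,
    excess kurtosis; for BG additionally the means of negative and positive
    consecutive-reading slopes (pairs <= 6 h apart)."""
    s = _window(t, t_event_h - config.longterm_window_days * 24.0, t_event_h)
    tt, x = t[s], v[s]
    names = ["mean", "std", "range", "max", "min", "mean_x", "skew", "kurt"]
    out: dict[str, float] = {f"{prefix}_{n}": np.nan for n in names}
    if with_slopes:
        out["neg_slopes_mean"] = np.nan
        out["pos_slopes_mean"] = np.nan
    if len(x) == 0:
        return out
    out[f"{prefix}_mean"] = float(np.mean(x))
    out[f"{prefix}_max"] = float(np.max(x))
    out[f"{prefix}_min"] = float(np.min(x))
    if len(x) >= 2:
        sd, g1, g2, rng = _moment_stats(x)
        out[f"{prefix}_std"] = sd
        out[f"{prefix}_range"] = rng
        out[f"{prefix}_mean_x"] = _mean_crossing_rate(x)
        out[f"{prefix}_skew"] = g1
        out[f"{prefix}_kurt"] = g2
        if with_slopes:
            dt = np.diff(tt)
            ok = (dt > 0) & (dt <= config.slope_max_gap_h)
            slopes = np.diff(x)[ok] / dt[ok]
            neg, pos = slopes[slopes < 0], slopes[slopes > 0]
            out["neg_slopes_mean"] = float(np.mean(neg)) if len(neg) else np.nan
            out["pos_slopes_mean"] = float(np.mean(pos)) if len(pos) else np.nan
    return out


def quiz_engagement_features(
    diary: Diary, t_event: datetime, config: WindowConfig = WindowConfig()
) -> dict[str, float]:
    """Quiz engagement over the 90 days before the event: answer count,
    distinct active days, mean/SD of points, mean/SD of per-session answer
    counts. Zero activity -> counts 0, means/SDs missing."""
    a = _arrays(diary)
    te = _hours(t_event)
    s = _window(a.quiz_t, te - config.longterm_window_days * 24.0, te)
    n = s.stop - s.start
    if n == 0:
        return {
            "cnc_ansnum": 0.0,
            "cnc_daysnum": 0.0,
            "cnc_points_avg": np.nan,
            "cnc_points_std": np.nan,
            "cnc_dist_avg": np.nan,
            "cnc_dist_std": np.nan,
        }
    points = a.quiz_points[s].astype(float)
    sessions = a.quiz_session[s]
    _, counts = np.unique(sessions, return_counts=True)
    counts = counts.astype(float)
    return {
        "cnc_ansnum": float(n),
        "cnc_daysnum": float(len(np.unique(a.quiz_day[s]))),
        "cnc_points_avg": float(np.mean(points)),
        "cnc_points_std": float(np.std(points)),
        "cnc_dist_avg": float(np.mean(counts)),
        "cnc_dist_std": float(np.std(counts)),
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def represent_event(
    episode: HypoEpisode, diary: Diary, config: WindowConfig = WindowConfig()
) -> dict[str, float]:
    """Assemble the full event representation: the 83 canonical slots in
    registry order plus the extras (tod, ba_iob, ba_allowed_bgv, ba_carb_cu).
    Deterministic for fixed inputs; NaN marks missing."""
    a = _arrays(diary)
    te = _hours(episode.timestamp)
    baselines = compute_baselines(diary, episode.timestamp, config)
    p = diary.profile
    vals: dict[str, float] = {
        "age": float(p.age),
        "gender": float(p.gender),
        "y_w_diab": float(p.years_with_diabetes),
    }
    vals.update(temporal_features(episode, diary, baselines, config))
    vals.update(interp_bg_features(episode, diary, config))
    vals.update(neighbor_bg_features(episode, diary, config))
    vals.update(intake_context_features(episode, diary, baselines))
    vals.update(advisor_features(episode, diary, config))
    vals.update(longterm_signal_stats(a.read_t, a.read_v, te, "glu", config, with_slopes=True))
    vals.update(longterm_signal_stats(a.qa_t, a.qa_v, te, "ins", config))
    vals.update(longterm_signal_stats(a.bas_t, a.bas_v, te, "bas", config))
    vals.update(longterm_signal_stats(a.car_t, a.car_v, te, "car", config))
    vals.update(quiz_engagement_features(diary, episode.timestamp, config))

    missing = [n for n in FEATURE_REGISTRY + EXTRA_FEATURES if n not in vals]
    if missing:  # impossible by construction
        raise RuntimeError(f"registry/vector mismatch, missing slots: {missing}")
    return {n: vals[n] for n in FEATURE_REGISTRY + EXTRA_FEATURES}


def featurize_cohort(
    diaries: dict[str, Diary] | Sequence[Diary],
    config: WindowConfig = WindowConfig(),
    min_confidence: int = 4,
) -> pd.DataFrame:
    """Filter episodes (confidence >= 4, analyzable category) and represent
    each as one row: episode_id, subject_id, category, then the canonical 83
    columns and the extras. Missing = NaN."""
    if isinstance(diaries, dict):
        diaries = list(diaries.values())
    rows = []
    for diary in diaries:
        for k, episode in enumerate(filter_label_episodes(diary.episodes, min_confidence)):
            rec = {
                "episode_id": f"{diary.subject_id}-{k:04d}",
                "subject_id": diary.subject_id,
                "category": episode.category.value,
            }
            rec.update(represent_event(episode, diary, config))
            rows.append(rec)
    cols = ["episode_id", "subject_id", "category"] + FEATURE_REGISTRY + EXTRA_FEATURES
    return pd.DataFrame(rows, columns=cols)


def registry_schema() -> dict:
    """Machine-readable registry description (dumped next to features.csv)."""
    return {
        "canonical": [
            {"name": n, "group": FEATURE_GROUPS[n]} for n in FEATURE_REGISTRY
        ],
        "extras": EXTRA_FEATURES,
        "advisor_features": ADVISOR_FEATURES,
        "n_canonical": len(FEATURE_REGISTRY),
    }
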