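"""Synthetic type 1 diabetes self-care cohorts with labeled hypoglycemia.

The generator emulates the statistical structure the downstream analyses
assume, not glucose physiology: each subject keeps a diary of 3–6 SMBG
readings/day, 2–4 meals/day (carb record plus a quick-acting dose near
grams / subject carb ratio), one basal dose/day, sporadic quiz sessions, and
occasional bolus-advisor interactions. Labeled hypoglycemia episodes
(SMBG < 4 mmol/L) are *injected* with cause-conditional mechanisms:

* ACTIVITY  — daytime-concentrated episode times, an 'exercise' advisor tag
  with high probability, preceding QA dose at-or-below the subject mean;
* FOOD      — morning/evening-skewed times, preceding QA dose above the
  subject mean (carb overestimate), a quick corrective carb afterwards;
* MEDICATION — business-day-skewed times, a longer gap since the last carb,
  a perturbed (raised) basal dose that day.

Effect magnitudes live in :class:`EffectProfile`; ``EffectProfile.zeroed()``
removes every mechanism so all three categories become exchangeable (the
null cohort used for calibration tests). Defaults are sized like a
real-world diary-labeling cohort: 54 subjects, ~15.2 episodes/subject
(~800 events), class mix 0.48/0.36/0.16
over activity/food/medication, advisor data on ~40% of events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .diary import (
    AdvisorRecord,
    CarbIntake,
    Category,
    Diary,
    GlucoseReading,
    HypoEpisode,
    InsulinDose,
    InsulinKind,
    QuizAnswer,
    SubjectProfile,
)

__all__ = [
    "CohortConfig",
    "EffectProfile",
    "GroundTruth",
    "simulate_subject_diary",
    "inject_cause_episode",
    "generate_cohort",
]

_EPOCH = datetime(2019, 1, 1)

#: reason labels emitted per category (all map back through the default
#: reason table in :mod:`hypocause.diary`)
_REASON_LABELS = {
    Category.ACTIVITY: "exercise or physical activity",
    Category.FOOD: "carbohydrate miscount",
    Category.MEDICATION: "too much quick-acting insulin",
}


@dataclass(frozen=True)
class EffectProfile:
    """Cause-conditional effect sizes injected by the generator.

    All fields are magnitudes of *mechanisms*, not regression coefficients;
    the association analysis should recover their signs.
    """

    #: probability that a cause's mechanism is actually expressed (and hence
    #: visible) in the recorded data of a given episode — labels reflect the
    #: patient's belief, not a deterministic data signature
    penetrance: float = 0.7

    # ACTIVITY: episode time-of-day ~ N(activity_tod_mean, activity_tod_sd) h
    activity_tod_mean: float = 14.0
    activity_tod_sd: float = 2.5
    #: probability an ACTIVITY episode's advisor record carries the exercise tag
    activity_exercise_tag_prob: float = 0.7
    #: QA dose before an ACTIVITY episode = subject mean * (1 - this fraction)
    activity_ins_deficit: float = 0.25

    # FOOD: morning/evening mixture means (hours) and sd
    food_tod_means: tuple[float, float] = (8.0, 20.0)
    food_tod_sd: float = 1.5
    #: QA dose before a FOOD episode = subject mean * (1 + this fraction)
    food_ins_excess: float = 0.35
    #: hours to the corrective carb after a FOOD episode
    food_next_carb_hours: float = 0.3

    # MEDICATION: probability the episode lands on a business day
    medication_bday_prob: float = 0.9
    #: extra hours inserted between the last carb and a MEDICATION episode
    medication_carb_gap_hours: float = 2.5
    #: the preceding basal dose is raised by this fraction of the subject mean
    medication_basal_excess: float = 0.15

    @classmethod
    def zeroed(cls) -> "EffectProfile":
        """A profile with every cause-conditional mechanism removed: episode
        times uniform, no dose manipulation, base-rate exercise tags —
        categories become statistically exchangeable."""
        return cls(
            penetrance=0.0,
            activity_tod_mean=float("nan"),
            activity_tod_sd=float("nan"),
            activity_exercise_tag_prob=0.1,
            activity_ins_deficit=0.0,
            food_tod_means=(float("nan"), float("nan")),
            food_tod_sd=float("nan"),
            food_ins_excess=0.0,
            food_next_carb_hours=float("nan"),
            medication_bday_prob=5.0 / 7.0,
            medication_carb_gap_hours=0.0,
            medication_basal_excess=0.0,
        )

    @property
    def is_null(self) -> bool:
        return np.isnan(self.activity_tod_mean)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the emulated cohort conditions."""

    n_subjects: int = 54
    days: int = 180
    episodes_per_subject: float = 15.2
    class_mix: tuple[float, float, float] = (0.48, 0.36, 0.16)
    advisor_availability: float = 0.40
    effect_profile: EffectProfile = field(default_factory=EffectProfile)
    #: negative-binomial-style dispersion of per-subject episode counts
    episode_rate_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {self.class_mix}")
        for p in (*self.class_mix, self.advisor_availability):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.days < 90:
            raise ValueError(
                "days must be >= 90 (long-horizon features need a 3-month window), "
                f"got {self.days}"
            )


@dataclass
class GroundTruth:
    """One row per generated episode: the true category and the mechanism
    parameters actually injected (enables parameter-recovery tests)."""

    table: pd.DataFrame  # episode_id, subject_id, timestamp, category, mechanism json

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subject-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SubjectParams:
    wake_hour: float  # usual first-reading time of day
    bg_mu: float  # subject mean BG, mmol/L
    bg_sigma: float  # lognormal sd on log scale
    carb_ratio: float  # grams covered per insulin unit
    basal_units: float
    meal_carb_mean: float
    quiz_rate: float  # sessions per day


def _draw_subject_params(rng: np.random.Generator) -> _SubjectParams:
    return _SubjectParams(
        wake_hour=float(np.clip(rng.normal(7.0, 0.8), 5.0, 10.0)),
        bg_mu=float(rng.uniform(6.0, 10.0)),
        bg_sigma=float(rng.uniform(0.18, 0.30)),
        carb_ratio=float(np.clip(rng.normal(10.0, 2.0), 5.0, 18.0)),
        basal_units=float(np.clip(rng.normal(24.0, 5.0), 8.0, 45.0)),
        meal_carb_mean=float(np.clip(rng.normal(50.0, 10.0), 25.0, 90.0)),
        quiz_rate=float(rng.uniform(0.05, 0.3)),
    )


def _ts(day: int, hour: float) -> datetime:
    """Minute-resolution timestamp for simulation day ``day`` at ``hour``."""
    minutes = int(round(hour * 60))
    return _EPOCH + timedelta(days=int(day), minutes=minutes)


def _bg_value(rng: np.random.Generator, sp: _SubjectParams) -> float:
    v = float(np.exp(rng.normal(np.log(sp.bg_mu), sp.bg_sigma)))
    return max(v, 1.2)


def simulate_subject_diary(
    profile: SubjectProfile,
    days: int,
    seed: int,
    params: _SubjectParams | None = None,
) -> Diary:
    """Simulate one subject's background diary (no episodes).

    Per day: a wake-time SMBG reading (subject wake hour plus jitter, never
    before 04:30), 2–4 meals each with a carb record, a QA dose near
    grams/carb-ratio and usually a pre-meal reading, one basal dose in the
    evening, an occasional bedtime reading, and sporadic quiz sessions.
    """
    if days < 90:
        raise ValueError(f"days must be >= 90, got {days}")
    rng = np.random.default_rng(seed)
    sp = params if params is not None else _draw_subject_params(rng)
    d = Diary(profile=profile)

    session_counter = 0
    for day in range(days):
        wake = max(4.55, sp.wake_hour + float(rng.normal(0.0, 0.4)))
        d.readings.append(GlucoseReading(_ts(day, wake), _bg_value(rng, sp)))

        n_meals = int(rng.integers(2, 5))  # 2..4
        meal_hours = np.sort(rng.uniform(wake + 0.5, 21.5, size=n_meals))
        for mh in meal_hours:
            grams = max(5.0, float(rng.normal(sp.meal_carb_mean, 15.0)))
            d.carbs.append(CarbIntake(_ts(day, mh), round(grams, 1)))
            dose = max(0.5, grams / sp.carb_ratio + float(rng.normal(0.0, 0.8)))
            d.qa_doses.append(InsulinDose(_ts(day, mh), round(dose, 1), InsulinKind.QA))
            if rng.random() < 0.7:  # pre-meal fingerstick
                d.readings.append(
                    GlucoseReading(_ts(day, max(4.6, mh - 0.2)), _bg_value(rng, sp))
                )

        basal = max(1.0, sp.basal_units + float(rng.normal(0.0, 1.0)))
        d.basal_doses.append(InsulinDose(_ts(day, 22.0), round(basal, 1), InsulinKind.BASAL))
        if rng.random() < 0.5:  # bedtime reading
            d.readings.append(GlucoseReading(_ts(day, 22.5), _bg_value(rng, sp)))

        if rng.random() < sp.quiz_rate:
            session_counter += 1
            n_ans = int(rng.integers(3, 11))
            start = float(rng.uniform(9.0, 21.0))
            for a in range(n_ans):
                d.quiz_answers.append(
                    QuizAnswer(
                        _ts(day, min(23.9, start + 0.03 * a)),
                        points=int(rng.integers(0, 11)),
                        session_id=f"{profile.subject_id}-s{session_counter}",
                    )
                )
    d.sort()
    return d


# ---------------------------------------------------------------------------
# Episode injection
# ---------------------------------------------------------------------------


def _episode_hour(rng: np.random.Generator, category: Category, ep: EffectProfile) -> float:
    expressed = rng.random() < ep.penetrance
    if ep.is_null or not expressed:
        return float(rng.uniform(5.0, 23.0))
    if category is Category.ACTIVITY:
        return float(np.clip(rng.normal(ep.activity_tod_mean, ep.activity_tod_sd), 5.0, 23.0))
    if category is Category.FOOD:
        mean = ep.food_tod_means[int(rng.random() < 0.5)]
        return float(np.clip(rng.normal(mean, ep.food_tod_sd), 5.0, 23.0))
    return float(rng.uniform(5.0, 23.0))


def _pick_day(rng: np.random.Generator, days: int, category: Category, ep: EffectProfile) -> int:
    """Episode day >= 90 so the 3-month lookback is always fully populated;
    MEDICATION episodes are skewed toward business days."""
    p_bday = (
        ep.penetrance * ep.medication_bday_prob + (1.0 - ep.penetrance) * 5.0 / 7.0
        if category is Category.MEDICATION
        else 5.0 / 7.0
    )
    want_bday = rng.random() < p_bday
    pool = [
        d for d in range(90, days)
        if ((_EPOCH + timedelta(days=d)).weekday() < 5) == want_bday
    ]
    return int(rng.choice(pool)) if pool else int(rng.integers(90, days))


def inject_cause_episode(
    diary: Diary,
    category: Category,
    effect_profile: EffectProfile,
    seed: int,
    *,
    days: int,
    advisor_availability: float = 0.40,
    subject_params: _SubjectParams | None = None,
) -> HypoEpisode:
    """Insert one labeled hypoglycemia episode into ``diary`` (in place) with
    the category-conditional mechanisms of ``effect_profile``; returns the
    episode (also appended to ``diary.episodes``)."""
    if category not in _REASON_LABELS:
        raise ValueError(f"cannot inject category {category}")
    rng = np.random.default_rng(seed)
    ep = effect_profile
    sp = subject_params
    sid = diary.subject_id

    day = _pick_day(rng, days, category, ep)
    hour = _episode_hour(rng, category, ep)
    t = _ts(day, hour)

    # the hypoglycemic SMBG reading itself
    smbg = round(float(rng.uniform(2.2, 3.9)), 1)
    diary.readings.append(GlucoseReading(t, smbg))

    qa_mean = (
        float(np.mean([x.units for x in diary.qa_doses])) if diary.qa_doses else 5.0
    )
    basal_mean = (
        float(np.mean([x.units for x in diary.basal_doses])) if diary.basal_doses else 24.0
    )

    mechanism: dict[str, float] = {}

    # preceding QA dose relative to subject mean (expressed mechanisms only)
    if category is Category.ACTIVITY and rng.random() < ep.penetrance:
        dose = qa_mean * (1.0 - ep.activity_ins_deficit * float(rng.uniform(0.5, 1.5)))
        offs = float(rng.uniform(1.0, 3.0))
        diary.qa_doses.append(InsulinDose(_ts(day, hour - offs), round(max(dose, 0.5), 1), InsulinKind.QA))
        mechanism["pre_qa_rel"] = dose - qa_mean
    elif category is Category.FOOD and rng.random() < ep.penetrance:
        dose = qa_mean * (1.0 + ep.food_ins_excess * float(rng.uniform(0.5, 1.5)))
        offs = float(rng.uniform(0.5, 2.0))
        diary.qa_doses.append(InsulinDose(_ts(day, hour - offs), round(dose, 1), InsulinKind.QA))
        mechanism["pre_qa_rel"] = dose - qa_mean
        # quick corrective carb after the episode
        diary.carbs.append(CarbIntake(_ts(day, hour + ep.food_next_carb_hours), 15.0))

    if category is Category.MEDICATION and rng.random() < ep.penetrance:
        # push the most recent carb further into the past
        gap = ep.medication_carb_gap_hours
        prior = [c for c in diary.carbs if timedelta(0) < t - c.timestamp < timedelta(hours=gap)]
        for c in prior:
            diary.carbs.remove(c)
        # raise the most recent basal dose before the episode (the one the
        # nearest-prior-dose feature reads)
        prior_basal = [i for i, b in enumerate(diary.basal_doses) if b.timestamp < t]
        if prior_basal:
            i = prior_basal[-1]
            b = diary.basal_doses[i]
            excess = ep.medication_basal_excess * basal_mean * float(rng.uniform(0.5, 1.5))
            diary.basal_doses[i] = InsulinDose(
                b.timestamp, round(b.units + excess, 1), b.kind
            )
            mechanism["basal_excess"] = excess

    # bolus-advisor record shortly before the episode, for a minority of events
    if rng.random() < advisor_availability:
        food_ins = round(max(0.5, qa_mean + float(rng.normal(0, 1))), 1)
        corr_ins = round(float(rng.uniform(0, 2)), 1)
        tag_prob = (
            ep.activity_exercise_tag_prob
            if (category is Category.ACTIVITY or ep.is_null)
            else 0.1
        )
        diary.advisor_records.append(
            AdvisorRecord(
                timestamp=t - timedelta(minutes=int(rng.integers(30, 180))),
                food_ins=food_ins,
                corr_ins=corr_ins,
                total_ins=round(food_ins + corr_ins, 1),
                logged_intake=round(max(0.0, food_ins + corr_ins + float(rng.normal(0, 0.7))), 1),
                iob=round(float(rng.uniform(0, 4)), 1),
                allowed_bgv=round(float(rng.uniform(8, 12)), 1),
                carb_cu=round(float(rng.uniform(0.8, 1.2)), 2),
                meal_rise=round(float(rng.uniform(1, 3)), 1),
                exercise_tag=bool(rng.random() < tag_prob),
            )
        )
        mechanism["advisor"] = 1.0

    confidence = int(rng.choice([5, 4, 3, 2, 1], p=[0.6, 0.3, 0.06, 0.03, 0.01]))
    episode = HypoEpisode(
        timestamp=t,
        subject_id=sid,
        smbg_value=smbg,
        raw_reason=_REASON_LABELS[category],
        confidence=confidence,
        category=category,
    )
    diary.episodes.append(episode)
    diary.sort()
    return episode


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> tuple[dict[str, Diary], GroundTruth]:
    """Generate ``config.n_subjects`` diaries with injected labeled episodes.

    Fully reproducible from ``config.seed``; episode categories are drawn from
    ``config.class_mix``; the returned :class:`GroundTruth` records every
    injected mechanism.
    """
    rng = np.random.default_rng(config.seed)
    diaries: dict[str, Diary] = {}
    rows = []
    cats = list(_REASON_LABELS)

    for s in range(config.n_subjects):
        sid = f"S{s:03d}"
        age = float(np.clip(rng.normal(46.8, 15.2), 18.0, 85.0))
        profile = SubjectProfile(
            subject_id=sid,
            age=round(age, 1),
            gender=int(rng.random() < 18.0 / 54.0),  # cohort was 2/3 female
            years_with_diabetes=round(float(rng.uniform(1.0, max(1.5, age - 15.0))), 1),
        )
        sp = _draw_subject_params(rng)
        diary = simulate_subject_diary(
            profile, config.days, seed=int(rng.integers(0, 2**31 - 1)), params=sp
        )

        n_ep = max(1, int(rng.normal(config.episodes_per_subject, config.episode_rate_sd)))
        for _ in range(n_ep):
            category = cats[int(rng.choice(3, p=list(config.class_mix)))]
            episode = inject_cause_episode(
                diary,
                category,
                config.effect_profile,
                seed=int(rng.integers(0, 2**31 - 1)),
                days=config.days,
                advisor_availability=config.advisor_availability,
                subject_params=sp,
            )
            rows.append(
                {
                    "episode_id": f"{sid}-e{len(rows):05d}",
                    "subject_id": sid,
                    "timestamp": episode.timestamp.isoformat(),
                    "category": category.value,
                    "confidence": episode.confidence,
                    "mechanism_params_json": json.dumps(
                        {"profile": "null" if config.effect_profile.is_null else "default"}
                    ),
                }
            )
        diaries[sid] = diary

    truth = GroundTruth(pd.DataFrame(rows))
    return diaries, truth
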