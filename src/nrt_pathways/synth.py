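"""Synthetic primary-care prescribing data for end-to-end testing.

Real UK primary-care databases (THIN/CPRD-style) are proprietary, so this
module generates practice, patient and prescription tables with the
statistical structure the analysis assumes: dated NRT, bupropion and
varenicline issues per patient; an incident patch cohort with configurable
yearly initiation weights; per-year combination-therapy probabilities;
repeat episodes separated by gaps of at least 91 days; planted patients
that each exclusion criterion will catch; and the demographic and
comorbidity profile of adult smokers seeking cessation support.

The defaults encode the prescribing landscape the package analyses:
combination therapy rising from ~26% of first episodes in 2008 to ~45% in
2011, patch+inhalator dominating combinations, a ~20% second-episode
rate, and roughly one year (range 91-1693 days) between episodes.  What
the generator deliberately does not simulate: quit outcomes (unobserved
in prescribing records), over-the-counter purchases, and prescription
quantity or duration.
"""

from __future__ import annotations

import datetime as dt
import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .records import (
    COMORBIDITIES,
    Dataset,
    PatientRecord,
    PracticeRecord,
    PrescriptionEvent,
)

#: Nicotine oral sprays were not licensed in the UK until November 2010;
#: the generator never dates an oral-spray issue before this.
ORAL_SPRAY_LAUNCH = dt.date(2010, 11, 1)

_NONPATCH = (
    "NRT_gum",
    "NRT_tablet",
    "NRT_inhalator",
    "NRT_lozenge",
    "NRT_oral_spray",
    "NRT_nasal_spray",
)

#: Strength labels per product form, with sampling weights.
_STRENGTHS = {
    "NRT_patch": (
        ("21 mg/24 hours", 0.38),
        ("15 mg/16 hours", 0.24),
        ("14 mg/24 hours", 0.14),
        ("10 mg/16 hours", 0.10),
        ("25 mg/16 hours", 0.14),
    ),
    "NRT_gum": (("2 mg", 0.6), ("4 mg", 0.4)),
    "NRT_tablet": (("2 mg", 1.0),),
    "NRT_inhalator": (("10 mg", 0.8), ("15 mg", 0.2)),
    "NRT_lozenge": (("1 mg", 0.3), ("2 mg", 0.4), ("4 mg", 0.3)),
    "NRT_oral_spray": (("1 mg/spray", 1.0),),
    "NRT_nasal_spray": (("500 micrograms/spray", 1.0),),
}


@dataclass(frozen=True)
class ExclusionKnobs:
    """Independent per-patient probabilities of planting each exclusion.

    Defaults reproduce the attrition profile of a large incident patch
    cohort: prior NRT history dominates, followed by prior
    bupropion/varenicline and insufficient baseline data.
    """

    under_18: float = 0.033
    short_baseline: float = 0.1579
    short_followup: float = 0.002
    prior_nrt: float = 0.4028
    prior_bup_var: float = 0.1422


@dataclass(frozen=True)
class Demographics:
    """Population profile of adults starting patch-supported quit attempts."""

    age_mean: float = 42.95
    age_sd: float = 15.74
    age_min: int = 18
    age_max: int = 96
    p_male: float = 0.497
    townsend_weights: tuple[float, ...] = (0.148, 0.168, 0.218, 0.250, 0.216)
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "CVD": 0.0652,
            "asthma": 0.1486,
            "COPD": 0.0756,
            "diabetes": 0.0466,
            "stroke": 0.0139,
        }
    )
    p_pregnant_given_female: float = 0.091


@dataclass(frozen=True)
class GapDistribution:
    """Log-normal inter-episode gap, truncated to [91, 1693] days.

    The location is set so the median is about one year between episodes;
    draws outside the support are rejected and resampled.
    """

    median_days: float = 365.0
    sigma: float = 0.60
    min_days: int = 91
    max_days: int = 1693

    def sample(self, rng: np.random.Generator) -> int:
        mu = math.log(self.median_days)
        while True:
            value = int(round(rng.lognormal(mu, self.sigma)))
            if self.min_days <= value <= self.max_days:
                return value


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of the generator.

    Year-indexed tuples align with the four calendar years of the default
    study window.  ``combination_mix`` is the distribution of the
    non-patch partner for combination first episodes, with ``three_plus``
    meaning two or more partners (three or more NRT types in total).
    """

    n_patients: int = 1000
    n_practices: int = 10
    study_start: dt.date = dt.date(2008, 1, 1)
    study_end: dt.date = dt.date(2011, 12, 31)
    #: All practices collect data until this date; generous follow-up so
    #: that repeat episodes seeded by the gap distribution stay observable.
    last_collection_date: dt.date = dt.date(2017, 6, 30)
    yearly_index_weights: tuple[float, ...] = (10632.0, 10501.0, 9337.0, 8484.0)
    p_combination_by_year: tuple[float, ...] = (0.257, 0.339, 0.408, 0.448)
    combination_mix: dict[str, float] = field(
        default_factory=lambda: {
            "NRT_gum": 0.1536,
            "NRT_tablet": 0.0296,
            "NRT_inhalator": 0.5624,
            "NRT_lozenge": 0.1145,
            "NRT_oral_spray": 0.0194,
            "NRT_nasal_spray": 0.0093,
            "three_plus": 0.1112,
        }
    )
    p_second_episode: float = 0.202
    p_third_given_second: float = 1926.0 / 7868.0
    inter_episode_gap_days: GapDistribution = GapDistribution()
    within_episode_gap_lo: int = 14
    within_episode_gap_hi: int = 35
    #: Shifted-geometric prescriptions per episode, capped.
    rx_per_episode_p: float = 0.4
    rx_per_episode_max: int = 8
    p_nonpatch_only: float = 0.243
    nonpatch_mix: dict[str, float] = field(
        default_factory=lambda: {
            "NRT_gum": 0.1679,
            "NRT_tablet": 0.0381,
            "NRT_inhalator": 0.5060,
            "NRT_lozenge": 0.1166,
            "NRT_oral_spray": 0.0189,
            "NRT_nasal_spray": 0.0169,
            "multiple": 0.1355,
        }
    )
    #: History rates among the non-patch-only arm (any prior NRT; prior
    #: bupropion/varenicline) — they do not affect cohort classification.
    p_nonpatch_prior_nrt: float = 0.364
    p_nonpatch_prior_bup_var: float = 0.162
    #: Regimen distribution of second and third episodes (ten categories).
    second_episode_regimen: dict[str, float] = field(
        default_factory=lambda: {
            "patch_only": 0.5017,
            "patch_gum": 0.0372,
            "patch_tablet": 0.0072,
            "patch_inhalator": 0.1473,
            "patch_lozenge": 0.0372,
            "patch_oral_spray": 0.0203,
            "patch_nasal_spray": 0.0028,
            "other_monotherapy": 0.1875,
            "other_dual": 0.0210,
            "three_plus_types": 0.0377,
        }
    )
    third_episode_regimen: dict[str, float] = field(
        default_factory=lambda: {
            "patch_only": 0.4574,
            "patch_gum": 0.0363,
            "patch_tablet": 0.0083,
            "patch_inhalator": 0.1345,
            "patch_lozenge": 0.0431,
            "patch_oral_spray": 0.0306,
            "patch_nasal_spray": 0.0026,
            "other_monotherapy": 0.2253,
            "other_dual": 0.0182,
            "three_plus_types": 0.0436,
        }
    )
    exclusion_knobs: ExclusionKnobs = ExclusionKnobs()
    demographics: Demographics = Demographics()

    def validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")

        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.n_practices < 1:
            raise ValueError("n_practices must be positive")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        n_years = self.study_end.year - self.study_start.year + 1
        if len(self.yearly_index_weights) != n_years:
            raise ValueError("yearly_index_weights must have one weight per study year")
        if any(w < 0 for w in self.yearly_index_weights):
            raise ValueError("yearly_index_weights must be non-negative")
        if len(self.p_combination_by_year) != n_years:
            raise ValueError("p_combination_by_year must have one value per study year")
        for i, p in enumerate(self.p_combination_by_year):
            _prob(f"p_combination_by_year[{i}]", p)
        for name in ("p_second_episode", "p_third_given_second", "p_nonpatch_only"):
            _prob(name, getattr(self, name))
        for mix_name in ("combination_mix", "nonpatch_mix",
                         "second_episode_regimen", "third_episode_regimen"):
            mix = getattr(self, mix_name)
            if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
                raise ValueError(f"{mix_name} must be a non-negative distribution")
        if not 1 <= self.within_episode_gap_lo <= self.within_episode_gap_hi <= 90:
            raise ValueError("within-episode gaps must lie in [1, 90]")
        if self.inter_episode_gap_days.min_days < 91:
            raise ValueError("inter-episode gaps must be at least 91 days")
        for k in ("under_18", "short_baseline", "short_followup", "prior_nrt",
                  "prior_bup_var"):
            _prob(f"exclusion_knobs.{k}", getattr(self.exclusion_knobs, k))


def _calibrate_age_location(target_mean: float, sd: float, lo: int, hi: int) -> float:
    """Location of the underlying normal so the truncated-and-floored age
    distribution has the requested mean.

    Truncating at the lower bound pulls the sample mean up (by ~1.9 years
    at the defaults) and flooring pulls it down by ~0.5; solving for the
    location keeps the configured mean an actual property of the output
    rather than a nominal label.
    """
    def _phi(z: float) -> float:
        return math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)

    def _cdf(z: float) -> float:
        return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))

    mu = target_mean
    for _ in range(60):
        a, b = (lo - mu) / sd, (hi + 1 - mu) / sd
        mass = _cdf(b) - _cdf(a)
        realized = mu + sd * (_phi(a) - _phi(b)) / mass - 0.5
        mu -= realized - target_mean
    return mu


@functools.lru_cache(maxsize=None)
def _age_location_cached(mean: float, sd: float, lo: int, hi: int) -> float:
    return _calibrate_age_location(mean, sd, lo, hi)


def _age_location(demo: Demographics) -> float:
    return _age_location_cached(demo.age_mean, demo.age_sd, demo.age_min, demo.age_max)


def _choice(rng: np.random.Generator, mix: dict[str, float], *, exclude: set[str] = frozenset()) -> str:
    items = [(k, w) for k, w in mix.items() if k not in exclude and w > 0]
    keys = [k for k, _ in items]
    weights = np.array([w for _, w in items], dtype=float)
    return keys[rng.choice(len(keys), p=weights / weights.sum())]


def _strength(rng: np.random.Generator, drug_class: str) -> str:
    options = _STRENGTHS[drug_class]
    labels = [s for s, _ in options]
    weights = np.array([w for _, w in options])
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


def _uniform_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


class _PatientBuilder:
    """Accumulates one patient's records in a deterministic draw order."""

    def __init__(self, config: SynthConfig, rng: np.random.Generator, patient_id: str,
                 practice_id: str):
        self.config = config
        self.rng = rng
        self.patient_id = patient_id
        self.practice_id = practice_id
        self.events: list[PrescriptionEvent] = []

    def issue(self, date: dt.date, drug_class: str, strength: str) -> None:
        self.events.append(
            PrescriptionEvent(self.patient_id, date, drug_class, strength)
        )

    def sample_age(self, adult: bool) -> int:
        demo = self.config.demographics
        if not adult:
            return int(self.rng.integers(12, 18))
        mu = _age_location(demo)
        while True:
            draw = self.rng.normal(mu, demo.age_sd)
            if demo.age_min <= draw < demo.age_max + 1:
                return math.floor(draw)

    def demographics(self, index_year: int, adult: bool = True):
        demo = self.config.demographics
        age = self.sample_age(adult)
        gender = "male" if self.rng.random() < demo.p_male else "female"
        townsend = 1 + int(
            self.rng.choice(5, p=np.array(demo.townsend_weights) / sum(demo.townsend_weights))
        )
        pregnant = gender == "female" and self.rng.random() < demo.p_pregnant_given_female
        comorbidities: dict[str, dt.date] = {}
        for name in COMORBIDITIES:
            prevalence = demo.comorbidity_prevalence.get(name, 0.0)
            lag = int(self.rng.integers(30, 3651))  # always draw: stable stream
            if self.rng.random() < prevalence:
                anchor = dt.date(index_year, 6, 30)
                comorbidities[name] = anchor - dt.timedelta(days=lag)
        return age, gender, townsend, pregnant, comorbidities


def _episode_dates(config: SynthConfig, rng: np.random.Generator,
                   start: dt.date) -> list[dt.date]:
    n_rx = min(int(rng.geometric(config.rx_per_episode_p)), config.rx_per_episode_max)
    dates = [start]
    for _ in range(n_rx - 1):
        step = int(rng.integers(config.within_episode_gap_lo,
                                config.within_episode_gap_hi + 1))
        dates.append(dates[-1] + dt.timedelta(days=step))
    return dates


def _emit_regimen(builder: _PatientBuilder, rng: np.random.Generator,
                  config: SynthConfig, start: dt.date, category: str,
                  *, pre_index_partner: bool) -> dt.date:
    """Write one episode's prescriptions; returns the episode's last date.

    ``category`` is a regimen-category name; for combination regimens the
    partner product's first issue is placed uniformly in
    [start - 14 days, start + 28 days] when ``pre_index_partner`` (first
    episodes exercise the pre-index allowance), else on the start date.
    Oral-spray issues are clamped to the product's launch date.
    """
    dates = _episode_dates(config, rng, start)
    classes: list[str]
    if category == "patch_only":
        classes = ["NRT_patch"]
    elif category.startswith("patch_"):
        classes = ["NRT_patch", "NRT_" + category.removeprefix("patch_")]
    elif category == "three_plus_types":
        exclude = {"three_plus"}
        if start < ORAL_SPRAY_LAUNCH:
            exclude.add("NRT_oral_spray")
        first = _choice(rng, config.combination_mix, exclude=exclude)
        second = _choice(rng, config.combination_mix, exclude=exclude | {first})
        classes = ["NRT_patch", first, second]
    elif category == "other_monotherapy":
        exclude = {"three_plus"}
        if start < ORAL_SPRAY_LAUNCH:
            exclude.add("NRT_oral_spray")
        classes = [_choice(rng, config.combination_mix, exclude=exclude)]
    elif category == "other_dual":
        exclude = {"three_plus"}
        if start < ORAL_SPRAY_LAUNCH:
            exclude.add("NRT_oral_spray")
        first = _choice(rng, config.combination_mix, exclude=exclude)
        second = _choice(rng, config.combination_mix, exclude=exclude | {first})
        classes = [first, second]
    else:
        raise ValueError(f"unknown regimen category {category!r}")

    anchor_class = classes[0]
    anchor_strength = _strength(rng, anchor_class)
    for date in dates:
        builder.issue(date, anchor_class, anchor_strength)
    last = dates[-1]
    for partner in classes[1:]:
        if pre_index_partner:
            offset = int(rng.integers(-14, 29))
        else:
            offset = int(rng.integers(0, 29))
        partner_date = start + dt.timedelta(days=offset)
        if partner == "NRT_oral_spray" and partner_date < ORAL_SPRAY_LAUNCH:
            partner_date = ORAL_SPRAY_LAUNCH
        builder.issue(partner_date, partner, _strength(rng, partner))
        last = max(last, partner_date)
    return last


def generate(config: SynthConfig, seed: int) -> Dataset:
    """Generate a full dataset; identical seed and config give identical output."""
    config.validate()
    rng = np.random.default_rng(seed)

    practices: dict[str, PracticeRecord] = {}
    for i in range(config.n_practices):
        practice_id = f"pr{i:03d}"
        vision = _uniform_date(rng, dt.date(1996, 1, 1), dt.date(2004, 12, 31))
        amr = _uniform_date(rng, vision, dt.date(2006, 6, 30))
        practices[practice_id] = PracticeRecord(
            practice_id=practice_id,
            vision_date=vision,
            amr_date=amr,
            last_collection_date=config.last_collection_date,
        )

    patients: dict[str, PatientRecord] = {}
    prescriptions: list[PrescriptionEvent] = []
    years = list(range(config.study_start.year, config.study_end.year + 1))
    year_weights = np.array(config.yearly_index_weights, dtype=float)
    year_weights = year_weights / year_weights.sum()

    for i in range(config.n_patients):
        patient_id = f"pt{i:06d}"
        practice_id = f"pr{int(rng.integers(0, config.n_practices)):03d}"
        builder = _PatientBuilder(config, rng, patient_id, practice_id)
        if rng.random() < config.p_nonpatch_only:
            patient = _generate_nonpatch_only(config, rng, builder, years, year_weights)
        else:
            patient = _generate_patch_patient(config, rng, builder, years, year_weights)
        patients[patient_id] = patient
        prescriptions.extend(builder.events)

    return Dataset(practices=practices, patients=patients, prescriptions=prescriptions)


def _generate_patch_patient(config: SynthConfig, rng: np.random.Generator,
                            builder: _PatientBuilder, years: list[int],
                            year_weights: np.ndarray) -> PatientRecord:
    knobs = config.exclusion_knobs
    year_idx = int(rng.choice(len(years), p=year_weights))
    index_year = years[year_idx]
    year_start = max(dt.date(index_year, 1, 1), config.study_start)
    year_end = min(dt.date(index_year, 12, 31), config.study_end)
    index_date = _uniform_date(rng, year_start, year_end)

    flag_under18 = rng.random() < knobs.under_18
    flag_short_baseline = rng.random() < knobs.short_baseline
    flag_short_followup = rng.random() < knobs.short_followup
    flag_prior_nrt = rng.random() < knobs.prior_nrt
    flag_prior_bup_var = rng.random() < knobs.prior_bup_var

    age, gender, townsend, pregnant, comorbidities = builder.demographics(
        index_year, adult=not flag_under18
    )

    if flag_short_baseline:
        registration = index_date - dt.timedelta(days=int(rng.integers(14, 183)))
    else:
        registration = index_date - dt.timedelta(days=int(rng.integers(250, 4001)))
    transfer_out = None
    if flag_short_followup:
        transfer_out = index_date + dt.timedelta(days=int(rng.integers(0, 14)))
    followup_end = transfer_out or config.last_collection_date

    if flag_prior_nrt:
        if rng.random() < 0.5:
            # Patch history strictly before the study window, so the index
            # remains the first in-window patch.
            prior_date = config.study_start - dt.timedelta(days=int(rng.integers(30, 1501)))
            builder.issue(prior_date, "NRT_patch", _strength(rng, "NRT_patch"))
        else:
            # Non-patch history more than two weeks before index.
            prior_date = index_date - dt.timedelta(days=int(rng.integers(20, 1501)))
            partner = _choice(rng, config.combination_mix,
                              exclude={"three_plus", "NRT_oral_spray"})
            builder.issue(prior_date, partner, _strength(rng, partner))
    if flag_prior_bup_var:
        drug = "bupropion" if rng.random() < 0.5 else "varenicline"
        prior_date = index_date - dt.timedelta(days=int(rng.integers(20, 1501)))
        builder.issue(prior_date, drug, "")

    # First episode.
    combination = rng.random() < config.p_combination_by_year[year_idx]
    if combination:
        exclude: set[str] = set()
        if index_date < ORAL_SPRAY_LAUNCH:
            exclude.add("NRT_oral_spray")
        partner = _choice(rng, config.combination_mix, exclude=exclude)
        category = (
            "three_plus_types" if partner == "three_plus"
            else "patch_" + partner.removeprefix("NRT_")
        )
    else:
        category = "patch_only"
    last_end = _emit_regimen(builder, rng, config, index_date, category,
                             pre_index_partner=True)

    # Repeat episodes.
    if rng.random() < config.p_second_episode:
        gap = config.inter_episode_gap_days.sample(rng)
        start2 = last_end + dt.timedelta(days=gap)
        if start2 <= followup_end:
            category2 = _pick_repeat_regimen(rng, config.second_episode_regimen, start2)
            last_end = _emit_regimen(builder, rng, config, start2, category2,
                                     pre_index_partner=False)
            if rng.random() < config.p_third_given_second:
                gap3 = config.inter_episode_gap_days.sample(rng)
                start3 = last_end + dt.timedelta(days=gap3)
                if start3 <= followup_end:
                    category3 = _pick_repeat_regimen(
                        rng, config.third_episode_regimen, start3
                    )
                    _emit_regimen(builder, rng, config, start3, category3,
                                  pre_index_partner=False)

    # Observation boundary: nothing is recorded after follow-up ends.
    builder.events = [e for e in builder.events if e.date <= followup_end]

    return PatientRecord(
        patient_id=builder.patient_id,
        practice_id=builder.practice_id,
        year_of_birth=index_year - age,
        gender=gender,
        registration_date=registration,
        transfer_out_date=transfer_out,
        townsend_quintile=townsend,
        pregnant_at_index=pregnant,
        comorbidities=comorbidities,
    )


def _pick_repeat_regimen(rng: np.random.Generator, mix: dict[str, float],
                         start: dt.date) -> str:
    exclude: set[str] = set()
    if start < ORAL_SPRAY_LAUNCH:
        exclude.add("patch_oral_spray")
    return _choice(rng, mix, exclude=exclude)


def _generate_nonpatch_only(config: SynthConfig, rng: np.random.Generator,
                            builder: _PatientBuilder, years: list[int],
                            year_weights: np.ndarray) -> PatientRecord:
    year_idx = int(rng.choice(len(years), p=year_weights))
    year = years[year_idx]
    age, gender, townsend, pregnant, comorbidities = builder.demographics(year)
    category = _choice(rng, config.nonpatch_mix)

    def event_date(drug_class: str) -> dt.date:
        if drug_class == "NRT_oral_spray":
            # Licensed late 2010: ignore the sampled year, date after launch.
            return _uniform_date(
                rng, max(config.study_start, ORAL_SPRAY_LAUNCH), config.study_end
            )
        lo = max(config.study_start, dt.date(year, 1, 1))
        hi = min(config.study_end, dt.date(year, 12, 31))
        return _uniform_date(rng, lo, hi)

    if category == "multiple":
        first = _choice(rng, config.nonpatch_mix, exclude={"multiple", "NRT_oral_spray"})
        second = _choice(rng, config.nonpatch_mix,
                         exclude={"multiple", "NRT_oral_spray", first})
        d1 = event_date(first)
        builder.issue(d1, first, _strength(rng, first))
        d2 = min(d1 + dt.timedelta(days=int(rng.integers(0, 60))), config.study_end)
        builder.issue(d2, second, _strength(rng, second))
        first_nrt = d1
    else:
        date = event_date(category)
        builder.issue(date, category, _strength(rng, category))
        first_nrt = date

    # Histories (do not change cohort classification: patch history stays
    # strictly before the study window).
    if rng.random() < config.p_nonpatch_prior_nrt:
        prior_date = config.study_start - dt.timedelta(days=int(rng.integers(30, 1501)))
        drug_class = "NRT_patch" if rng.random() < 0.5 else "NRT_gum"
        builder.issue(prior_date, drug_class, _strength(rng, drug_class))
    if rng.random() < config.p_nonpatch_prior_bup_var:
        drug = "bupropion" if rng.random() < 0.5 else "varenicline"
        builder.issue(first_nrt - dt.timedelta(days=int(rng.integers(20, 1501))),
                      drug, "")

    registration = first_nrt - dt.timedelta(days=int(rng.integers(250, 4001)))
    return PatientRecord(
        patient_id=builder.patient_id,
        practice_id=builder.practice_id,
        year_of_birth=year - age,
        gender=gender,
        registration_date=registration,
        transfer_out_date=None,
        townsend_quintile=townsend,
        pregnant_at_index=pregnant,
        comorbidities=comorbidities,
    )


def generate_toy_fixture() -> Dataset:
    """A tiny hand-built dataset with one patient per interesting case.

    Planted patients (practice ``pr001``, last collection 2013-06-30):

    ======================  =====================================================
    patient                 role
    ======================  =====================================================
    ``excl_under18``        aged 16 at index -> excluded (under_18)
    ``excl_short_base``     registered 92 days before index -> short_baseline
    ``excl_short_fup``      transfers out 9 days after index -> short_followup
    ``excl_prior_patch``    patch in 2007, before the window -> prior_patch
    ``excl_prior_nonpatch`` gum 31 days before index -> prior_nonpatch
    ``excl_bupvar``         varenicline before index -> prior_bup_var
    ``inc_patch_only``      two patch issues 28 days apart; long quiet tail ->
                            included, patch_only, discontinued
    ``inc_patch_inhal``     inhalator 9 days before the index patch (inside the
                            two-week allowance) -> included, patch_inhalator
    ``inc_three_types``     patch + gum + lozenge in episode 1 -> three_plus
    ``inc_two_episodes``    patches 91 days apart -> two episodes (gap 91)
    ``inc_gap90``           patches 90 days apart -> one episode
    ``inc_active``          refills up to 41 days before follow-up end ->
                            included, not discontinued
    ``nonpatch_inhal``      inhalator only in window -> nonpatch_only arm
    ======================  =====================================================
    """
    practice = PracticeRecord(
        practice_id="pr001",
        vision_date=dt.date(2000, 1, 1),
        amr_date=dt.date(2001, 1, 1),
        last_collection_date=dt.date(2013, 6, 30),
    )

    def patient(pid: str, yob: int = 1970, registration: dt.date = dt.date(2005, 1, 1),
                transfer_out: dt.date | None = None, gender: str = "male",
                townsend: int | None = 3) -> PatientRecord:
        return PatientRecord(
            patient_id=pid,
            practice_id="pr001",
            year_of_birth=yob,
            gender=gender,
            registration_date=registration,
            transfer_out_date=transfer_out,
            townsend_quintile=townsend,
        )

    d = dt.date
    patients = [
        patient("excl_under18", yob=1992),
        patient("excl_short_base", registration=d(2008, 3, 1)),
        patient("excl_short_fup", transfer_out=d(2008, 6, 10)),
        patient("excl_prior_patch"),
        patient("excl_prior_nonpatch"),
        patient("excl_bupvar"),
        patient("inc_patch_only"),
        patient("inc_patch_inhal", gender="female"),
        patient("inc_three_types"),
        patient("inc_two_episodes"),
        patient("inc_gap90"),
        patient("inc_active"),
        patient("nonpatch_inhal"),
    ]

    patch21 = ("NRT_patch", "21 mg/24 hours")
    events = [
        ("excl_under18", d(2008, 6, 1), *patch21),
        ("excl_short_base", d(2008, 6, 1), *patch21),
        ("excl_short_fup", d(2008, 6, 1), *patch21),
        ("excl_prior_patch", d(2007, 5, 1), *patch21),
        ("excl_prior_patch", d(2008, 6, 1), *patch21),
        ("excl_prior_nonpatch", d(2008, 5, 1), "NRT_gum", "2 mg"),
        ("excl_prior_nonpatch", d(2008, 6, 1), *patch21),
        ("excl_bupvar", d(2008, 1, 15), "varenicline", ""),
        ("excl_bupvar", d(2008, 6, 1), *patch21),
        ("inc_patch_only", d(2008, 6, 1), *patch21),
        ("inc_patch_only", d(2008, 6, 29), *patch21),
        ("inc_patch_inhal", d(2009, 2, 20), "NRT_inhalator", "10 mg"),
        ("inc_patch_inhal", d(2009, 3, 1), *patch21),
        ("inc_three_types", d(2010, 4, 1), *patch21),
        ("inc_three_types", d(2010, 4, 8), "NRT_gum", "2 mg"),
        ("inc_three_types", d(2010, 5, 1), "NRT_lozenge", "2 mg"),
        ("inc_two_episodes", d(2008, 2, 1), *patch21),
        ("inc_two_episodes", d(2008, 5, 2), *patch21),  # gap 91 -> new episode
        ("inc_gap90", d(2008, 2, 1), *patch21),
        ("inc_gap90", d(2008, 5, 1), *patch21),  # gap 90 -> same episode
        ("inc_active", d(2011, 12, 1), *patch21),
        ("inc_active", d(2012, 2, 10), *patch21),
        ("inc_active", d(2012, 4, 20), *patch21),
        ("inc_active", d(2012, 6, 25), *patch21),
        ("inc_active", d(2012, 9, 1), *patch21),
        ("inc_active", d(2012, 11, 5), *patch21),
        ("inc_active", d(2013, 1, 10), *patch21),
        ("inc_active", d(2013, 3, 15), *patch21),
        ("inc_active", d(2013, 5, 20), *patch21),
        ("nonpatch_inhal", d(2009, 7, 1), "NRT_inhalator", "10 mg"),
    ]

    return Dataset(
        practices={practice.practice_id: practice},
        patients={p.patient_id: p for p in patients},
        prescriptions=[PrescriptionEvent(*e) for e in events],
    )


#: Hand-verified expectations for :func:`generate_toy_fixture`, used by the
#: test-suite and by the worked examples.
TOY_EXPECTATIONS = {
    "status": {
        "excl_under18": "excluded",
        "excl_short_base": "excluded",
        "excl_short_fup": "excluded",
        "excl_prior_patch": "excluded",
        "excl_prior_nonpatch": "excluded",
        "excl_bupvar": "excluded",
        "inc_patch_only": "included",
        "inc_patch_inhal": "included",
        "inc_three_types": "included",
        "inc_two_episodes": "included",
        "inc_gap90": "included",
        "inc_active": "included",
        "nonpatch_inhal": "nonpatch_only",
    },
    "exclusion_reasons": {
        "excl_under18": ["under_18"],
        "excl_short_base": ["short_baseline"],
        "excl_short_fup": ["short_followup"],
        "excl_prior_patch": ["prior_patch"],
        "excl_prior_nonpatch": ["prior_nonpatch"],
        "excl_bupvar": ["prior_bup_var"],
    },
    "n_episodes": {
        "inc_patch_only": 1,
        "inc_patch_inhal": 1,
        "inc_three_types": 1,
        "inc_two_episodes": 2,
        "inc_gap90": 1,
        "inc_active": 1,
    },
    "episode1_category": {
        "inc_patch_only": "patch_only",
        "inc_patch_inhal": "patch_inhalator",
        "inc_three_types": "three_plus_types",
        "inc_two_episodes": "patch_only",
        "inc_gap90": "patch_only",
        "inc_active": "patch_only",
    },
    "discontinued": {
        "inc_patch_only": True,
        "inc_active": False,
    },
}


def small_config(n_patients: int = 500) -> SynthConfig:
    """Convenience config for quick examples and tests."""
    return replace(SynthConfig(), n_patients=n_patients, n_practices=3)
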