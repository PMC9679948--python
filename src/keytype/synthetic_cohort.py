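"""Synthetic longitudinal cohort with known ground truth.

Emulates a one-year observational study of ~100 people with multiple
sclerosis: per-subject latent motor and cognitive typing latencies with
between-subject heterogeneity and per-visit within-subject deviations,
raw press/release keystroke event streams whose extracted daily cluster
values recover the latent states, clinical scores (Nine-Hole Peg Test and
Symbol Digit Modalities Test) linked to the latents through the hybrid
between/within model, an SDMT practice effect increasing across visits,
and clinical-visit missingness concentrated at the mid-study visits.

Calibration
-----------
Per-sample latencies are log-normal with a *constant coefficient of
variation*.  For a log-normal with mean M and CV c the median is
M / sqrt(1 + c^2), so the daily summary (mean + median)/2 equals
kappa(c) * M with kappa = (1 + 1/sqrt(1+c^2))/2 — linear in M.  The
generator inverts this mapping (and accounts for hold time entering the
flight-time member of the fine-motor cluster) so that the expected
extracted daily cluster value equals the latent latency exactly; the
hybrid-model coefficients configured here are therefore the estimands of
the analysis pipeline, which is what makes unbiased end-to-end parameter
recovery possible.

Clinical scores are generated *after* visit missingness so that the
person-mean used in the generating model is the mean over the visits the
analysis will actually see.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events_io import EVENT_COLUMNS

_MS_PER_DAY = 86_400_000


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Generating parameters of the synthetic cohort.

    Defaults are the emulated study's conditions: 102 subjects, five
    3-monthly visits over one year, fine-motor cluster ~0.43 (SD 0.16) s,
    cognition cluster ~0.94 (SD 0.41) s, NHPT between/within slopes
    15.9/6.9 s per second of cluster latency, SDMT slopes −11.2/−0.4
    points, an SDMT practice effect rising across occasions, and visit
    missingness concentrated at M6/M9.
    """

    n_subjects: int = 102
    visit_schedule_days: tuple = (0, 91, 182, 273, 365)
    visit_labels: tuple = ("M0", "M3", "M6", "M9", "M12")
    start_date: str = "2019-01-01"

    # typing behaviour
    adherence_mean: float = 0.91  # per-day typing probability (subject-level Beta)
    adherence_concentration: float = 13.0
    events_per_day_mean: float = 250.0
    events_per_day_sd: float = 150.0
    max_keys_per_day: int = 5000
    typing_days: str = "all"  # "all" = every study day; "windows_only" = visit windows
    session_keys_mean: float = 40.0  # mean keys between long (session-splitting) breaks

    # key-class mix of the simulated streams
    p_backspace: float = 0.05
    p_punctuation: float = 0.03
    p_other: float = 0.12  # space/return/etc.

    # latent cluster-scale states (seconds)
    fmsc_mean: float = 0.43
    fmsc_between_sd: float = 0.16
    csc_mean: float = 0.94
    csc_between_sd: float = 0.40
    motor_within_sd: float = 0.06
    cog_within_sd: float = 0.12
    motor_trend_per_occasion: float = 0.0
    cog_trend_per_occasion: float = 0.0

    # per-sample variability (constant CV keeps the daily summary calibratable)
    motor_sample_cv: float = 0.28
    cog_sample_cv: float = 0.25  # keeps P(pause > session gap) negligible for all subjects
    hold_mean: float = 0.08
    hold_subject_sd: float = 0.015
    hold_day_sd: float = 0.010
    hold_sample_sd: float = 0.010
    backspace_hold_mean: float = 0.12
    intra_burst_gap: float = 0.15
    rollover_prob: float = 0.0  # exercises negative flight time when > 0

    # clinical linkage: NHPT (seconds)
    nhpt_intercept: float = 14.0
    nhpt_beta_between: float = 15.9
    nhpt_beta_within: float = 6.9
    nhpt_subject_sd: float = 2.5
    nhpt_resid_sd: float = 1.2
    nhpt_trial_sd: float = 0.8
    nhpt_floor: float = 5.0
    nhpt_age_effect: float = 0.0
    nhpt_sex_effect: float = 0.0

    # clinical linkage: SDMT (points)
    sdmt_intercept: float = 65.0
    sdmt_beta_between: float = -11.2
    sdmt_beta_within: float = -0.4
    sdmt_subject_sd: float = 9.0
    sdmt_resid_sd: float = 4.0
    sdmt_practice_per_occasion: float = 1.5
    sdmt_occasion_sd: float = 0.8
    sdmt_age_effect: float = -0.15
    sdmt_education_effects: tuple = (-4.0, -1.5, 0.0)  # low, middle, high
    cog_education_effects: tuple = (0.15, 0.05, -0.03)  # confounding path

    # demographics
    age_mean: float = 46.4
    age_sd: float = 10.4
    age_range: tuple = (18.0, 65.0)
    p_female: float = 0.735
    education_probs: tuple = (0.029, 0.334, 0.637)  # low, middle, high

    # clinical-visit missingness per occasion (most prominent mid-study)
    visit_missingness: tuple = (0.0, 0.09, 0.25, 0.43, 0.13)
    dropout_hazard: float = 0.0  # optional monotone dropout per visit

    def validate(self) -> None:
        sched = self.visit_schedule_days
        if not all(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError("visit_schedule_days must be strictly increasing")
        if len(sched) != len(self.visit_labels):
            raise ValueError("visit schedule and labels differ in length")
        for name in (
            "fmsc_between_sd", "csc_between_sd", "motor_within_sd", "cog_within_sd",
            "nhpt_subject_sd", "nhpt_resid_sd", "sdmt_subject_sd", "sdmt_resid_sd",
            "events_per_day_sd", "hold_subject_sd", "hold_day_sd", "hold_sample_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = (
            self.adherence_mean, self.p_backspace, self.p_punctuation, self.p_other,
            self.p_female, self.rollover_prob, self.dropout_hazard,
            *self.visit_missingness, *self.education_probs,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.visit_missingness) != len(sched):
            raise ValueError("visit_missingness must have one rate per visit")
        if self.typing_days not in ("all", "windows_only"):
            raise ValueError("typing_days must be 'all' or 'windows_only'")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in dataclasses.asdict(self).items()},
                fh, sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown config key: {k}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def daily_summary_factor(cv: float) -> float:
    """kappa(cv): E[(mean+median)/2] / mean for a log-normal with that CV."""
    return 0.5 * (1.0 + 1.0 / np.sqrt(1.0 + cv * cv))


def _lognormal_musigma(mean: np.ndarray | float, cv: float) -> tuple[np.ndarray, float]:
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _lognormal_from_mean_sd(rng, mean: float, sd: float, size) -> np.ndarray:
    mu, sigma = _lognormal_musigma(mean, sd / mean)
    return rng.lognormal(mu, sigma, size=size)


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: events, clinical visits and ground truth."""

    events: pd.DataFrame
    visits: pd.DataFrame
    ground_truth: pd.DataFrame
    config: CohortConfig
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(outdir / "events.csv", index=False)
        self.visits.to_csv(outdir / "visits.csv", index=False)
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        self.config.to_yaml(outdir / "cohort_config.yaml")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def apply_missingness(
    visits: pd.DataFrame,
    rates: dict | tuple,
    seed: int | np.random.Generator,
    labels: tuple = ("M0", "M3", "M6", "M9", "M12"),
    dropout_hazard: float = 0.0,
) -> pd.DataFrame:
    """Drop clinical visits per configured per-occasion missingness rates.

    ``rates`` is either a mapping label -> probability or a sequence
    aligned with ``labels``.  Optionally a monotone dropout process is
    superimposed: at each occasion after the first a subject drops out
    with probability ``dropout_hazard`` and contributes no later visits.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not isinstance(rates, dict):
        rates = dict(zip(labels, rates))
    bad = [r for r in rates.values() if not (0.0 <= r <= 1.0)]
    if bad or not (0.0 <= dropout_hazard <= 1.0):
        raise ValueError("missingness rates must lie in [0, 1]")
    p = visits["visit_label"].map(rates).fillna(0.0).to_numpy(dtype=float)
    keep = rng.random(len(visits)) >= p
    if dropout_hazard > 0:
        order = {lab: i for i, lab in enumerate(labels)}
        occ = visits["visit_label"].map(order).to_numpy()
        for sid, idx in visits.groupby("subject_id").groups.items():
            idx = np.asarray(idx)
            n_occ = occ[idx].max() + 1
            drops = rng.random(max(n_occ - 1, 0)) < dropout_hazard
            if drops.any():
                first_drop = int(np.argmax(drops)) + 1
                keep[idx[occ[idx] >= first_drop]] = False
    return visits.loc[keep].reset_index(drop=True)


def simulate_clinical_scores(
    latents: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical scores for retained visits from the latent states.

    ``latents`` must carry one row per retained subject-visit with columns
    ``subject_id, visit_label, occasion_idx, motor_latent, cog_latent,
    motor_mean, cog_mean, age, sex_male, education_idx``.  NHPT follows the
    hybrid linkage on the motor latent (four trials are emitted whose mean
    is the visit score); SDMT follows the cognitive latent plus a practice
    increment and a shared occasion effect, rounded to integer points.
    """
    lat = latents
    n = len(lat)
    subs = lat["subject_id"].to_numpy()
    uniq, inv = np.unique(subs, return_inverse=True)
    u_nhpt = rng.normal(0.0, config.nhpt_subject_sd, size=len(uniq))[inv]
    u_sdmt = rng.normal(0.0, config.sdmt_subject_sd, size=len(uniq))[inv]
    occ = lat["occasion_idx"].to_numpy()
    n_occ = len(config.visit_labels)
    occ_effect = (
        config.sdmt_practice_per_occasion * np.arange(n_occ)
        + rng.normal(0.0, config.sdmt_occasion_sd, size=n_occ)
    )

    age_c = lat["age"].to_numpy() - config.age_mean
    male = lat["sex_male"].to_numpy(dtype=float)
    edu = lat["education_idx"].to_numpy(dtype=int)

    nhpt = (
        config.nhpt_intercept
        + config.nhpt_beta_between * lat["motor_mean"].to_numpy()
        + config.nhpt_beta_within * (lat["motor_latent"] - lat["motor_mean"]).to_numpy()
        + config.nhpt_age_effect * age_c
        + config.nhpt_sex_effect * male
        + u_nhpt
        + rng.normal(0.0, config.nhpt_resid_sd, size=n)
    )
    nhpt = np.maximum(nhpt, config.nhpt_floor)
    trials = nhpt[:, None] + rng.normal(0.0, config.nhpt_trial_sd, size=(n, 4))
    trials = np.maximum(trials, 1.0)

    sdmt = (
        config.sdmt_intercept
        + config.sdmt_beta_between * lat["cog_mean"].to_numpy()
        + config.sdmt_beta_within * (lat["cog_latent"] - lat["cog_mean"]).to_numpy()
        + np.asarray(config.sdmt_education_effects)[edu]
        + config.sdmt_age_effect * age_c
        + occ_effect[occ]
        + u_sdmt
        + rng.normal(0.0, config.sdmt_resid_sd, size=n)
    )
    sdmt = np.maximum(np.rint(sdmt), 0.0)

    out = lat[["subject_id", "visit_label"]].copy()
    for i in range(4):
        out[f"nhpt_trial_{i + 1}"] = np.round(trials[:, i], 2)
    out["sdmt_score"] = sdmt.astype(int)
    return out


def _candidate_days(config: CohortConfig) -> np.ndarray:
    """Study days on which typing may occur."""
    last = config.visit_schedule_days[-1]
    if config.typing_days == "all":
        return np.arange(0, last + 1)
    days: set[int] = set()
    for v, half in zip(config.visit_schedule_days, (14,) * len(config.visit_schedule_days)):
        days.update(range(max(v - half, 0), min(v + half, last) + 1))
    return np.array(sorted(days))


def _simulate_event_streams(
    subj_idx: np.ndarray,
    day_num: np.ndarray,
    n_keys: np.ndarray,
    m_day: np.ndarray,
    c_day: np.ndarray,
    h_day: np.ndarray,
    subject_ids: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    epoch_day0: int,
) -> pd.DataFrame:
    """Vectorized press/release stream for many subject-days at once.

    Per-day inputs: subject index, calendar day number, key count, latent
    motor (FMSC-scale) and cognitive (CSC-scale) latencies and the day's
    mean hold time.  Returns events in the canonical schema.
    """
    D = len(day_num)
    K = int(n_keys.sum())
    day_of_key = np.repeat(np.arange(D), n_keys)
    starts = np.r_[0, np.cumsum(n_keys)[:-1]]
    is_first = np.zeros(K, dtype=bool)
    is_first[starts] = True

    # key classes
    u = rng.random(K)
    p_bs, p_pu, p_ot = config.p_backspace, config.p_punctuation, config.p_other
    cls = np.full(K, 0, dtype=np.int8)  # 0 alnum, 1 backspace, 2 punct, 3 other
    cls[u < p_bs] = 1
    cls[(u >= p_bs) & (u < p_bs + p_pu)] = 2
    cls[(u >= p_bs + p_pu) & (u < p_bs + p_pu + p_ot)] = 3

    # hold times (seconds)
    hold = h_day[day_of_key] + rng.normal(0.0, config.hold_sample_sd, size=K)
    is_bs = cls == 1
    hold[is_bs] = config.backspace_hold_mean + rng.normal(0.0, 0.01, size=int(is_bs.sum()))
    np.clip(hold, 0.02, None, out=hold)

    # latency draws: motor-rhythm gaps (press-to-press) and cognitive pauses
    kappa_m = daily_summary_factor(config.motor_sample_cv)
    kappa_c = daily_summary_factor(config.cog_sample_cv)
    mu_g, sig_g = _lognormal_musigma((m_day + h_day / 3.0) / kappa_m, config.motor_sample_cv)
    mu_c, sig_c = _lognormal_musigma(c_day / kappa_c, config.cog_sample_cv)
    G = rng.lognormal(mu_g[day_of_key], sig_g)
    C = rng.lognormal(mu_c[day_of_key], sig_c)

    prev_cls = np.r_[np.int8(0), cls[:-1]]
    prev_hold = np.r_[0.0, hold[:-1]]
    cur_bs = cls == 1
    prev_bs = prev_cls == 1
    prev_punct = prev_cls == 2

    # incoming flight gap F = press(k) - release(k-1), by transition type
    F = G - prev_hold  # default: typing rhythm (PPL == G for alnum pairs)
    if config.rollover_prob > 0:
        rolled = (rng.random(K) < config.rollover_prob) & ~cur_bs & ~prev_bs & ~prev_punct
        F[rolled] = -0.5 * prev_hold[rolled]
    cog_gap = cur_bs | prev_bs | prev_punct
    F[cog_gap] = C[cog_gap]
    intra = cur_bs & prev_bs
    F[intra] = config.intra_burst_gap + rng.normal(0.0, 0.02, size=int(intra.sum()))
    np.clip(F, -2.0, None, out=F)

    # long breaks split the stream into sessions
    brk = rng.random(K) < 1.0 / config.session_keys_mean
    F = np.where(brk & ~is_first, F + 30.0 + rng.exponential(60.0, size=K), F)

    delta = F + prev_hold
    delta[is_first] = 0.0
    cs = np.cumsum(delta)
    press_rel = cs - cs[starts][day_of_key]  # seconds since day stream start

    start_s = rng.uniform(9 * 3600, 12 * 3600, size=D)
    press_ms = (
        (epoch_day0 + day_num[day_of_key]) * _MS_PER_DAY
        + ((start_s[day_of_key] + press_rel) * 1000.0).astype(np.int64)
    )
    release_ms = press_ms + (hold * 1000.0).astype(np.int64)

    token_codes = (np.arange(K) % 16).astype(np.int8)
    class_names = np.array(["alphanumeric", "backspace", "punctuation", "other"])
    subj_codes = subj_idx[day_of_key]

    ts_all = np.r_[press_ms, release_ms]
    subj_all = np.r_[subj_codes, subj_codes].astype(np.int32)
    order = np.lexsort((np.r_[np.zeros(K, np.int8), np.ones(K, np.int8)], ts_all, subj_all))
    ev = pd.DataFrame(
        {
            "subject_id": pd.Categorical.from_codes(
                subj_all[order], categories=list(subject_ids)
            ),
            "timestamp_ms": ts_all[order],
            "action": pd.Categorical.from_codes(
                np.r_[np.zeros(K, np.int8), np.ones(K, np.int8)][order],
                categories=["press", "release"],
            ),
            "key_class": pd.Categorical.from_codes(
                np.r_[cls, cls][order], categories=list(class_names)
            ),
            "key_token": pd.Categorical.from_codes(
                np.r_[token_codes, token_codes][order], categories=[f"k{i}" for i in range(16)]
            ),
        }
    )
    return ev


def simulate_day_events(
    motor_latent: float,
    cog_latent: float,
    n_events: int,
    seed: int | np.random.Generator,
    config: CohortConfig | None = None,
    subject_id: str = "S000",
    day_num: int = 0,
) -> pd.DataFrame:
    """One subject-day of synthetic press/release events.

    ``motor_latent`` is the target fine-motor cluster value of the day
    (the mean of the extracted PPL/RRL/FT daily values); ``cog_latent``
    the target cognition cluster value.  ``n_events`` counts press+release
    events, so the stream has ``n_events // 2`` key instances.
    """
    if n_events < 2:
        raise ValueError("n_events must be >= 2")
    config = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = config.hold_mean + rng.normal(0.0, config.hold_day_sd)
    epoch0 = int(np.datetime64(config.start_date, "D").astype(int))
    return _simulate_event_streams(
        subj_idx=np.array([0]),
        day_num=np.array([day_num]),
        n_keys=np.array([max(n_events // 2, 1)]),
        m_day=np.array([motor_latent]),
        c_day=np.array([cog_latent]),
        h_day=np.array([max(h, 0.03)]),
        subject_ids=np.array([subject_id]),
        config=config,
        rng=rng,
        epoch_day0=epoch0,
    )


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort: events, clinical visits, ground truth.

    Fully reproducible given ``(config, seed)``.  The ground-truth table
    records the latent cluster values per subject-visit and the
    person-means actually used in the clinical linkage (taken over
    retained visits, i.e. the hybrid-model estimand).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    n_occ = len(config.visit_labels)
    sched = np.asarray(config.visit_schedule_days)

    subject_ids = np.array([f"S{i:03d}" for i in range(n)])
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), *config.age_range)
    sex_male = rng.random(n) >= config.p_female
    edu_probs = np.asarray(config.education_probs, dtype=float)
    education_idx = rng.choice(3, size=n, p=edu_probs / edu_probs.sum())

    # latent baselines (log-normal across subjects: positive, right-skewed)
    motor_base = _lognormal_from_mean_sd(rng, config.fmsc_mean, config.fmsc_between_sd, n)
    edu_shift = np.asarray(config.cog_education_effects)[education_idx]
    cog_base = (
        _lognormal_from_mean_sd(
            rng, config.csc_mean - float(edu_shift.mean()), config.csc_between_sd, n
        )
        + edu_shift
    )
    motor_base = np.clip(motor_base, 0.08, None)
    cog_base = np.clip(cog_base, 0.15, None)

    occ_idx = np.arange(n_occ)
    motor_visit = np.clip(
        motor_base[:, None]
        + config.motor_trend_per_occasion * occ_idx[None, :]
        + rng.normal(0.0, config.motor_within_sd, size=(n, n_occ)),
        0.05,
        None,
    )
    cog_visit = np.clip(
        cog_base[:, None]
        + config.cog_trend_per_occasion * occ_idx[None, :]
        + rng.normal(0.0, config.cog_within_sd, size=(n, n_occ)),
        0.10,
        None,
    )

    start = pd.Timestamp(config.start_date)
    skeleton = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_occ),
            "visit_label": np.tile(config.visit_labels, n),
            "occasion_idx": np.tile(occ_idx, n),
            "visit_date": [
                (start + pd.Timedelta(days=int(d))).date() for _ in range(n) for d in sched
            ],
            "motor_latent": motor_visit.ravel(),
            "cog_latent": cog_visit.ravel(),
        }
    )
    retained = apply_missingness(
        skeleton,
        config.visit_missingness,
        rng,
        labels=config.visit_labels,
        dropout_hazard=config.dropout_hazard,
    )
    # person-means over retained visits = the hybrid-model estimand
    retained["motor_mean"] = retained.groupby("subject_id")["motor_latent"].transform("mean")
    retained["cog_mean"] = retained.groupby("subject_id")["cog_latent"].transform("mean")

    demo = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": np.round(age, 1),
            "sex_male": sex_male,
            "education_idx": education_idx,
        }
    )
    retained = retained.merge(demo, on="subject_id", how="left")
    scores = simulate_clinical_scores(retained, config, rng)

    edu_names = np.array(["low", "middle", "high"])
    visits = retained[["subject_id", "visit_label", "visit_date"]].copy()
    visits = visits.merge(scores, on=["subject_id", "visit_label"], how="left")
    visits["age"] = retained["age"].to_numpy()
    visits["sex"] = np.where(retained["sex_male"], "male", "female")
    visits["education"] = edu_names[retained["education_idx"].to_numpy(dtype=int)]

    # --- typing event streams -------------------------------------------
    days = _candidate_days(config)
    adherence = rng.beta(
        config.adherence_mean * config.adherence_concentration,
        (1.0 - config.adherence_mean) * config.adherence_concentration,
        size=n,
    )
    active = rng.random((n, len(days))) < adherence[:, None]
    subj_day_idx, day_pos = np.nonzero(active)
    day_num = days[day_pos]
    n_days_total = len(day_num)

    n_events_day = _lognormal_from_mean_sd(
        rng, config.events_per_day_mean, max(config.events_per_day_sd, 1e-6), n_days_total
    )
    n_keys = np.clip((n_events_day / 2.0).astype(int), 2, config.max_keys_per_day)

    nearest_occ = np.abs(day_num[:, None] - sched[None, :]).argmin(axis=1)
    m_day = motor_visit[subj_day_idx, nearest_occ]
    c_day = cog_visit[subj_day_idx, nearest_occ]
    hold_subject = config.hold_mean + rng.normal(0.0, config.hold_subject_sd, size=n)
    h_day = np.clip(
        hold_subject[subj_day_idx] + rng.normal(0.0, config.hold_day_sd, size=n_days_total),
        0.03,
        None,
    )

    epoch0 = int(np.datetime64(config.start_date, "D").astype(int))
    events = _simulate_event_streams(
        subj_idx=subj_day_idx,
        day_num=day_num,
        n_keys=n_keys,
        m_day=m_day,
        c_day=c_day,
        h_day=h_day,
        subject_ids=subject_ids,
        config=config,
        rng=rng,
        epoch_day0=epoch0,
    )

    ground_truth = retained[
        [
            "subject_id", "visit_label", "occasion_idx", "visit_date",
            "motor_latent", "cog_latent", "motor_mean", "cog_mean",
        ]
    ].copy()
    return SyntheticCohort(
        events=events[EVENT_COLUMNS],
        visits=visits,
        ground_truth=ground_truth,
        config=config,
        seed=seed,
    )
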