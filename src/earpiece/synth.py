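"""Synthetic cohort generator.

Produces survey-style participants and career-segments tables with the
statistical structure the analyses assume and with every generating
parameter recorded, so each pipeline stage has a parameter-recovery surface.

Default parameters emulate the published cohort: 4,498 respondents split
48% nonusers / 41% unilateral / 11% nonunilateral users; 57/43 right/left
device side; age ~ N(55.6, 8.6) with users about two years younger than
nonusers; 66% male; volume-control settings centred on 81% ("loud") and 51%
("normal") of full volume with the loud setting used ~48% of the time;
five-level TTS frequency responses drawn from a proportional-odds model on
the energy-weighted average volume; prolonged-tinnitus risk 13.1% in
nonusers and, among users, driven by TTS burden (ORs 2.8 and 3.0 for 1-100
and >100 instances against a 13.2% never-TTS baseline); 60% of tinnitus
central, with asymmetric tinnitus siding with the exposed ear with
probability 0.8 in unilateral users; and digits-in-noise thresholds with a
null exposure effect, ~83% task uptake, and a small bad-equipment stratum
that the 3-SD quality-control rule is meant to catch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import dosimetry

__all__ = [
    "GeneratorConfig",
    "CohortData",
    "generate_cohort",
    "generate_null_cohort",
    "generate_earwise_null",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "device_use",
    "device_side",
    "side_reason_contra_pathology",
    "tts_prop",
    "tin_long",
    "tin_location",
    "diagnosed_hl",
    "diagnosed_hl_laterality",
    "din_right",
    "din_left",
    "din_antiphasic",
    "excluded_prior_hl",
    "ear_tested_first",
]

SEGMENT_COLUMNS = [
    "participant_id",
    "segment_index",
    "duration_years",
    "hours_per_week",
    "prop_loud",
    "volume_loud",
    "volume_normal",
]

_TTS_LEVELS = ("Never", "Sometimes", "About half the time", "Most of the time", "Every time")


@dataclass(frozen=True)
class GeneratorConfig:
    """All distributions and true effect sizes for the synthetic cohort."""

    n: int = 4498
    # group structure
    p_nonuser: float = 0.48
    p_unilateral: float = 0.41
    p_nonunilateral: float = 0.11
    p_right_side: float = 0.57
    p_contra_pathology: float = 0.02
    # demographics
    age_mean: float = 55.6
    age_sd: float = 8.6
    age_user_shift: float = -2.0  # users' mean minus nonusers' mean, years
    p_male: float = 0.66
    # career model
    seg_extra_mean: float = 0.8  # Poisson mean for segments beyond the first
    years_total_min: float = 2.0
    years_total_max: float = 24.0
    hours_per_week_median: float = 25.5  # wearing time; x0.2 duty -> ~5.1 h exposure
    hours_per_week_sigma: float = 1.1  # log-scale SD (usage is strongly right-skewed)
    hours_per_week_cap: float = 80.0
    prop_loud_a: float = 2.4  # Beta(a, b): mean ~0.48
    prop_loud_b: float = 2.6
    volume_loud_mean: float = 81.0
    volume_loud_sd: float = 12.0
    volume_normal_mean: float = 51.0
    volume_normal_sd: float = 15.0
    # TTS ordinal model (proportional odds on centred volume average)
    tts_slope: float = 0.04  # log-odds per % volume
    tts_cutpoints: tuple[float, ...] = (0.1926, 2.8622, 3.2604, 4.8203)
    tts_volume_center: float = 73.0  # ~ the cohort's mean energy-weighted volume
    # tinnitus model
    tin_base_nonuser: float = 0.131
    tin_base_user: float = 0.132  # never-TTS users
    or_use: float = 1.0  # extra multiplicative odds for any user
    or_tts_1_100: float = 2.8
    or_tts_gt100: float = 3.0
    beta_age: float = 0.022  # log-odds per year
    p_central: float = 0.60
    concordance: float = 0.8  # P(tinnitus side == exposed side | asymmetric, unilateral)
    p_left_unexposed: float = 0.5  # left-side prob when no exposure drives the side
    # diagnosed hearing loss (stored, not analysed)
    p_diagnosed_hl: float = 0.102
    # DIN model
    din_completion: float = 0.834
    din_mean: float = -10.0
    din_personal_sd: float = 1.2
    din_meas_sd: float = 0.8
    right_ear_advantage: float = 0.0  # dB; >0 makes right-ear thresholds lower (better)
    din_exposure_effect: float = 0.0  # dB added to the exposed ear of unilateral users
    antiphasic_adv_mean: float = 6.0
    antiphasic_adv_sd: float = 1.0
    p_bad_equipment: float = 0.028
    bad_shift_db: float = 8.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        probs = (
            self.p_nonuser,
            self.p_unilateral,
            self.p_nonunilateral,
            self.p_right_side,
            self.p_contra_pathology,
            self.p_male,
            self.p_central,
            self.concordance,
            self.p_left_unexposed,
            self.p_diagnosed_hl,
            self.din_completion,
            self.p_bad_equipment,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(self.p_nonuser + self.p_unilateral + self.p_nonunilateral - 1) > 1e-9:
            raise ValueError("device-use fractions must sum to 1")

    def null(self) -> "GeneratorConfig":
        """Copy with every effect parameter at its no-effect value."""
        return dataclasses.replace(
            self,
            tts_slope=0.0,
            tin_base_user=self.tin_base_nonuser,
            or_use=1.0,
            or_tts_1_100=1.0,
            or_tts_gt100=1.0,
            concordance=0.5,
            din_exposure_effect=0.0,
        )


@dataclass
class CohortData:
    participants: pd.DataFrame
    segments: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False, float_format="%.4f")
        self.segments.to_csv(out / "segments.csv", index=False, float_format="%.4f")
        import json

        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def _segments_frame(cfg: GeneratorConfig, rng, user_ids: np.ndarray) -> pd.DataFrame:
    n_users = len(user_ids)
    if n_users == 0:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    nseg = 1 + np.minimum(rng.poisson(cfg.seg_extra_mean, n_users), 3)
    total_years = rng.uniform(cfg.years_total_min, cfg.years_total_max, n_users)
    pid = np.repeat(user_ids, nseg)
    owner = np.repeat(np.arange(n_users), nseg)
    # split each career's years across its segments with random weights
    w = rng.exponential(1.0, pid.size) + 0.05
    totals = np.bincount(owner, weights=w)
    years = total_years[owner] * w / totals[owner]
    years = np.maximum(years, 0.05)
    m = pid.size
    hours = np.exp(np.log(cfg.hours_per_week_median) + cfg.hours_per_week_sigma * rng.standard_normal(m))
    hours = np.clip(hours, 1.0, cfg.hours_per_week_cap)
    prop_loud = rng.beta(cfg.prop_loud_a, cfg.prop_loud_b, m)
    vol_loud = _truncnorm(rng, cfg.volume_loud_mean, cfg.volume_loud_sd, 2.0, 100.0, m)
    vol_norm = _truncnorm(rng, cfg.volume_normal_mean, cfg.volume_normal_sd, 2.0, 100.0, m)
    seg_index = np.concatenate([np.arange(k) for k in nseg])
    return pd.DataFrame(
        {
            "participant_id": pid,
            "segment_index": seg_index,
            "duration_years": years,
            "hours_per_week": hours,
            "prop_loud": prop_loud,
            "volume_loud": vol_loud,
            "volume_normal": vol_norm,
        }
    )


def _draw_tts_prop(cfg: GeneratorConfig, rng, volume_average: np.ndarray) -> np.ndarray:
    """Ordinal draw from the proportional-odds model the RQ3 analysis fits."""
    eta = cfg.tts_slope * (volume_average - cfg.tts_volume_center)
    cuts = np.asarray(cfg.tts_cutpoints)
    cum = expit(cuts[None, :] - eta[:, None])  # P(Y <= j), shape (n, 4)
    u = rng.random(volume_average.size)
    cat = (u[:, None] > cum).sum(axis=1)  # 0..4
    return np.array(_TTS_LEVELS, dtype=object)[cat]


def generate_cohort(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    curve: dosimetry.CalibrationCurve | None = None,
) -> CohortData:
    """Generate one synthetic cohort; fully reproducible from (config, seed)."""
    cfg = config or GeneratorConfig()
    curve = curve or dosimetry.default_calibration()
    rng = np.random.default_rng(seed)
    n = cfg.n
    ids = np.array([f"P{i:05d}" for i in range(n)], dtype=object)

    use = rng.choice(
        ["nonuser", "unilateral", "nonunilateral"],
        size=n,
        p=[cfg.p_nonuser, cfg.p_unilateral, cfg.p_nonunilateral],
    )
    is_user = use != "nonuser"
    is_uni = use == "unilateral"

    shift = cfg.age_user_shift
    age_means = np.where(is_user, cfg.age_mean + shift / 2.0, cfg.age_mean - shift / 2.0)
    age = np.clip(rng.normal(age_means, cfg.age_sd), 25.0, 90.0)
    sex = np.where(rng.random(n) < cfg.p_male, "male", "female")

    side = np.full(n, "", dtype=object)
    side[is_uni] = np.where(rng.random(is_uni.sum()) < cfg.p_right_side, "right", "left")
    contra = np.zeros(n, dtype=bool)
    contra[is_uni] = rng.random(is_uni.sum()) < cfg.p_contra_pathology

    segments = _segments_frame(cfg, rng, ids[is_user])

    # exposure-derived quantities the outcome models condition on
    expo = dosimetry.summarize_career_table(segments, curve)
    vol_avg = pd.Series(np.nan, index=ids, dtype=float)
    if len(expo):
        vol_avg.loc[expo.index] = expo["volume_average"].to_numpy(dtype=float)

    tts_prop = np.full(n, None, dtype=object)
    tts_prop[is_user] = _draw_tts_prop(cfg, rng, vol_avg.to_numpy()[is_user])

    # TTS burden (via the derivation rules) feeds the tinnitus model
    from . import derive as _derive

    shifts = _derive._shifts_table(segments)
    shifts_full = pd.Series(0, index=ids, dtype=float)
    shifts_full.loc[shifts.index] = shifts.to_numpy(dtype=float)
    mult = pd.Series(tts_prop, index=ids).map(_derive.TTS_MULTIPLIER)
    counts = np.floor(mult * shifts_full + 0.5)
    group = np.select(
        [counts == 0, counts <= 100, counts > 100], [0, 1, 2], default=0
    )

    base = np.where(is_user, cfg.tin_base_user, cfg.tin_base_nonuser)
    eta = logit(base) + cfg.beta_age * (age - cfg.age_mean)
    eta += np.where(is_user, np.log(cfg.or_use), 0.0)
    eta += np.where(is_user & (group == 1), np.log(cfg.or_tts_1_100), 0.0)
    eta += np.where(is_user & (group == 2), np.log(cfg.or_tts_gt100), 0.0)
    tin_long = rng.random(n) < expit(eta)

    tin_location = np.full(n, "none", dtype=object)
    has_tin = tin_long
    central = rng.random(n) < cfg.p_central
    tin_location[has_tin & central] = "central"
    asym = has_tin & ~central
    # asymmetric tinnitus: concordant with the exposed ear for unilateral
    # users, otherwise a (possibly biased) coin
    u = rng.random(n)
    left = np.where(
        asym & is_uni & (side == "left"),
        u < cfg.concordance,
        np.where(asym & is_uni, u >= cfg.concordance, u < cfg.p_left_unexposed),
    )
    tin_location[asym & left] = "left_only_or_mainly"
    tin_location[asym & ~left] = "right_only_or_mainly"

    diagnosed = rng.random(n) < cfg.p_diagnosed_hl
    hl_lat = np.full(n, "", dtype=object)
    hl_lat[diagnosed] = rng.choice(
        ["bilateral", "right", "left"], size=int(diagnosed.sum()), p=[0.6, 0.2, 0.2]
    )

    # DIN thresholds
    completed = rng.random(n) < cfg.din_completion
    personal = rng.normal(cfg.din_mean, cfg.din_personal_sd, n)
    t_right = personal - cfg.right_ear_advantage / 2.0
    t_left = personal + cfg.right_ear_advantage / 2.0
    if cfg.din_exposure_effect != 0.0:
        t_right = t_right + np.where(
            is_uni & (side == "right"), cfg.din_exposure_effect, 0.0
        )
        t_left = t_left + np.where(
            is_uni & (side == "left"), cfg.din_exposure_effect, 0.0
        )
    anti_adv = rng.normal(cfg.antiphasic_adv_mean, cfg.antiphasic_adv_sd, n)
    t_anti = np.minimum(t_right, t_left) - anti_adv
    noise = rng.normal(0.0, cfg.din_meas_sd, (3, n))
    bad = rng.random(n) < cfg.p_bad_equipment
    shift_db = np.where(bad, cfg.bad_shift_db, 0.0)
    din_r = t_right + noise[0] + shift_db
    din_l = t_left + noise[1] + shift_db
    din_a = t_anti + noise[2] + shift_db
    din_r = np.where(completed, np.round(din_r, 2), np.nan)
    din_l = np.where(completed, np.round(din_l, 2), np.nan)
    din_a = np.where(completed, np.round(din_a, 2), np.nan)
    first = np.where(
        completed, np.where(rng.random(n) < 0.5, "right", "left"), ""
    ).astype(object)

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "age": np.round(age, 1),
            "sex": sex,
            "device_use": use,
            "device_side": side,
            "side_reason_contra_pathology": contra,
            "tts_prop": tts_prop,
            "tin_long": tin_long,
            "tin_location": tin_location,
            "diagnosed_hl": diagnosed,
            "diagnosed_hl_laterality": hl_lat,
            "din_right": din_r,
            "din_left": din_l,
            "din_antiphasic": din_a,
            "excluded_prior_hl": np.zeros(n, dtype=bool),
            "ear_tested_first": first,
        },
        columns=PARTICIPANT_COLUMNS,
    )
    truth = {"seed": int(seed), "config": dataclasses.asdict(cfg)}
    truth["config"]["tts_cutpoints"] = list(cfg.tts_cutpoints)
    return CohortData(participants, segments, truth)


def generate_null_cohort(
    config: GeneratorConfig | None = None, seed: int = 0, **kwargs
) -> CohortData:
    """Cohort with all effect parameters at no-effect values (OR = 1, zero
    ordinal slope, 0.5 laterality concordance, zero DIN exposure effect)."""
    cfg = (config or GeneratorConfig()).null()
    return generate_cohort(cfg, seed=seed, **kwargs)


def generate_earwise_null(
    n_pairs: int, seed: int, p_right_side: float = 0.57
) -> pd.DataFrame:
    """Ear-wise records under the laterality null: tinnitus side assigned by
    fair coin, independent of the exposed side. Matches the RQ6 input schema."""
    rng = np.random.default_rng(seed)
    ids = np.array([f"E{i:05d}" for i in range(n_pairs)], dtype=object)
    exposed_side = np.where(rng.random(n_pairs) < p_right_side, "right", "left")
    tin_side = np.where(rng.random(n_pairs) < 0.5, "right", "left")
    rows = []
    for ear in ("right", "left"):
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": ids,
                    "ear": ear,
                    "exposed": exposed_side == ear,
                    "tin_present": tin_side == ear,
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["participant_id", "ear"], ignore_index=True
    )
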