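"""Derivation of registered analysis variables from raw survey rows.

Builds, from the participants and career-segments tables:

* exposure metrics (via :mod:`earpiece.dosimetry`),
* the temporary-threshold-shift variables (shift estimate, TTS count, TTS
  group),
* the pseudorandom side imputation for nonusers,
* the per-analysis sample exclusions,
* the ear-wise reshape for the tinnitus-laterality model,
* the exposed-minus-control DIN difference, and
* the 3-SD DIN quality-control exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import dosimetry
from .dosimetry import CalibrationCurve, CareerSegment, WORKING_YEAR_WEEKS

__all__ = [
    "TTS_LEVELS",
    "TTS_MULTIPLIER",
    "SHIFT_HOURS",
    "MAX_SHIFTS_PER_WEEK",
    "MissingDataError",
    "ContractViolation",
    "TTSSummary",
    "estimate_shifts",
    "tts_count",
    "tts_group",
    "impute_device_side",
    "attach_derived",
    "analysis_sample",
    "earwise_reshape",
    "digits_diff",
    "din_outlier_filter",
]

#: The five response options, in ordinal order, spelled as asked.
TTS_LEVELS = ["Never", "Sometimes", "About half the time", "Most of the time", "Every time"]

#: Proportion-of-shifts multiplier per response option. "About half the time"
#: is fixed at 0.5 by its wording; "Sometimes"/"Most of the time" use the
#: midpoints of their plain-language intervals and may be overridden.
TTS_MULTIPLIER = {
    "Never": 0.0,
    "Sometimes": 0.25,
    "About half the time": 0.5,
    "Most of the time": 0.75,
    "Every time": 1.0,
}

#: Assumed shift length (h) and ceiling on shifts/week for the shift-count
#: estimate: a standard full-time policing pattern.
SHIFT_HOURS = 8.0
MAX_SHIFTS_PER_WEEK = 5.0

USE_LEVELS = ("nonuser", "unilateral", "nonunilateral")
TIN_LOCATIONS = ("none", "central", "right_only_or_mainly", "left_only_or_mainly")
_ASYMMETRIC = ("right_only_or_mainly", "left_only_or_mainly")


class MissingDataError(ValueError):
    """A required field is absent for this derivation."""


class ContractViolation(RuntimeError):
    """A record reached an operation whose preconditions exclude it."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_shifts(
    segments: Iterable[CareerSegment],
    shift_hours: float = SHIFT_HOURS,
    max_shifts_per_week: float = MAX_SHIFTS_PER_WEEK,
) -> int:
    """Estimated number of work shifts during which an ear-piece was worn.

    Per segment: years x 47 working weeks x min(hours_per_week / shift length,
    shifts/week ceiling); summed and rounded half-up.
    """
    total = 0.0
    for seg in segments:
        total += (
            seg.duration_years
            * WORKING_YEAR_WEEKS
            * min(seg.hours_per_week / shift_hours, max_shifts_per_week)
        )
    return _round_half_up(total)


def _shifts_table(
    segments: pd.DataFrame,
    shift_hours: float = SHIFT_HOURS,
    max_shifts_per_week: float = MAX_SHIFTS_PER_WEEK,
) -> pd.Series:
    if segments.empty:
        return pd.Series(dtype=float, name="shifts_estimate")
    per_week = np.minimum(
        segments["hours_per_week"].to_numpy(float) / shift_hours, max_shifts_per_week
    )
    raw = segments["duration_years"].to_numpy(float) * WORKING_YEAR_WEEKS * per_week
    s = pd.Series(raw, index=segments["participant_id"]).groupby(level=0).sum()
    return np.floor(s + 0.5).astype(int).rename("shifts_estimate")


def tts_count(tts_prop: str, shifts: int, multiplier: dict[str, float] | None = None) -> int:
    """Estimated instances of post-shift TTS signs: shifts x option multiplier."""
    if tts_prop is None or (isinstance(tts_prop, float) and math.isnan(tts_prop)):
        raise MissingDataError("tts_prop is absent (nonuser or missing response)")
    table = TTS_MULTIPLIER if multiplier is None else multiplier
    if tts_prop not in table:
        raise MissingDataError(f"unknown TTS response option: {tts_prop!r}")
    return _round_half_up(table[tts_prop] * shifts)


def tts_group(count: int) -> str:
    """Three-level ordinal grouping of the TTS count: none / 1-100 / >100."""
    if count < 0:
        raise ValueError("TTS count cannot be negative")
    if count == 0:
        return "none"
    return "1-100" if count <= 100 else ">100"


@dataclass(frozen=True)
class TTSSummary:
    tts_count: int
    tts_group: str
    shifts_estimate: int


def summarize_tts(tts_prop: str, segments: Sequence[CareerSegment]) -> TTSSummary:
    shifts = estimate_shifts(segments)
    count = tts_count(tts_prop, shifts)
    return TTSSummary(count, tts_group(count), shifts)


def impute_device_side(
    nonuser_ids: Sequence, seed: int, p_right: float = 0.57
) -> dict:
    """Pseudorandom right/left assignment for nonusers.

    Exactly ``round(p_right * n)`` ids (round-half-even) are assigned "right",
    the remainder "left"; which ids get which is a seeded permutation, so the
    assignment is reproducible.
    """
    ids = list(nonuser_ids)
    n = len(ids)
    if n == 0:
        return {}
    n_right = round(p_right * n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return {ids[j]: ("right" if k < n_right else "left") for k, j in enumerate(order)}


def attach_derived(
    participants: pd.DataFrame,
    segments: pd.DataFrame,
    curve: CalibrationCurve,
    seed: int,
    p_right_impute: float = 0.57,
) -> pd.DataFrame:
    """Return a copy of ``participants`` with all derived analysis columns.

    Adds: device_noise, exposure_hours, weeks_of_use, weekly_level,
    volume_average, avg_level_during_exposure, shifts_estimate, tts_count,
    tts_group, device_side_full (reported side, imputed for nonusers),
    device_side_imputed (flag), digits_diff, din_complete.

    The imputed sides reproduce the right/left proportions observed among
    unilateral users by default (p_right_impute).
    """
    df = participants.copy()
    expo = dosimetry.summarize_career_table(segments, curve)
    df = df.merge(expo, how="left", left_on="participant_id", right_index=True)
    df["device_noise"] = df["device_noise"].fillna(0.0)
    df["exposure_hours"] = df["exposure_hours"].fillna(0.0)
    df["weeks_of_use"] = df["weeks_of_use"].fillna(0.0)

    shifts = _shifts_table(segments)
    df = df.merge(shifts, how="left", left_on="participant_id", right_index=True)
    df["shifts_estimate"] = df["shifts_estimate"].fillna(0).astype(int)

    is_user = df["device_use"] != "nonuser"
    mult = df["tts_prop"].map(TTS_MULTIPLIER)
    df["tts_count"] = np.where(
        is_user & mult.notna(),
        np.floor(mult * df["shifts_estimate"] + 0.5),
        np.nan,
    )
    df["tts_group"] = pd.Series(
        np.select(
            [df["tts_count"] == 0, df["tts_count"] <= 100, df["tts_count"] > 100],
            ["none", "1-100", ">100"],
            default=None,
        ),
        index=df.index,
        dtype=object,
    )

    nonuser_ids = df.loc[df["device_use"] == "nonuser", "participant_id"].tolist()
    imputed = impute_device_side(nonuser_ids, seed=seed, p_right=p_right_impute)
    df["device_side_full"] = df["device_side"]
    df.loc[df["device_use"] == "nonuser", "device_side_full"] = [
        imputed[i] for i in nonuser_ids
    ]
    df["device_side_imputed"] = df["device_use"] == "nonuser"

    df["din_complete"] = (
        df["din_right"].notna() & df["din_left"].notna() & df["din_antiphasic"].notna()
    )
    df["digits_diff"] = digits_diff(df)
    return df


def digits_diff(df: pd.DataFrame) -> pd.Series:
    """Exposed-ear DIN threshold minus control-ear DIN threshold (dB SNR).

    Positive values indicate poorer performance in the exposed ear. NaN where
    either monaural threshold or the (possibly imputed) side is missing.
    """
    side = df["device_side_full"] if "device_side_full" in df else df["device_side"]
    exposed = np.where(side == "right", df["din_right"], df["din_left"])
    control = np.where(side == "right", df["din_left"], df["din_right"])
    out = pd.Series(exposed - control, index=df.index, name="digits_diff")
    out[~side.isin(["right", "left"])] = np.nan
    return out


_ANALYSES = ("RQ3", "RQ4", "RQ5", "RQ6", "RQ7")


def analysis_sample(df: pd.DataFrame, analysis: str) -> tuple[pd.DataFrame, dict]:
    """Apply the registered sample-exclusion rules for one analysis.

    Returns the filtered frame and a per-rule exclusion-count log. RQ3/RQ5
    keep ear-piece users only; RQ4/RQ7 drop nonunilateral users and
    unilateral users who chose their ear because of contralateral pathology;
    RQ6 additionally keeps only users with noncentral (asymmetric) tinnitus.
    """
    if analysis not in _ANALYSES:
        raise ValueError(f"unknown analysis label {analysis!r}; expected one of {_ANALYSES}")
    out = df
    log: dict[str, int] = {"input": len(df)}
    contra = (out["device_use"] == "unilateral") & (
        out["side_reason_contra_pathology"].fillna(False).astype(bool)
    )
    if analysis in ("RQ3", "RQ5"):
        keep = out["device_use"] != "nonuser"
        log["excluded_nonuser"] = int((~keep).sum())
        out = out[keep]
    elif analysis in ("RQ4", "RQ7"):
        keep = out["device_use"] != "nonunilateral"
        log["excluded_nonunilateral"] = int((~keep).sum())
        out = out[keep]
        keep = ~contra.loc[out.index]
        log["excluded_contra_pathology"] = int((~keep).sum())
        out = out[keep]
    else:  # RQ6
        keep = out["device_use"] == "unilateral"
        log["excluded_non_unilateral_user"] = int((~keep).sum())
        out = out[keep]
        keep = ~contra.loc[out.index]
        log["excluded_contra_pathology"] = int((~keep).sum())
        out = out[keep]
        keep = out["tin_location"].isin(_ASYMMETRIC)
        log["excluded_no_asymmetric_tinnitus"] = int((~keep).sum())
        out = out[keep]
    log["analysed"] = len(out)
    return out.copy(), log


def earwise_reshape(df: pd.DataFrame) -> pd.DataFrame:
    """Reshape RQ6-filtered participants to two ear-wise rows each.

    Output columns: participant_id, ear (right/left), exposed (this ear wore
    the device), tin_present (this ear is the predominant tinnitus location).
    Exactly one exposed and one tinnitus-present row per participant.
    """
    bad = ~df["tin_location"].isin(_ASYMMETRIC)
    if bad.any():
        raise ContractViolation(
            "earwise_reshape received records without asymmetric tinnitus; "
            "apply the RQ6 sample filter first"
        )
    if not df["device_side"].isin(["right", "left"]).all():
        raise ContractViolation("earwise_reshape requires a reported device side")
    tin_side = df["tin_location"].map(
        {"right_only_or_mainly": "right", "left_only_or_mainly": "left"}
    )
    rows = []
    for ear in ("right", "left"):
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": df["participant_id"].to_numpy(),
                    "ear": ear,
                    "exposed": (df["device_side"] == ear).to_numpy(),
                    "tin_present": (tin_side == ear).to_numpy(),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["participant_id", "ear"], ignore_index=True)


DIN_CONDITIONS = ("din_right", "din_left", "din_antiphasic")


def din_outlier_filter(
    df: pd.DataFrame, n_sd: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Single-pass 3-SD DIN quality-control exclusion.

    Per-condition mean and SD are computed once over all complete records
    (all three thresholds present). A participant is excluded if any of their
    three thresholds lies strictly outside mean +/- ``n_sd`` x SD for its
    condition; exclusion removes all of that participant's DIN data.

    Returns (kept, excluded, stats): kept/excluded partition the complete
    records; stats holds the per-condition mean and SD used.
    """
    complete = df[
        df["din_right"].notna() & df["din_left"].notna() & df["din_antiphasic"].notna()
    ]
    if len(complete) < 2:
        raise ValueError("need >= 2 complete DIN records to compute a sample SD")
    stats = pd.DataFrame(
        {
            "mean": [complete[c].mean() for c in DIN_CONDITIONS],
            "sd": [complete[c].std(ddof=1) for c in DIN_CONDITIONS],
        },
        index=DIN_CONDITIONS,
    )
    out = np.zeros(len(complete), dtype=bool)
    for c in DIN_CONDITIONS:
        m, s = stats.loc[c, "mean"], stats.loc[c, "sd"]
        out |= (complete[c] - m).abs().to_numpy() > n_sd * s
    return complete[~out].copy(), complete[out].copy(), stats
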