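"""Input schemas, validation and run manifests.

CSV dialect: UTF-8, comma-separated, mandatory header, ``.`` decimal,
empty field = missing. The validator type/range-checks every column,
enforces the cross-field invariants of the participants schema, and applies
the survey-consistency rule that flags careers whose total reported
ear-piece years exceed a cap (default 25) as inconsistent (excludable).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .derive import TTS_LEVELS, TIN_LOCATIONS, USE_LEVELS

__all__ = [
    "PARTICIPANT_COLUMNS",
    "SEGMENT_COLUMNS",
    "ValidationIssue",
    "ValidationReport",
    "read_participants",
    "read_segments",
    "validate_participants",
    "validate_segments",
    "validate_files",
    "RunManifest",
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

#: Survey-consistency cap on total reported career ear-piece years.
CAREER_YEARS_CAP = 25.0

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False, "yes": True, "no": False,
    True: True, False: False, 1: True, 0: False, 1.0: True, 0.0: False,
}


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    row: int | None  # 0-based data-row index; None for table-level issues
    column: str | None
    message: str
    kind: str  # "error" | "flag"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    n_participants: int = 0
    n_segments: int = 0
    inconsistent_ids: list = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.kind == "error"]

    @property
    def flags(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.kind == "flag"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)
        self.inconsistent_ids.extend(other.inconsistent_ids)

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "n_participants": self.n_participants,
            "n_segments": self.n_segments,
            "n_errors": len(self.errors),
            "n_flags": len(self.flags),
            "inconsistent_ids": list(self.inconsistent_ids),
            "issues": [asdict(i) for i in self.issues],
        }


def _coerce_bool(s: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return pd.NA
        key = v.strip().lower() if isinstance(v, str) else v
        return _BOOL_MAP.get(key, pd.NA)

    return s.map(conv)


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read a participants CSV, coercing booleans and keeping missing as NaN."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    for col in ("side_reason_contra_pathology", "tin_long", "diagnosed_hl", "excluded_prior_hl"):
        if col in df.columns:
            df[col] = _coerce_bool(df[col])
    for col in ("device_side", "diagnosed_hl_laterality", "ear_tested_first"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def read_segments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> list[ValidationIssue]:
    missing = [c for c in required if c not in df.columns]
    return [
        ValidationIssue(table, None, c, f"required column {c!r} is missing", "error")
        for c in missing
    ]


def _range_issues(df, table, column, lo, hi, lo_open=False) -> list[ValidationIssue]:
    issues = []
    vals = pd.to_numeric(df[column], errors="coerce")
    bad_type = df[column].notna() & vals.isna()
    low = (vals <= lo) if lo_open else (vals < lo)
    for idx in df.index[bad_type]:
        issues.append(ValidationIssue(table, int(idx), column, "not numeric", "error"))
    for idx in df.index[(low | (vals > hi)).fillna(False)]:
        bound = f"({lo}, {hi}]" if lo_open else f"[{lo}, {hi}]"
        issues.append(
            ValidationIssue(table, int(idx), column, f"value {vals[idx]} outside {bound}", "error")
        )
    return issues


def validate_participants(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport(n_participants=len(df))
    rep.issues += _require_columns(df, PARTICIPANT_COLUMNS, "participants")
    if rep.errors:
        return rep
    if df["participant_id"].duplicated().any():
        for idx in df.index[df["participant_id"].duplicated()]:
            rep.issues.append(
                ValidationIssue("participants", int(idx), "participant_id", "duplicate id", "error")
            )
    rep.issues += _range_issues(df, "participants", "age", 16, 110)
    for col, allowed in (
        ("sex", {"male", "female"}),
        ("device_use", set(USE_LEVELS)),
    ):
        bad = df[col].notna() & ~df[col].isin(allowed)
        for idx in df.index[bad]:
            rep.issues.append(
                ValidationIssue(
                    "participants", int(idx), col,
                    f"value {df.loc[idx, col]!r} not in {sorted(allowed)}", "error",
                )
            )
    tts_bad = df["tts_prop"].notna() & ~df["tts_prop"].isin(TTS_LEVELS)
    for idx in df.index[tts_bad]:
        rep.issues.append(
            ValidationIssue(
                "participants", int(idx), "tts_prop",
                f"unknown response option {df.loc[idx, 'tts_prop']!r}", "error",
            )
        )
    loc_bad = df["tin_location"].notna() & ~df["tin_location"].isin(TIN_LOCATIONS)
    for idx in df.index[loc_bad]:
        rep.issues.append(
            ValidationIssue(
                "participants", int(idx), "tin_location",
                f"unknown location {df.loc[idx, 'tin_location']!r}", "error",
            )
        )
    # cross-field invariants
    side = df["device_side"].replace("", pd.NA)
    uni = df["device_use"] == "unilateral"
    for idx in df.index[uni & side.isna()]:
        rep.issues.append(
            ValidationIssue("participants", int(idx), "device_side",
                            "unilateral user without a device side", "error")
        )
    for idx in df.index[~uni & side.notna()]:
        rep.issues.append(
            ValidationIssue("participants", int(idx), "device_side",
                            "device side reported for a non-unilateral record", "error")
        )
    tin = df["tin_long"].fillna(False).astype(bool)
    loc_none = df["tin_location"].fillna("none") == "none"
    for idx in df.index[tin & loc_none]:
        rep.issues.append(
            ValidationIssue("participants", int(idx), "tin_location",
                            "tinnitus present but location is 'none'", "error")
        )
    for idx in df.index[~tin & ~loc_none]:
        rep.issues.append(
            ValidationIssue("participants", int(idx), "tin_location",
                            "tinnitus location given without tinnitus", "error")
        )
    nonuser = df["device_use"] == "nonuser"
    for idx in df.index[nonuser & df["tts_prop"].notna()]:
        rep.issues.append(
            ValidationIssue("participants", int(idx), "tts_prop",
                            "TTS response present for a nonuser", "error")
        )
    return rep


def validate_segments(
    df: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    career_years_cap: float = CAREER_YEARS_CAP,
) -> ValidationReport:
    rep = ValidationReport(n_segments=len(df))
    rep.issues += _require_columns(df, SEGMENT_COLUMNS, "segments")
    if rep.errors:
        return rep
    rep.issues += _range_issues(df, "segments", "duration_years", 0, 100, lo_open=True)
    rep.issues += _range_issues(df, "segments", "hours_per_week", 0, 168, lo_open=True)
    rep.issues += _range_issues(df, "segments", "prop_loud", 0, 1)
    rep.issues += _range_issues(df, "segments", "volume_loud", 0, 100)
    rep.issues += _range_issues(df, "segments", "volume_normal", 0, 100)
    inverted = df["volume_loud"] < df["volume_normal"]
    for idx in df.index[inverted.fillna(False)]:
        rep.issues.append(
            ValidationIssue("segments", int(idx), "volume_loud",
                            "loud setting below normal setting (accepted)", "flag")
        )
    totals = df.groupby("participant_id")["duration_years"].sum()
    over = totals[totals > career_years_cap]
    for pid, yrs in over.items():
        rep.inconsistent_ids.append(pid)
        rep.issues.append(
            ValidationIssue("segments", None, "duration_years",
                            f"participant {pid}: total career years {yrs:.1f} "
                            f"exceed {career_years_cap:g} (inconsistent)", "flag")
        )
    if participants is not None:
        known = set(participants["participant_id"])
        orphan = ~df["participant_id"].isin(known)
        for idx in df.index[orphan]:
            rep.issues.append(
                ValidationIssue("segments", int(idx), "participant_id",
                                f"unknown participant {df.loc[idx, 'participant_id']!r}", "error")
            )
        users = set(
            participants.loc[participants["device_use"] != "nonuser", "participant_id"]
        )
        nonuser_with_segments = set(df["participant_id"]) & (known - users)
        for pid in sorted(nonuser_with_segments):
            rep.issues.append(
                ValidationIssue("segments", None, "participant_id",
                                f"nonuser {pid} has career segments", "error")
            )
    return rep


def validate_files(
    participants_path: str | Path,
    segments_path: str | Path,
    calibration_path: str | Path | None = None,
    career_years_cap: float = CAREER_YEARS_CAP,
) -> ValidationReport:
    """Validate the three input files together; parse errors surface with the
    offending row number via pandas' error message."""
    from .dosimetry import CalibrationCurve, DosimetryDomainError

    participants = read_participants(participants_path)
    segments = read_segments(segments_path)
    rep = validate_participants(participants)
    rep.n_segments = len(segments)
    rep.extend(validate_segments(segments, participants, career_years_cap))
    if calibration_path is not None:
        try:
            CalibrationCurve.from_csv(calibration_path)
        except DosimetryDomainError as exc:
            rep.issues.append(
                ValidationIssue("calibration", None, None, str(exc), "error")
            )
    return rep


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Audit record for one pipeline run: input digests, seed, and the
    row-count deltas at every stage boundary, so each reported n is
    derivable from the counts."""

    input_digests: dict
    seed: int
    package_version: str
    stage_counts: dict

    @classmethod
    def build(cls, files: dict, seed: int, stage_counts: dict) -> "RunManifest":
        from . import __version__

        digests = {name: _sha256(p) for name, p in files.items() if p is not None}
        return cls(digests, int(seed), __version__, stage_counts)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
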