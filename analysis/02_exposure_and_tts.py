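#!/usr/bin/env python
"""Exposure descriptives (RQ1) and TTS frequency table (RQ2).

Reads the cohort from results/cohort/ (run 01 first), derives the exposure
metrics, and writes the weekly-level summary, the five-option TTS response
table with Sison-Glaz simultaneous CIs, and the corresponding figures.
"""

import json
from pathlib import Path

from earpiece import analyses, derive, dosimetry, figures, validate

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260930


def main() -> None:
    participants = validate.read_participants(ROOT / "cohort" / "participants.csv")
    segments = validate.read_segments(ROOT / "cohort" / "segments.csv")
    curve = dosimetry.CalibrationCurve.from_csv(ROOT / "cohort" / "calibration.csv")
    derived = derive.attach_derived(participants, segments, curve, seed=SEED + 1)

    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)

    rq1 = analyses.run_analysis(derived, "RQ1")
    (out / "rq1_weekly_levels.json").write_text(json.dumps(rq1, indent=2, default=str))
    print(
        f"RQ1 (n={rq1['n']}): median weekly level {rq1['median_weekly_level']:.1f} dBA, "
        f"{100 * rq1['frac_above_action_value']:.1f}% above 85 dBA;\n"
        f"  median weekly exposure {rq1['median_weekly_exposure_hours']:.1f} h at a median "
        f"{rq1['median_level_during_exposure']:.1f} dBA during exposure"
    )

    rq2 = analyses.run_analysis(derived, "RQ2")
    rq2["table"].round(1).to_csv(out / "rq2_tts_table.csv", index=False)
    s = rq2["summary"]
    print(
        f"RQ2 (n={s['n']}): {s['pct_ever']:.1f}% ever experienced TTS signs, "
        f"{s['pct_half_or_more']:.1f}% after at least half of shifts, "
        f"{s['pct_every_time']:.1f}% after every shift"
    )

    figdir = ROOT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    figures.fig_weekly_levels(derived).savefig(figdir / "fig1_weekly_levels.png", dpi=150)
    figures.fig_volume_by_tts(derived).savefig(figdir / "fig2_volume_by_tts.png", dpi=150)
    print(f"tables -> {out}, figures -> {figdir}")


if __name__ == "__main__":
    main()
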