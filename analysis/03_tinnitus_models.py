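#!/usr/bin/env python
"""Tinnitus analyses: TTS vs volume (RQ3), tinnitus vs use (RQ4), tinnitus
vs TTS burden (RQ5), and the ear-wise laterality model (RQ6).

Writes the fit results as JSON plus a tidy estimates table, and the
prevalence figures. The laterality model is the study's decisive piece:
because each participant contributes an exposed and a control ear, a
within-pair association between tinnitus side and ear-piece side cannot be
produced by person-level confounding.
"""

import json
from pathlib import Path

import pandas as pd

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
    rows = []
    for rq in ("RQ3", "RQ4", "RQ5", "RQ6"):
        fr = analyses.run_analysis(derived, rq)
        (out / f"{rq.lower()}_fit.json").write_text(json.dumps(fr.to_dict(), indent=2))
        for e in fr.estimates:
            rows.append({"analysis": rq, "term": e.term, "estimate": e.estimate,
                         "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p,
                         "scale": fr.scale, "n": fr.n_used})
    pd.DataFrame(rows).to_csv(out / "tinnitus_estimates.csv", index=False)

    for row in rows:
        print(
            f"{row['analysis']:4s} {row['term']:>14s}: {row['estimate']:6.3f} "
            f"({row['ci_low']:.3f} to {row['ci_high']:.3f}), p = {row['p']:.2g} "
            f"[{row['scale']}, n={row['n']}]"
        )

    figdir = ROOT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    figures.fig_tinnitus_prevalence(derived).savefig(
        figdir / "fig3_tinnitus_prevalence.png", dpi=150
    )
    figures.fig_tinnitus_location(derived).savefig(
        figdir / "fig4_tinnitus_location.png", dpi=150
    )
    print(f"tables -> {out}, figures -> {figdir}")


if __name__ == "__main__":
    main()
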