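#!/usr/bin/env python
"""Scaled-down operating-characteristics check of the registered models.

Runs a small parameter-recovery study (CI coverage of generating values)
and a small type-I-error study (rejection under null cohorts) and prints
the rates. The full-scale versions (200 recovery replicates, 1,000 null
replicates) live in the test suite; this driver gives a quick desk view.
"""

from pathlib import Path

import json

from earpiece import analyses, derive, dosimetry, synth

ROOT = Path(__file__).resolve().parents[1] / "results"
CURVE = dosimetry.default_calibration()
REPS = 40
N = 4500


def recovery() -> dict:
    cfg_a = synth.GeneratorConfig(n=N, or_use=1.7, or_tts_1_100=1.0, or_tts_gt100=1.0,
                                  tin_base_user=0.131, concordance=0.8)
    cfg_b = synth.GeneratorConfig(n=N, or_use=1.0, tin_base_user=0.131,
                                  or_tts_1_100=2.8, or_tts_gt100=3.0)
    hits = {"rq4_or_1.7": 0, "rq5_or_2.8": 0, "rq5_or_3.0": 0,
            "rq6_conc_0.8": 0, "rq7_null": 0}
    for r in range(REPS):
        ca = synth.generate_cohort(cfg_a, seed=70_000 + 2 * r)
        da = derive.attach_derived(ca.participants, ca.segments, CURVE, seed=70_000 + 2 * r)
        e = analyses.run_analysis(da, "RQ4").term("user")
        hits["rq4_or_1.7"] += e.ci_low <= 1.7 <= e.ci_high
        e = analyses.run_analysis(da, "RQ6").term("exposed")
        hits["rq6_conc_0.8"] += e.ci_low <= 4.0 <= e.ci_high
        e = analyses.run_analysis(da, "RQ7").term("user")
        hits["rq7_null"] += e.ci_low <= 0.0 <= e.ci_high
        cb = synth.generate_cohort(cfg_b, seed=70_001 + 2 * r)
        db = derive.attach_derived(cb.participants, cb.segments, CURVE, seed=70_001 + 2 * r)
        fr = analyses.run_analysis(db, "RQ5")
        hits["rq5_or_2.8"] += fr.term("tts_1_100").ci_low <= 2.8 <= fr.term("tts_1_100").ci_high
        hits["rq5_or_3.0"] += fr.term("tts_gt100").ci_low <= 3.0 <= fr.term("tts_gt100").ci_high
    return {k: v / REPS for k, v in hits.items()}


def type_i() -> dict:
    cfg = synth.GeneratorConfig(n=N).null()
    rej = {"rq3": 0, "rq4": 0, "rq5": 0, "rq6": 0, "rq7": 0}
    for r in range(REPS):
        c = synth.generate_cohort(cfg, seed=80_000 + r)
        df = derive.attach_derived(c.participants, c.segments, CURVE, seed=80_000 + r)
        rej["rq3"] += analyses.run_analysis(df, "RQ3").term("volume_average").p < 0.05
        rej["rq4"] += analyses.run_analysis(df, "RQ4").term("user").p < 0.05
        rej["rq5"] += analyses.run_analysis(df, "RQ5").term("tts_gt100").p < 0.05
        rej["rq7"] += analyses.run_analysis(df, "RQ7").term("user").p < 0.05
        ears = synth.generate_earwise_null(150, seed=80_000 + r)
        rej["rq6"] += analyses.rq6_earwise(ears).term("exposed").p < 0.05
    return {k: v / REPS for k, v in rej.items()}


def main() -> None:
    cov = recovery()
    print(f"CI coverage of generating values over {REPS} cohorts of n={N}:")
    for k, v in cov.items():
        print(f"  {k:12s}: {v:.2f}")
    rates = type_i()
    print(f"type-I rejection at alpha=.05 over {REPS} null cohorts:")
    for k, v in rates.items():
        print(f"  {k:4s}: {v:.3f}")
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    (out / "operating_characteristics.json").write_text(
        json.dumps({"reps": REPS, "n": N, "coverage": cov, "type_i": rates}, indent=2)
    )
    print(f"-> {out / 'operating_characteristics.json'}")


if __name__ == "__main__":
    main()
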