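"""Reproducible figures mirroring the study's Results graphics.

Each function takes the derived cohort frame and returns a matplotlib
Figure: weekly-level histogram against the 85-dBA action value, volume by
TTS-frequency boxplots, tinnitus-prevalence bars (by use and by TTS
burden), tinnitus-location prevalence by exposure group, and the DIN
threshold boxplots with the between-ear difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import derive

__all__ = [
    "fig_weekly_levels",
    "fig_volume_by_tts",
    "fig_tinnitus_prevalence",
    "fig_tinnitus_location",
    "fig_din_thresholds",
    "save_all",
]


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (0.0, 0.0)
    p = k / n
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def fig_weekly_levels(df: pd.DataFrame, action_value: float = 85.0):
    levels = df["weekly_level"].dropna()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(levels, bins=30, color="#4878a8", edgecolor="white")
    ax.axvline(action_value, color="red", linestyle=":", label=f"{action_value:g} dBA action value")
    ax.set_xlabel("Weekly-averaged noise-exposure level (dBA)")
    ax.set_ylabel("Ear-piece users")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def fig_volume_by_tts(df: pd.DataFrame):
    users = df[df["tts_prop"].notna() & df["volume_average"].notna()]
    groups = [
        users.loc[users["tts_prop"] == lvl, "volume_average"] for lvl in derive.TTS_LEVELS
    ]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(groups, tick_labels=derive.TTS_LEVELS, whis=1.5, showfliers=False)
    ax.set_ylabel("Average volume-control setting (%)")
    ax.set_xlabel("Frequency of TTS signs after ear-piece use")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    return fig


def fig_tinnitus_prevalence(df: pd.DataFrame):
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    use = [("Nonusers", df["device_use"] == "nonuser"), ("Users", df["device_use"] != "nonuser")]
    # panel a: users vs nonusers; panel b: users by TTS burden
    panels = [
        ("Ear-piece use", use),
        (
            "TTS burden (users)",
            [
                ("No TTS", df["tts_group"] == "none"),
                ("1–100", df["tts_group"] == "1-100"),
                (">100", df["tts_group"] == ">100"),
            ],
        ),
    ]
    for ax, (title, groups) in zip(axes, panels):
        xs, ps, errs = [], [], []
        for i, (label, mask) in enumerate(groups):
            sub = df.loc[mask, "tin_long"].dropna().astype(bool)
            k, n = int(sub.sum()), len(sub)
            p = k / n if n else 0.0
            lo, hi = _binom_ci(k, n)
            xs.append(i)
            ps.append(100 * p)
            errs.append((100 * (p - lo), 100 * (hi - p)))
        ax.bar(xs, ps, color="#4878a8")
        ax.errorbar(
            xs, ps, yerr=np.array(errs).T, fmt="none", ecolor="black", capsize=4
        )
        ax.set_xticks(xs)
        ax.set_xticklabels([g[0] for g in groups])
        ax.set_title(title)
    axes[0].set_ylabel("Prolonged spontaneous tinnitus (%)")
    fig.tight_layout()
    return fig


def fig_tinnitus_location(df: pd.DataFrame):
    groups = [
        ("Nonusers", df["device_use"] == "nonuser"),
        ("Right-side users", (df["device_use"] == "unilateral") & (df["device_side"] == "right")),
        ("Left-side users", (df["device_use"] == "unilateral") & (df["device_side"] == "left")),
    ]
    locations = [
        ("central", "Central", "#888888"),
        ("right_only_or_mainly", "Only/mainly right", "#c0392b"),
        ("left_only_or_mainly", "Only/mainly left", "#2e6da4"),
    ]
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.25
    for j, (loc, label, color) in enumerate(locations):
        xs, ps, errs = [], [], []
        for i, (_, mask) in enumerate(groups):
            n = int(mask.sum())
            k = int(((df["tin_location"] == loc) & mask).sum())
            p = k / n if n else 0.0
            lo, hi = _binom_ci(k, n)
            xs.append(i + (j - 1) * width)
            ps.append(100 * p)
            errs.append((100 * (p - lo), 100 * (hi - p)))
        ax.bar(xs, ps, width=width, label=label, color=color)
        ax.errorbar(xs, ps, yerr=np.array(errs).T, fmt="none", ecolor="black", capsize=3)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([g[0] for g in groups])
    ax.set_ylabel("Prevalence (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def fig_din_thresholds(df: pd.DataFrame):
    users = df[(df["device_use"] == "unilateral") & df["din_complete"]]
    non = df[(df["device_use"] == "nonuser") & df["din_complete"]]
    exposed = np.where(users["device_side"] == "right", users["din_right"], users["din_left"])
    control = np.where(users["device_side"] == "right", users["din_left"], users["din_right"])
    both_avg = (non["din_right"] + non["din_left"]) / 2.0
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].boxplot(
        [exposed, control, both_avg],
        tick_labels=["Exposed ear", "Control ear", "Nonusers\n(both-ear mean)"],
        whis=1.5,
        showfliers=False,
    )
    axes[0].set_ylabel("DIN threshold (dB SNR)")
    diff = users["digits_diff"].dropna()
    axes[1].boxplot([diff], tick_labels=["DigitsDiff (users)"], whis=1.5, showfliers=False)
    axes[1].axhline(0.0, color="grey", linewidth=0.8)
    axes[1].set_ylabel("Exposed − control threshold (dB SNR)")
    fig.tight_layout()
    return fig


def save_all(df: pd.DataFrame, out_dir) -> list[str]:
    """Write all five figures as PNGs under ``out_dir``; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    makers = {
        "fig1_weekly_levels.png": fig_weekly_levels,
        "fig2_volume_by_tts.png": fig_volume_by_tts,
        "fig3_tinnitus_prevalence.png": fig_tinnitus_prevalence,
        "fig4_tinnitus_location.png": fig_tinnitus_location,
        "fig5_din_thresholds.png": fig_din_thresholds,
    }
    paths = []
    for name, fn in makers.items():
        fig = fn(df)
        path = out / name
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(str(path))
    return paths
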