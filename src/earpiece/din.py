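"""Digits-in-noise (DIN) test simulator.

Replaces the human listener in the online digit-triplet task with a
psychometric model, so the adaptive track, threshold extraction, scoring
rule and quality-control machinery can be exercised end to end.

Listener model
--------------
Per-digit recognition probability is a lapse-adjusted logistic in SNR:

    p(snr) = (1 - lapse) / (1 + exp(-4 * slope * (snr - threshold)))

where ``threshold`` is the per-ear digit threshold (dB SNR at which a digit
is recognised with probability ~0.5) and ``slope`` is the psychometric slope
(probability change per dB at the midpoint). A trial (three digits) is
scored correct when at least two of three digits are correct, so the trial
probability is p^3 + 3 p^2 (1 - p).

In the antiphasic condition (digits phase-inverted in one ear, diotic
noise), binaural unmasking is modelled as a scalar dB advantage applied to
the better ear's digit threshold.

Adaptive track
--------------
Two-down one-up staircase starting at +2 dB SNR: SNR drops one step after
two consecutive correct trials and rises one step after any incorrect
trial. Steps are 6 dB until the second turnpoint (SNR direction reversal)
and 2 dB thereafter; the run ends at the sixth turnpoint and threshold is
the mean SNR of turnpoints 3-6. This rule converges on the SNR at which the
trial probability is sqrt(1/2) ~ 70.7% correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ListenerProfile",
    "StaircaseConfig",
    "StaircaseResult",
    "BatteryResult",
    "trial_correct_prob",
    "target_snr",
    "run_staircase",
    "replay_track",
    "simulate_battery",
]

Condition = Literal["right", "left", "antiphasic"]

#: Two-down one-up convergence point on the trial psychometric function.
LEVITT_TARGET = 2.0 ** -0.5


@dataclass(frozen=True)
class ListenerProfile:
    """Simulated listener psychometrics."""

    digit_threshold_right: float = -11.0
    digit_threshold_left: float = -11.0
    slope: float = 0.2
    antiphasic_advantage: float = 6.0
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.antiphasic_advantage < 0:
            raise ValueError("antiphasic_advantage must be >= 0")
        if not (0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")

    def effective_threshold(self, condition: Condition) -> float:
        if condition == "right":
            return self.digit_threshold_right
        if condition == "left":
            return self.digit_threshold_left
        if condition == "antiphasic":
            better = min(self.digit_threshold_right, self.digit_threshold_left)
            return better - self.antiphasic_advantage
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive-track rules (two-down one-up)."""

    start_snr: float = 2.0
    step_initial: float = 6.0
    step_final: float = 2.0
    turnpoints_initial: int = 2
    turnpoints_final: int = 4
    max_trials: int = 100
    snr_floor: float = -30.0
    snr_ceiling: float = 20.0

    def __post_init__(self) -> None:
        if self.step_initial <= 0 or self.step_final <= 0:
            raise ValueError("step sizes must be positive")
        if self.turnpoints_final < 2:
            raise ValueError("need >= 2 final turnpoints")
        if self.max_trials < 20:
            raise ValueError("max_trials must be >= 20")

    @property
    def turnpoints_total(self) -> int:
        return self.turnpoints_initial + self.turnpoints_final


def digit_correct_prob(listener: ListenerProfile, snr: float, condition: Condition) -> float:
    thr = listener.effective_threshold(condition)
    return (1.0 - listener.lapse_rate) * float(expit(4.0 * listener.slope * (snr - thr)))


def trial_correct_prob(listener: ListenerProfile, snr: float, condition: Condition) -> float:
    """Probability of >= 2-of-3 digits correct on one triplet trial."""
    p = digit_correct_prob(listener, snr, condition)
    return p ** 3 + 3.0 * p ** 2 * (1.0 - p)


def target_snr(listener: ListenerProfile, condition: Condition) -> float:
    """SNR at which the trial probability equals the staircase's 70.7% target."""
    return float(
        brentq(
            lambda s: trial_correct_prob(listener, s, condition) - LEVITT_TARGET,
            -60.0,
            60.0,
            xtol=1e-10,
        )
    )


@dataclass
class Trial:
    snr: float
    correct: bool
    is_turnpoint: bool


@dataclass
class StaircaseResult:
    threshold: float | None
    track: list[Trial]
    turnpoint_snrs: list[float]
    converged: bool
    degenerate: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.track)


def _step_track(
    cfg: StaircaseConfig, answers
) -> StaircaseResult:
    """Shared state machine; ``answers(snr) -> bool`` supplies each response."""
    snr = cfg.start_snr
    consecutive = 0
    last_dir = 0
    pinned = 0
    track: list[Trial] = []
    turnpoints: list[float] = []
    degenerate = False
    for _ in range(cfg.max_trials):
        correct = bool(answers(snr))
        move = 0
        if correct:
            consecutive += 1
            if consecutive == 2:
                move = -1
                consecutive = 0
        else:
            consecutive = 0
            move = +1
        is_turn = move != 0 and last_dir != 0 and move == -last_dir
        track.append(Trial(snr, correct, is_turn))
        if is_turn:
            turnpoints.append(snr)
            if len(turnpoints) >= cfg.turnpoints_total:
                break
        if move != 0:
            step = (
                cfg.step_initial
                if len(turnpoints) < cfg.turnpoints_initial
                else cfg.step_final
            )
            new_snr = min(max(snr + move * step, cfg.snr_floor), cfg.snr_ceiling)
            last_dir = move
            snr = new_snr
        if snr in (cfg.snr_floor, cfg.snr_ceiling):
            pinned += 1
            if pinned > 10:
                degenerate = True
                break
        else:
            pinned = 0
    converged = len(turnpoints) >= cfg.turnpoints_total
    threshold = (
        float(np.mean(turnpoints[cfg.turnpoints_initial:])) if converged else None
    )
    return StaircaseResult(threshold, track, turnpoints, converged, degenerate)


def run_staircase(
    listener: ListenerProfile,
    config: StaircaseConfig,
    condition: Condition,
    rng: np.random.Generator,
) -> StaircaseResult:
    """Run one adaptive block against a simulated listener.

    Non-convergence (max_trials before the sixth turnpoint) and degenerate
    listeners (SNR pinned at a bound for > 10 consecutive trials) are
    signalled on the result rather than raised: threshold is ``None`` and
    the corresponding flag is set.
    """

    def answer(snr: float) -> bool:
        return rng.random() < trial_correct_prob(listener, snr, condition)

    return _step_track(config, answer)


def replay_track(track: list[Trial], config: StaircaseConfig) -> StaircaseResult:
    """Recompute all staircase decisions from the stored (snr, correct) pairs.

    Verifies that the stored SNR sequence is consistent with the stepping
    rule and returns the re-derived result (turnpoint flags and threshold
    must match the original run exactly).
    """
    seq = iter(track)

    def answer(snr: float) -> bool:
        trial = next(seq)
        if trial.snr != snr:
            raise ValueError(
                f"stored track inconsistent with stepping rule: expected SNR "
                f"{snr}, stored {trial.snr}"
            )
        return trial.correct

    return _step_track(config, answer)


@dataclass
class BatteryResult:
    din_right: float | None
    din_left: float | None
    din_antiphasic: float | None
    block_order: tuple[str, ...]
    converged: bool


def simulate_battery(
    listener: ListenerProfile,
    config: StaircaseConfig,
    rng: np.random.Generator,
) -> BatteryResult:
    """The full test session: an unscored antiphasic practice block, the two
    monaural blocks in randomised order, then the scored antiphasic block."""
    run_staircase(listener, config, "antiphasic", rng)  # practice; discarded
    monaural = ["right", "left"] if rng.random() < 0.5 else ["left", "right"]
    order = tuple(monaural) + ("antiphasic",)
    results: dict[str, StaircaseResult] = {}
    for cond in order:
        results[cond] = run_staircase(listener, config, cond, rng)
    return BatteryResult(
        din_right=results["right"].threshold,
        din_left=results["left"].threshold,
        din_antiphasic=results["antiphasic"].threshold,
        block_order=order,
        converged=all(r.converged for r in results.values()),
    )
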