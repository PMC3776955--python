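"""Adaptive frequency-discrimination task simulator.

Two-interval forced choice on a pair of bandpass noises whose center
frequencies differ by ``delta`` percent; the difficulty is adjusted in real
time by a pair of randomly interleaved two-up/one-down (Levitt) staircases,
which converge on the 70.7%-correct point of the observer.  After each run
the threshold is estimated as the mean frequency difference over the latter
half of that run's trials, and the next run is re-initialized 30% above it,
producing the characteristic easy-start/return-to-threshold pattern.

Human subjects are replaced by a stated observer model: a cumulative-normal
psychometric function in log difficulty with a 50% guessing floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri


@dataclass(frozen=True)
class Observer:
    """2AFC observer: P(correct) = 0.5 + 0.5 * Phi((log d - log alpha)/beta).

    ``alpha_pct`` is the frequency difference (percent) at which the observer
    is 75% correct; ``beta`` is the log-difficulty spread of the psychometric
    function.
    """

    alpha_pct: float = 4.0
    beta: float = 0.35

    def p_correct(self, delta_pct) -> np.ndarray | float:
        delta_pct = np.asarray(delta_pct, dtype=float)
        return 0.5 + 0.5 * ndtr((np.log(delta_pct) - np.log(self.alpha_pct)) / self.beta)

    def delta_at(self, p: float) -> float:
        """Difficulty at which P(correct) = p (analytic inverse)."""
        return float(self.alpha_pct * np.exp(self.beta * ndtri(2.0 * p - 1.0)))


def observer_respond(delta_pct: float, observer: Observer,
                     rng: np.random.Generator) -> bool:
    """One Bernoulli trial of the observer at the given difficulty."""
    if delta_pct <= 0:
        raise ValueError("delta_pct must be positive")
    return bool(rng.random() < observer.p_correct(delta_pct))


@dataclass
class StaircaseState:
    """State of one two-up/one-down staircase.

    Two consecutive correct responses make the task harder (delta divided by
    the step factor); any incorrect response makes it easier (delta
    multiplied).  The streak counter resets whenever the difficulty changes.
    """

    delta_pct: float
    step_factor: float = 1.12
    floor_pct: float = 0.05
    correct_streak: int = 0
    history: list = field(default_factory=list)

    def __post_init__(self):
        if self.delta_pct <= 0:
            raise ValueError("delta_pct must be positive")
        if self.step_factor <= 1:
            raise ValueError("step_factor must exceed 1")


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply the Levitt two-up/one-down rule in place; returns the state."""
    state.history.append((state.delta_pct, bool(correct)))
    if correct:
        state.correct_streak += 1
        if state.correct_streak >= 2:
            state.delta_pct = max(state.delta_pct / state.step_factor, state.floor_pct)
            state.correct_streak = 0
    else:
        state.delta_pct = state.delta_pct * state.step_factor
        state.correct_streak = 0
    return state


@dataclass
class RunResult:
    """Per-run outcome: threshold from the latter half of trials."""

    run: int
    threshold_pct: float
    pct_correct: float
    n_trials: int

    def __post_init__(self):
        if not (0.0 <= self.pct_correct <= 100.0):
            raise ValueError("pct_correct must lie in [0, 100]")


@dataclass
class SessionResult:
    runs: list
    trials: pd.DataFrame
    pct_correct: float  # over every trial of the session
    pct_correct_latter: float  # over latter halves only (excludes easy restarts)


def run_session(
    observer: Observer = Observer(),
    n_runs: int = 11,
    trials_per_run: int = 25,
    start_delta_pct: float = 6.0,
    step_factor: float = 1.12,
    floor_pct: float = 0.05,
    reinit_factor: float = 1.3,
    seed: int = 0,
) -> SessionResult:
    """Simulate a session of interleaved staircases with cross-run re-init.

    Within each run the two staircases are interleaved by a seeded coin flip;
    the run threshold is the mean presented difficulty over the latter half
    of its trials, and both staircases of the next run start at
    ``reinit_factor`` times that threshold.  Identical seeds reproduce the
    exact trial sequence.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    delta0 = start_delta_pct
    runs = []
    records = []
    for run in range(n_runs):
        stairs = [
            StaircaseState(delta0, step_factor, floor_pct),
            StaircaseState(delta0, step_factor, floor_pct),
        ]
        deltas, corrects = [], []
        for trial in range(trials_per_run):
            s = int(rng.integers(2))
            delta = stairs[s].delta_pct
            correct = observer_respond(delta, observer, rng)
            staircase_step(stairs[s], correct)
            deltas.append(delta)
            corrects.append(correct)
            records.append(
                dict(run=run, trial=trial, staircase=s, delta_pct=delta,
                     correct=correct, latter_half=trial >= trials_per_run // 2)
            )
        latter = slice(trials_per_run // 2, None)
        threshold = float(np.mean(deltas[latter]))
        runs.append(
            RunResult(
                run=run,
                threshold_pct=threshold,
                pct_correct=100.0 * float(np.mean(corrects)),
                n_trials=trials_per_run,
            )
        )
        delta0 = reinit_factor * threshold
    trials = pd.DataFrame(records)
    return SessionResult(
        runs=runs,
        trials=trials,
        pct_correct=100.0 * float(trials["correct"].mean()),
        pct_correct_latter=100.0 * float(trials.loc[trials["latter_half"], "correct"].mean()),
    )
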