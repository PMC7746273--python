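"""Adaptive psychophysical staircase and simulated observers.

The stimulus difference between the two gratings (orientation or contrast)
is controlled by a weighted up-down staircase (Kaernbach 1991 style): the
difference shrinks by one step after a correct response and grows by three
steps after an error, so the procedure equilibrates where
``p(correct) * step = (1 - p) * 3 step``, i.e. at 75% correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm

TARGET_P = 0.75


@dataclass
class StaircaseTrace:
    """Per-trial record of a staircase run."""

    delta: np.ndarray       # stimulus difference presented on each trial
    correct: np.ndarray     # response correctness
    threshold: np.ndarray   # running threshold estimate (reversal average)
    target_p: float = TARGET_P

    def percent_correct(self, last_n: int | None = None) -> float:
        c = self.correct if last_n is None else self.correct[-last_n:]
        return 100.0 * float(np.mean(c))


def gaussian_observer(psychometric_sd: float) -> Callable[[float], float]:
    """Two-interval discriminator with a cumulative-Gaussian psychometric
    function: p(correct) = Phi(delta / sd), chance 0.5 at delta = 0."""
    if psychometric_sd <= 0:
        raise ValueError("psychometric sd must be positive")
    return lambda delta: float(norm.cdf(delta / psychometric_sd))


def simulate_staircase_observer(psychometric_sd: float, n_trials: int = 512, seed: int = 0,
                                initial_delta: float = 2.0, step_down: float = 0.25,
                                step_ratio: float = 3.0, floor: float = 0.0,
                                p_correct_fn: Callable[[float], float] | None = None,
                                ) -> StaircaseTrace:
    """Run the weighted up-down staircase against a simulated observer.

    ``p_correct_fn`` overrides the default cumulative-Gaussian observer
    (useful for step or deterministic observers).  The running threshold is
    the mean stimulus difference over the reversals seen so far.
    """
    if n_trials < 20:
        raise ValueError("need at least 20 trials to assess staircase convergence")
    if p_correct_fn is None:
        p_correct_fn = gaussian_observer(psychometric_sd)
    elif psychometric_sd <= 0:
        raise ValueError("psychometric sd must be positive")
    rng = np.random.default_rng(seed)
    step_up = step_ratio * step_down

    delta = float(initial_delta)
    deltas = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    thresholds = np.empty(n_trials)
    reversal_deltas: list[float] = []
    last_direction = 0  # -1 down, +1 up
    for t in range(n_trials):
        deltas[t] = delta
        correct[t] = rng.random() < p_correct_fn(delta)
        direction = -1 if correct[t] else 1
        if last_direction != 0 and direction != last_direction:
            reversal_deltas.append(delta)
        last_direction = direction
        delta = max(floor, delta + (step_up if direction > 0 else -step_down))
        thresholds[t] = (np.mean(reversal_deltas[-8:]) if reversal_deltas else deltas[t])
    return StaircaseTrace(delta=deltas, correct=correct, threshold=thresholds)


def staircase_percent_correct(psychometric_sd: float, n_trials: int = 512,
                              n_seeds: int = 100, seed: int = 0,
                              **kwargs) -> float:
    """Mean percent correct over the last half of the run, averaged over
    independently seeded staircase simulations."""
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    pcs = [simulate_staircase_observer(psychometric_sd, n_trials, int(s), **kwargs)
           .percent_correct(last_n=n_trials // 2) for s in seeds]
    return float(np.mean(pcs))
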