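"""Experimental design generation for the cued-orientation paradigm.

Each trial starts with a coloured cue (cyan/orange fixation dot) predicting
the orientation (45 or 135 degrees) of a grating pair presented 750 ms
later.  On a fixed fraction of trials (default 25%) the gratings are
omitted, isolating the orientation expectation from any bottom-up input.
Runs alternate between an orientation- and a contrast-discrimination task
on the grating pair; the cue-colour/orientation contingency flips halfway
through the session.  Default counts reproduce the full session: 4 runs x
2 blocks x 64 trials = 512 trials, 256 per task.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

TASKS = ("orientation", "contrast")
ORIENTATIONS = (45, 135)

#: trial span from cue onset to the end of the response window (s):
#: 250 ms cue + 750 ms SOA wraps the cue into the SOA, then grating (250 ms),
#: blank (500 ms), grating (250 ms), response deadline (750 ms)
TRIAL_SPAN_S = 0.75 + 0.25 + 0.5 + 0.25 + 0.75
#: stimulus-onset asynchrony between cue and (expected) first grating
SOA_S = 0.75
#: rest at the start of each run before the first cue (s)
RUN_LEAD_IN_S = 10.0


def _truncated_exp_scale(lo: float, hi: float) -> float:
    """Scale of an exponential truncated to [0, hi-lo] whose mean is (hi-lo)/3."""
    r = hi - lo

    def mean_err(tau: float) -> float:
        e = np.exp(-r / tau)
        return (tau - r * e / (1 - e)) - r / 3.0

    return brentq(mean_err, 1e-3 * r, 100 * r)


def sample_iti(rng: np.random.Generator, size: int,
               iti_range_s: tuple[float, float] = (2.15, 5.15)) -> np.ndarray:
    """Inter-trial intervals: truncated exponential jitter over the range,
    with the mean one-third of the way up the interval."""
    lo, hi = iti_range_s
    tau = _truncated_exp_scale(lo, hi)
    u = rng.random(size)
    x = -tau * np.log1p(-u * (1 - np.exp(-(hi - lo) / tau)))
    return lo + x


def simulate_design(n_runs: int = 4, blocks_per_run: int = 2, trials_per_block: int = 64,
                    validity: float = 0.75, omission_rate: float = 0.25,
                    soa_s: float = SOA_S, iti_range_s: tuple[float, float] = (2.15, 5.15),
                    seed: int = 0, delta_orientation_deg: float = 3.3,
                    delta_contrast: float = 6.9) -> pd.DataFrame:
    """Generate the trial table for a full scanning session.

    Within each block the cued orientation is counterbalanced exactly and
    omissions are interleaved at the exact stated rate in random positions.
    Onsets are expressed within-run (seconds from run start) and are
    strictly increasing; ``grating_onset_s`` marks the (expected) first
    grating time, which is where both presentation and omission events are
    modelled downstream.
    """
    if not (0 <= omission_rate <= 1 and 0 <= validity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if abs(validity + omission_rate - 1.0) > 1e-9:
        raise ValueError("cue validity and omission rate must sum to 1 "
                         "(omitted trials are the invalid trials)")
    if min(n_runs, blocks_per_run, trials_per_block) < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    n_omit = int(round(omission_rate * trials_per_block))
    rows = []
    trial_index = 0
    for run in range(n_runs):
        task = TASKS[run % 2]
        # contingency flip halfway through the session
        flipped = run >= n_runs // 2
        colour_of = {45: "cyan", 135: "orange"} if not flipped else {45: "orange", 135: "cyan"}
        t = RUN_LEAD_IN_S
        for block in range(blocks_per_run):
            orients = np.repeat(ORIENTATIONS, trials_per_block // 2)
            if trials_per_block % 2:
                orients = np.append(orients, rng.choice(ORIENTATIONS))
            rng.shuffle(orients)
            omitted = np.zeros(trials_per_block, dtype=bool)
            omitted[rng.choice(trials_per_block, size=n_omit, replace=False)] = True
            itis = sample_iti(rng, trials_per_block, iti_range_s)
            for i in range(trials_per_block):
                present = not omitted[i]
                rows.append({
                    "trial_index": trial_index,
                    "run": run,
                    "block": block,
                    "task": task,
                    "cue_colour": colour_of[int(orients[i])],
                    "cued_orientation_deg": int(orients[i]),
                    "trial_type": "present" if present else "omission",
                    "onset_s": t,
                    "grating_onset_s": t + soa_s,
                    "iti_s": itis[i],
                    "grating1_orientation_deg": float(orients[i]) if present else np.nan,
                    "grating2_delta_orientation_deg": delta_orientation_deg if present else np.nan,
                    "grating2_delta_contrast": delta_contrast if present else np.nan,
                })
                t += TRIAL_SPAN_S + itis[i]
                trial_index += 1
    return pd.DataFrame(rows)


def run_duration_s(design: pd.DataFrame, run: int, tail_s: float = 20.0) -> float:
    d = design[design["run"] == run]
    return float(d["onset_s"].max() + TRIAL_SPAN_S + d["iti_s"].iloc[-1] + tail_s)


def write_events_tsv(design: pd.DataFrame, path: str | Path) -> None:
    """BIDS-style events table, one file for the whole session."""
    out = pd.DataFrame({
        "onset": design["onset_s"],
        "duration": TRIAL_SPAN_S,
        "trial_type": design["trial_type"],
        "task": design["task"],
        "run": design["run"],
        "cue": design["cue_colour"],
        "orientation": design["cued_orientation_deg"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
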