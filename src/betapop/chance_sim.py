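"""Target-shuffled chance-level simulation of the neurofeedback epoch.

A session's displayed cursor trace is re-run through the task with the
realized beta-target sequence randomly permuted.  Each simulation walks
the cursor trace in time: when the cursor stays inside the current
target's band for the 450 ms hold, the target is acquired and an
average reach time, reward time, and inter-trial interval elapse before
the next shuffled target appears.  A target unmet within the timeout
simply repeats (as in the task), so the search continues.  The output
is the distribution of acquisitions per minute over ``n_sims``
simulations, whose mean and standard deviation z-score the observed
reward rate.

The cursor is piecewise-constant between 100 ms updates; hold
completion is tracked in continuous time (a hold started at time s
completes at s + hold_s if the displayed cursor stays in band), so an
always-in-band cursor acquires exactly
floor(session / (hold + reach + reward + iti)) targets.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TaskTimingConfig", "simulate_chance", "chance_zscore"]


@dataclass
class TaskTimingConfig:
    """Timing constants of the neurofeedback epoch simulation."""

    hold_s: float = 0.45
    timeout_s: float = 60.0
    mean_reach_s: float = 1.0
    reward_s: float = 0.5
    iti_s: float = 1.0
    n_sims: int = 100
    target_bands: dict = field(default_factory=dict)  # target -> (lo, hi) screen_y

    def validate(self) -> None:
        for name in ("hold_s", "timeout_s", "mean_reach_s", "reward_s", "iti_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.target_bands:
            raise ValueError("target_bands is empty")


def _runs(in_band: np.ndarray, times: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time [start, end) spans of consecutive in-band updates."""
    padded = np.diff(np.concatenate(([0], in_band.astype(np.int8), [0])))
    starts = times[np.flatnonzero(padded == 1)]
    ends = times[np.flatnonzero(padded == -1) - 1] + dt
    return starts, ends


def simulate_chance(
    times: np.ndarray,
    screen_y: np.ndarray,
    target_sequence,
    timing: TaskTimingConfig,
    rng: np.random.Generator,
    screen_x: np.ndarray | None = None,
    x_band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-simulation successful-target rates (acquisitions per minute).

    ``times`` are the cursor update times (uniform cadence); the cursor
    holds each value until the next update.  ``target_sequence`` is the
    session's realized target order; each simulation uses an
    independent permutation of it (target frequencies preserved).  With
    ``screen_x``/``x_band`` set, being in band additionally requires
    the x cursor inside ``x_band`` (two-axis task variant).
    """
    times = np.asarray(times, float)
    screen_y = np.asarray(screen_y, float)
    if times.size == 0:
        raise ValueError("empty cursor trace")
    timing.validate()
    target_sequence = list(target_sequence)
    if not target_sequence:
        raise ValueError("empty target sequence")
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.1
    session_end = float(times[-1] + dt)
    session_min = (session_end - float(times[0])) / 60.0

    x_ok = (
        np.ones_like(screen_y, bool)
        if screen_x is None or x_band is None
        else (np.asarray(screen_x) >= x_band[0]) & (np.asarray(screen_x) <= x_band[1])
    )
    runs_by_target = {}
    for target, (lo, hi) in timing.target_bands.items():
        in_band = (screen_y >= lo) & (screen_y <= hi) & x_ok
        runs_by_target[target] = _runs(in_band, times, dt)

    cycle_after_hold = timing.mean_reach_s + timing.reward_s + timing.iti_s
    rates = np.empty(timing.n_sims)
    for s in range(timing.n_sims):
        order = rng.permutation(len(target_sequence))
        t = float(times[0])
        successes = 0
        k = 0
        while t < session_end:
            target = target_sequence[order[k % len(order)]]
            starts, ends = runs_by_target[target]
            # first run whose usable span [max(t, start), end) covers the hold
            j = bisect_left(ends, t + timing.hold_s)
            done = None
            while j < starts.size:
                s0 = max(t, starts[j])
                if ends[j] - s0 >= timing.hold_s:
                    done = s0 + timing.hold_s
                    break
                j += 1
            # the full trial cycle (hold + reach + reward + ITI) must fit in
            # the session for the acquisition to count as a rewarded trial
            if done is None or done + cycle_after_hold > session_end:
                break
            successes += 1
            k += 1
            t = done + cycle_after_hold
        rates[s] = successes / session_min
    return rates


def chance_zscore(observed_rate: float, simulated_rates: np.ndarray) -> float:
    """z-score of the observed reward rate against the chance distribution.

    Returns NaN (flagged undefined) when the simulated distribution has
    zero spread; the caller reports rather than fabricates a z.
    """
    simulated_rates = np.asarray(simulated_rates, float)
    sd = simulated_rates.std(ddof=0)
    if sd == 0:
        return float("nan")
    return float((observed_rate - simulated_rates.mean()) / sd)
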