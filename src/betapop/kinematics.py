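"""Movement-onset-time (MOT) extraction and hand-speed labeling.

MOT is defined relative to the peak of the reach: project the hand
velocity onto the unit vector from the center target to the reach
target, find the index and value (i, M) of the maximum projected
speed, then scan backward from i until the projected speed first falls
strictly below 0.2 * M.  That sample's time is the movement onset.
Because the 20% rule is relative, MOT is invariant to rescaling speed.

Trials with MOT outside [0.0, 0.7] s relative to the go cue (or with
undefined MOT) are excluded from downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotResult",
    "movement_onset_time",
    "speed_labels",
    "filter_trials_by_mot",
    "smooth_and_differentiate",
]

SPEED_THRESHOLD_CM_S = 3.5  # slow/fast boundary
MOT_RANGE_S = (0.0, 0.7)  # inclusive retention range relative to go cue


@dataclass
class MotResult:
    """Result of the backward-scan movement-onset search."""

    peak_index: int
    peak_speed: float  # M, cm/s
    mot_index: int | None
    mot_s: float  # NaN when undefined
    projected_speed: np.ndarray
    onset_acceleration: float  # projected-speed derivative at MOT (convention)

    @property
    def defined(self) -> bool:
        return self.mot_index is not None


def movement_onset_time(
    velocity: np.ndarray,
    center: tuple[float, float],
    target: tuple[float, float],
    times: np.ndarray,
    fraction: float = 0.2,
) -> MotResult:
    """Backward-scan MOT from a (t, 2) velocity trace.

    ``times`` gives each sample's time relative to the go cue.  If no
    sample before the peak falls strictly below ``fraction * M`` the
    MOT is flagged undefined (``mot_s`` = NaN) and the trial is meant
    to be excluded by :func:`filter_trials_by_mot`.
    """
    velocity = np.asarray(velocity, float)
    times = np.asarray(times, float)
    if velocity.ndim != 2 or velocity.shape[1] != 2 or velocity.shape[0] == 0:
        raise ValueError("velocity must be a non-empty (t, 2) array")
    direction = np.asarray(target, float) - np.asarray(center, float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("center and target coincide: no reach direction")
    u = direction / norm
    speed = velocity @ u

    i = int(np.argmax(speed))
    M = float(speed[i])
    cutoff = fraction * M
    mot_index = None
    for j in range(i - 1, -1, -1):
        if speed[j] < cutoff:
            mot_index = j
            break
    if mot_index is None:
        mot_s = float("nan")
        accel = float("nan")
    else:
        mot_s = float(times[mot_index])
        if velocity.shape[0] >= 2:
            grad = np.gradient(speed, times)
            accel = float(grad[mot_index])
        else:
            accel = float("nan")
    return MotResult(
        peak_index=i,
        peak_speed=M,
        mot_index=mot_index,
        mot_s=mot_s,
        projected_speed=speed,
        onset_acceleration=accel,
    )


def speed_labels(
    speed: np.ndarray,
    fs: float,
    bin_s: float,
    threshold: float = SPEED_THRESHOLD_CM_S,
) -> np.ndarray:
    """Per-bin slow (0) / fast (1) labels on hand speed.

    A bin is fast iff its mean speed is strictly above ``threshold``
    (cm/s); a bin exactly at the threshold is slow.  Trailing samples
    not filling a whole bin are ignored.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    speed = np.asarray(speed, float)
    n_per = int(round(bin_s * fs))
    n_bins = speed.size // n_per
    means = speed[: n_bins * n_per].reshape(n_bins, n_per).mean(axis=1)
    return (means > threshold).astype(np.uint8)


def filter_trials_by_mot(
    mot_s: np.ndarray, mot_range: tuple[float, float] = MOT_RANGE_S
) -> tuple[np.ndarray, dict]:
    """Retention mask for MOTs in the closed range [0.0, 0.7] s.

    Undefined (NaN) MOTs are excluded.  Returns ``(mask, report)`` with
    counts of each exclusion reason.
    """
    mot_s = np.asarray(mot_s, float)
    undefined = ~np.isfinite(mot_s)
    with np.errstate(invalid="ignore"):
        too_early = np.isfinite(mot_s) & (mot_s < mot_range[0])
        too_late = np.isfinite(mot_s) & (mot_s > mot_range[1])
    mask = ~(undefined | too_early | too_late)
    report = {
        "n_total": int(mot_s.size),
        "n_kept": int(mask.sum()),
        "n_undefined": int(undefined.sum()),
        "n_below_range": int(too_early.sum()),
        "n_above_range": int(too_late.sum()),
    }
    return mask, report


def smooth_and_differentiate(
    position: np.ndarray, fs: float, smooth_s: float = 0.05
) -> np.ndarray:
    """Velocity from a (t, 2) position trace when hardware velocity is absent.

    Applies a moving-average pre-smooth (50 ms default) then central
    differences, so differentiation noise does not create spurious
    speed peaks.
    """
    position = np.asarray(position, float)
    n = max(1, int(round(smooth_s * fs)))
    kernel = np.ones(n) / n
    smoothed = np.column_stack(
        [np.convolve(position[:, k], kernel, mode="same") for k in range(2)]
    )
    return np.gradient(smoothed, axis=0) * fs
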