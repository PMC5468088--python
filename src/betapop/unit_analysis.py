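"""Per-unit firing-rate comparisons and the beta-amplitude-to-rate mapping.

The decile mapping concatenates all of a task's trial slices (1 ms
spike-count bins over the (-1.5, +1.0) s window around the go cue,
2500 samples per trial), sorts timepoints by the instantaneous beta
amplitude envelope (spike rows co-sorted), and reduces both to 10
values: each decile's mean log10 amplitude and mean spike rate (counts
per 1 ms bin scaled to Hz).  A least-squares line through the 10 pairs
gives the unit's slope in Hz per log10-amplitude.  Stability is
assessed by re-estimating the slope on interleaved (even/odd timepoint
index) halves, or on two 75% subsets when one task has limited data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BetaRateMapping",
    "firing_rate_comparison",
    "beta_rate_mapping",
    "split_half_slopes",
    "split_half_slope_stability",
    "cross_task_slope_comparison",
]


@dataclass
class BetaRateMapping:
    """Decile beta-amplitude-to-spike-rate mapping for one unit."""

    amplitude_log10: np.ndarray  # 10 decile means of log10 amplitude
    rate_hz: np.ndarray  # 10 decile means of firing rate
    slope: float  # Hz per log10-amplitude
    intercept: float
    task: str = ""
    subset: str = "full"


def firing_rate_comparison(
    counts_a: list[np.ndarray],
    counts_b: list[np.ndarray],
    alpha: float = 0.05,
    min_bins: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Mann-Whitney comparison of qualifying-bin spike counts per unit.

    ``counts_a``/``counts_b`` hold, per unit, the 100 ms-bin spike
    counts from the qualifying (e.g. slow, on-beta) bins of each task.
    Units with fewer than ``min_bins`` bins in either task, or with no
    spikes in both, are excluded and reported.  Returns the per-unit
    table and the fraction of included units significant at ``alpha``.
    """
    if len(counts_a) != len(counts_b):
        raise ValueError("unit count mismatch between tasks")
    rows = []
    for u, (a, b) in enumerate(zip(counts_a, counts_b)):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size < min_bins or b.size < min_bins:
            rows.append({"unit": u, "p": np.nan, "excluded": "too few bins"})
            continue
        if a.sum() == 0 and b.sum() == 0:
            rows.append({"unit": u, "p": np.nan, "excluded": "no spikes"})
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append({"unit": u, "p": np.nan, "excluded": "constant counts"})
            continue
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({"unit": u, "p": float(p), "excluded": ""})
    df = pd.DataFrame(rows)
    included = df[df["excluded"] == ""]
    frac = float((included["p"] < alpha).mean()) if len(included) else float("nan")
    return df, frac


def _decile_mapping(
    counts: np.ndarray, envelope: np.ndarray, bin_s: float, task: str, subset: str
) -> list[BetaRateMapping]:
    order = np.argsort(envelope, kind="stable")
    amp_sorted = envelope[order]
    counts_sorted = counts[order]
    amp_chunks = np.array_split(amp_sorted, 10)
    cnt_chunks = np.array_split(counts_sorted, 10, axis=0)
    pos = amp_sorted[amp_sorted > 0]
    floor = pos.min() if pos.size else np.finfo(float).eps
    if (amp_sorted <= 0).any():
        warnings.warn(
            "non-positive amplitude values floored before log10", stacklevel=3
        )
    amp_means = np.array(
        [np.log10(np.maximum(c, floor)).mean() for c in amp_chunks]
    )
    rate_means = np.vstack([c.mean(axis=0) / bin_s for c in cnt_chunks])  # (10, U)
    out = []
    for u in range(counts.shape[1]):
        slope, intercept = np.polyfit(amp_means, rate_means[:, u], 1)
        out.append(
            BetaRateMapping(
                amplitude_log10=amp_means,
                rate_hz=rate_means[:, u],
                slope=float(slope),
                intercept=float(intercept),
                task=task,
                subset=subset,
            )
        )
    return out


def beta_rate_mapping(
    counts: np.ndarray,
    envelope: np.ndarray,
    bin_s: float = 0.001,
    task: str = "",
    subset: str = "full",
) -> list[BetaRateMapping]:
    """Decile mapping for every unit.

    ``counts`` is the concatenated (n_timepoints, n_units) matrix of
    1 ms spike counts across a task's trials and ``envelope`` the
    matching (n_timepoints,) beta amplitude vector.  Invariant to trial
    ordering: concatenation is followed by a global sort on amplitude.
    """
    counts = np.atleast_2d(np.asarray(counts, float).T).T
    envelope = np.asarray(envelope, float)
    if counts.shape[0] != envelope.size:
        raise ValueError("counts and envelope length mismatch")
    if envelope.size < 10:
        raise ValueError("need at least 10 timepoints for decile averaging")
    return _decile_mapping(counts, envelope, bin_s, task, subset)


def split_half_slopes(
    counts: np.ndarray,
    envelope: np.ndarray,
    mode: str = "interleaved",
    subset_frac: float = 0.75,
    bin_s: float = 0.001,
    task: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit slope estimates from two data subsets.

    ``mode='interleaved'``: even vs odd timepoint indices of the
    concatenated arrays (equal, non-overlapping halves).
    ``mode='subsets'``: the first and last ``subset_frac`` of
    timepoints (overlapping by construction; used when one task has
    limited data).
    """
    counts = np.atleast_2d(np.asarray(counts, float).T).T
    envelope = np.asarray(envelope, float)
    n = envelope.size
    if mode == "interleaved":
        idx1, idx2 = np.arange(0, n, 2), np.arange(1, n, 2)
    elif mode == "subsets":
        m = int(round(subset_frac * n))
        idx1, idx2 = np.arange(0, m), np.arange(n - m, n)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    s1 = [
        m.slope
        for m in _decile_mapping(counts[idx1], envelope[idx1], bin_s, task, "half1")
    ]
    s2 = [
        m.slope
        for m in _decile_mapping(counts[idx2], envelope[idx2], bin_s, task, "half2")
    ]
    return np.asarray(s1), np.asarray(s2)


def split_half_slope_stability(
    days: list[tuple[np.ndarray, np.ndarray]],
    mode: str = "interleaved",
    subset_frac: float = 0.75,
    bin_s: float = 0.001,
    min_units: int = 3,
) -> dict:
    """Within-day correlation of split-half slopes, averaged across days.

    ``days`` holds per-day (counts, envelope) pairs.  Days with fewer
    than ``min_units`` units are excluded from the correlation.
    """
    per_day = []
    slopes = []
    for counts, envelope in days:
        s1, s2 = split_half_slopes(
            counts, envelope, mode=mode, subset_frac=subset_frac, bin_s=bin_s
        )
        slopes.append((s1, s2))
        if s1.size < min_units:
            per_day.append(np.nan)
            continue
        per_day.append(float(np.corrcoef(s1, s2)[0, 1]))
    valid = [r for r in per_day if np.isfinite(r)]
    return {
        "per_day_r": per_day,
        "mean_r": float(np.mean(valid)) if valid else float("nan"),
        "slopes": slopes,
    }


def cross_task_slope_comparison(
    co1: np.ndarray, co2: np.ndarray, nr1: np.ndarray, nr2: np.ndarray
) -> pd.DataFrame:
    """Paired t-tests on within-task and across-task slope differences.

    Units are the observations: (CO1 vs CO2) and (NR1 vs NR2) gauge
    within-task stability, (CO2 vs NR1) the across-task shift.
    """
    arrays = [np.asarray(a, float) for a in (co1, co2, nr1, nr2)]
    n = arrays[0].size
    if any(a.size != n for a in arrays) or n < 3:
        raise ValueError("need matched slope arrays with at least 3 units")
    co1, co2, nr1, nr2 = arrays
    rows = []
    for name, a, b in (
        ("CO1_vs_CO2", co1, co2),
        ("NR1_vs_NR2", nr1, nr2),
        ("CO2_vs_NR1", co2, nr1),
    ):
        if np.ptp(a - b) == 0:
            raise ValueError(f"{name}: zero-variance differences, t undefined")
        t, p = stats.ttest_rel(a, b)
        rows.append({"pair": name, "t": float(t), "p": float(p), "n": n})
    return pd.DataFrame(rows)
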