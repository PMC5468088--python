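"""On-beta / off-beta labeling of LFP from the Hilbert amplitude envelope.

A 1 ms sample is "on-beta" when the 25-40 Hz amplitude envelope of one
neurofeedback channel exceeds a day-level threshold (the 60th
percentile of envelope values aggregated over that day's rewarded
trials) for an uninterrupted block of at least 125 ms (3-4 beta
cycles).  Shorter supra-threshold blocks are reset to off-beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from betapop.spectral import BETA_BAND

__all__ = [
    "BetaLabelSeries",
    "beta_amplitude",
    "on_beta_labels",
    "bin_labels",
    "percent_on_beta",
    "label_intervals",
    "interval_recovery",
]

FILTER_ORDER = 5  # Butterworth bandpass design order


@dataclass
class BetaLabelSeries:
    """Binary on-beta labels at the native LFP sampling rate."""

    labels: np.ndarray  # uint8, per 1 ms sample
    threshold: float
    percentile: float
    min_duration_s: float
    fs: float


def beta_amplitude(
    lfp: np.ndarray, fs: float, band: tuple[float, float] = BETA_BAND
) -> np.ndarray:
    """Amplitude envelope of the beta-band-passed signal.

    The LFP is filtered with a fifth-order Butterworth bandpass applied
    forward-backward (zero phase, so burst timing is preserved) and the
    envelope is the magnitude of the analytic signal from the Hilbert
    transform.  Output has the same length as the input.
    """
    lfp = np.asarray(lfp, float)
    if fs < 2 * band[1]:
        raise ValueError(f"fs={fs} too low to represent the {band} Hz band")
    sos_pad = 3 * (2 * FILTER_ORDER + 1)
    if lfp.size <= sos_pad:
        raise ValueError(f"signal too short to filter (need > {sos_pad} samples)")
    b, a = butter(FILTER_ORDER, band, btype="bandpass", fs=fs)
    filtered = filtfilt(b, a, lfp)
    return np.abs(hilbert(filtered))


def _zero_short_runs(labels: np.ndarray, min_samples: int) -> np.ndarray:
    out = labels.astype(np.uint8).copy()
    padded = np.diff(np.concatenate(([0], out, [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for s, e in zip(starts, ends):
        if e - s < min_samples:
            out[s:e] = 0
    return out


def on_beta_labels(
    envelope: np.ndarray,
    aggregate: np.ndarray | None = None,
    percentile: float = 60.0,
    min_duration_s: float = 0.125,
    fs: float = 1000.0,
) -> BetaLabelSeries:
    """Threshold the envelope and enforce the minimum burst duration.

    ``aggregate`` is the day-level distribution of envelope values
    (typically the concatenated envelopes of all rewarded trials of the
    day); the threshold is its ``percentile``-th percentile.  When
    ``aggregate`` is omitted, the envelope itself is used.  Supra-
    threshold runs shorter than ``min_duration_s`` are reset to 0.
    """
    envelope = np.asarray(envelope, float)
    pool = envelope if aggregate is None else np.asarray(aggregate, float)
    if np.ptp(pool) == 0:
        raise ValueError("degenerate threshold: envelope distribution is constant")
    threshold = float(np.percentile(pool, percentile))
    raw = envelope > threshold
    min_samples = int(round(min_duration_s * fs))
    labels = _zero_short_runs(raw, min_samples)
    return BetaLabelSeries(
        labels=labels,
        threshold=threshold,
        percentile=percentile,
        min_duration_s=min_duration_s,
        fs=fs,
    )


def bin_labels(series: BetaLabelSeries | np.ndarray, bin_s: float, fs: float = 1000.0) -> np.ndarray:
    """Aggregate 1 ms labels into analysis bins by strict majority.

    A bin is labeled 1 iff strictly more than half of its samples are 1;
    exact ties resolve to 0 (off-beta, the conservative choice).
    Trailing samples that do not fill a whole bin are ignored.
    """
    if isinstance(series, BetaLabelSeries):
        labels, fs = series.labels, series.fs
    else:
        labels = np.asarray(series)
    n_per = int(round(bin_s * fs))
    if n_per < 1 or abs(bin_s * fs - n_per) > 1e-9:
        raise ValueError("bin_s must be a positive multiple of the sample period")
    n_bins = labels.size // n_per
    counts = labels[: n_bins * n_per].reshape(n_bins, n_per).sum(axis=1)
    return (counts * 2 > n_per).astype(np.uint8)


def percent_on_beta(
    series: BetaLabelSeries, window: tuple[float, float] | None = None
) -> float:
    """Percentage of on-beta samples within ``window`` (start_s, end_s)."""
    labels = series.labels
    if window is not None:
        i0 = int(round(window[0] * series.fs))
        i1 = int(round(window[1] * series.fs))
        labels = labels[i0:i1]
    if labels.size == 0:
        raise ValueError("empty window")
    return 100.0 * float(labels.mean())


def label_intervals(series: BetaLabelSeries) -> list[tuple[float, float]]:
    """(start_s, end_s) of every maximal on-beta run."""
    padded = np.diff(np.concatenate(([0], series.labels, [0])))
    starts = np.flatnonzero(padded == 1) / series.fs
    ends = np.flatnonzero(padded == -1) / series.fs
    return list(zip(starts.tolist(), ends.tolist()))


def interval_recovery(
    true_intervals: list[tuple[float, float]],
    detected_intervals: list[tuple[float, float]],
    tol_s: float = 0.02,
    min_overlap: float = 0.5,
) -> tuple[float, float]:
    """Sensitivity and precision of detected burst intervals.

    A true interval counts as recovered when some detected interval,
    after allowing ``tol_s`` of slack at each edge, covers at least
    ``min_overlap`` of it; precision applies the symmetric rule to the
    detected intervals.  Returns ``(sensitivity, precision)``; either is
    NaN when its denominator is empty.
    """

    def covered(a: tuple[float, float], bs: list[tuple[float, float]]) -> bool:
        dur = a[1] - a[0]
        if dur <= 0:
            return False
        for b in bs:
            lo = max(a[0], b[0] - tol_s)
            hi = min(a[1], b[1] + tol_s)
            if hi - lo >= min_overlap * dur:
                return True
        return False

    sens = (
        np.mean([covered(t, detected_intervals) for t in true_intervals])
        if true_intervals
        else np.nan
    )
    prec = (
        np.mean([covered(d, true_intervals) for d in detected_intervals])
        if detected_intervals
        else np.nan
    )
    return float(sens), float(prec)
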