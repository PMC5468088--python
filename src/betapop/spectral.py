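"""Multitaper band power and the normalized beta cursor.

The neurofeedback cursor is driven by a normalized estimate of beta
power: with per-channel multitaper PSDs over the trailing 200 ms of
LFP,

    beta_est = mean_ch( sum_{f in [25,40]} PSD_f^ch )
             / mean_ch( sum_{f in [1,100]} PSD_f^ch )

where band sums include every frequency-grid bin whose center lies in
the closed interval.  A 200 ms window gives a 5 Hz grid (beta bins
{25, 30, 35, 40}); the 1 Hz-grid convention (16/100 for a flat
spectrum) applies to analyses with windows of 1 s or longer.  beta_est
is unitless in [0, 1] and invariant under global signal rescaling.

Slepian tapers use time-bandwidth product NW = (n_tapers + 1) / 2, so
the default five tapers correspond to NW = 3 (2*NW - 1 = 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss

__all__ = [
    "PSD",
    "CursorTrace",
    "DetrendCoefficients",
    "multitaper_psd",
    "band_power",
    "beta_cursor_value",
    "cursor_trace",
    "normalized_beta_trace",
    "detrended_spectrogram",
    "zscored_psd",
]

BETA_BAND = (25.0, 40.0)
BROAD_BAND = (1.0, 100.0)
LOWFREQ_BAND = (1.0, 10.0)


@dataclass
class PSD:
    """One-sided multitaper power spectral density (relative units)."""

    frequencies: np.ndarray
    power: np.ndarray  # same length as frequencies
    window: tuple[float, float] = (0.0, 0.0)
    n_tapers: int = 5


@dataclass
class CursorTrace:
    """Normalized beta power at the cursor update cadence.

    ``screen_y`` is the linear transform of ``beta_est`` smoothed with
    the two-timestep (200 ms) boxcar the online task displayed.
    """

    times: np.ndarray
    beta_est: np.ndarray
    screen_y: np.ndarray
    transform: tuple[float, float]
    screen_x: np.ndarray | None = None
    x_est: np.ndarray | None = None
    x_transform: tuple[float, float] | None = None


@dataclass
class DetrendCoefficients:
    """Linear power-vs-frequency fit used to flatten the 1/f trend."""

    slope: float
    intercept: float


def _tapers(n: int, n_tapers: int) -> np.ndarray:
    nw = (n_tapers + 1) / 2.0
    w = dpss(n, nw, Kmax=n_tapers)
    # unit-energy tapers -> density units consistent with signal variance
    return w / np.sqrt(np.sum(w**2, axis=1, keepdims=True))


def _mt_power(segments: np.ndarray, fs: float, n_tapers: int) -> np.ndarray:
    """Multitaper one-sided PSD of segments (..., n) -> (..., n//2+1)."""
    n = segments.shape[-1]
    w = _tapers(n, n_tapers)  # (k, n)
    spec = np.fft.rfft(segments[..., None, :] * w, axis=-1)
    p = (np.abs(spec) ** 2).mean(axis=-2) / fs
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    return p


def multitaper_psd(
    segment: np.ndarray, fs: float, n_tapers: int = 5, window: tuple[float, float] = (0.0, 0.0)
) -> PSD:
    """Average Slepian-taper periodogram of one signal segment.

    The one-sided density integrates (sum times bin width) to the
    taper-weighted signal power, so band-integrated power is consistent
    with time-domain variance.
    """
    segment = np.asarray(segment, float)
    if segment.ndim != 1 or segment.size < 2:
        raise ValueError("segment must be a 1-D array with at least 2 samples")
    if n_tapers < 1:
        raise ValueError("n_tapers must be >= 1")
    if np.isnan(segment).all():
        raise ValueError("segment is all-NaN")
    power = _mt_power(segment, fs, n_tapers)
    freqs = np.fft.rfftfreq(segment.size, 1.0 / fs)
    return PSD(frequencies=freqs, power=power, window=window, n_tapers=n_tapers)


def band_power(psd: PSD, band: tuple[float, float]) -> float:
    """Sum of PSD bins whose center frequency lies in the closed band."""
    lo, hi = band
    mask = (psd.frequencies >= lo) & (psd.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(np.sum(psd.power[mask]))


def beta_cursor_value(
    psds: Sequence[PSD] | PSD,
    beta_band: tuple[float, float] = BETA_BAND,
    broad_band: tuple[float, float] = BROAD_BAND,
) -> float:
    """Normalized beta power: channel-averaged beta sum over broadband sum."""
    if isinstance(psds, PSD):
        psds = [psds]
    beta = np.mean([band_power(p, beta_band) for p in psds])
    broad = np.mean([band_power(p, broad_band) for p in psds])
    if broad <= 0:
        raise ValueError("zero broadband power: beta_est undefined")
    return float(beta / broad)


def _band_mask(n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return (freqs >= band[0]) & (freqs <= band[1])


def _sliding_band_ratio(
    lfp: np.ndarray,
    fs: float,
    window_s: float,
    step_s: float,
    n_tapers: int,
    num_band: tuple[float, float],
    den_band: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Band-power ratio over trailing windows; times mark window ends."""
    lfp = np.atleast_2d(np.asarray(lfp, float).T).T  # (n, n_ch)
    n_win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if lfp.shape[0] < n_win:
        raise ValueError("signal shorter than one analysis window")
    num_mask = _band_mask(n_win, fs, num_band)
    den_mask = _band_mask(n_win, fs, den_band)
    ratios = []
    for ch in range(lfp.shape[1]):
        segs = sliding_window_view(lfp[:, ch], n_win)[::step]
        p = _mt_power(segs, fs, n_tapers)  # (n_seg, n_freq)
        ratios.append((p[:, num_mask].sum(axis=1), p[:, den_mask].sum(axis=1)))
    num = np.mean([r[0] for r in ratios], axis=0)
    den = np.mean([r[1] for r in ratios], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    n_seg = val.size
    times = (n_win + step * np.arange(n_seg)) / fs
    return times, val


def _boxcar2(x: np.ndarray) -> np.ndarray:
    """Two-timestep moving average; the first sample is passed through."""
    out = x.copy()
    if x.size >= 2:
        out[1:] = 0.5 * (x[1:] + x[:-1])
    return out


def cursor_trace(
    lfp: np.ndarray,
    fs: float,
    update_s: float = 0.1,
    window_s: float = 0.2,
    n_tapers: int = 5,
    transform: tuple[float, float] = (1.0, 0.0),
    beta_band: tuple[float, float] = BETA_BAND,
    broad_band: tuple[float, float] = BROAD_BAND,
    x_band: tuple[float, float] | None = None,
    x_transform: tuple[float, float] | None = None,
) -> CursorTrace:
    """Online-style beta cursor: beta_est every ``update_s`` over trailing
    ``window_s`` windows, mapped to screen position by the linear
    ``transform`` (gain, offset) and smoothed with a 2-tap boxcar.

    With ``x_band`` set (e.g. the 1-10 Hz band of the two-axis task
    variant) a second normalized-power axis is computed the same way.
    """
    times, beta = _sliding_band_ratio(
        lfp, fs, window_s, update_s, n_tapers, beta_band, broad_band
    )
    gain, offset = transform
    screen_y = _boxcar2(gain * beta + offset)
    trace = CursorTrace(
        times=times, beta_est=beta, screen_y=screen_y, transform=transform
    )
    if x_band is not None:
        _, x_est = _sliding_band_ratio(
            lfp, fs, window_s, update_s, n_tapers, x_band, broad_band
        )
        xg, xo = x_transform if x_transform is not None else (1.0, 0.0)
        trace.x_est = x_est
        trace.screen_x = _boxcar2(xg * x_est + xo)
        trace.x_transform = (xg, xo)
    return trace


def normalized_beta_trace(
    lfp: np.ndarray,
    fs: float,
    window_s: float = 0.2,
    step_s: float = 0.01,
    n_tapers: int = 5,
    beta_band: tuple[float, float] = BETA_BAND,
    broad_band: tuple[float, float] = BROAD_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """beta_est at a fine cadence (10 ms default), no transform/smoothing."""
    return _sliding_band_ratio(
        lfp, fs, window_s, step_s, n_tapers, beta_band, broad_band
    )


def detrended_spectrogram(
    trials: np.ndarray,
    fs: float,
    window_s: float = 0.2,
    step_s: float = 0.01,
    n_tapers: int = 5,
    t0_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, DetrendCoefficients]:
    """Trial-averaged spectrogram with the linear 1/f trend removed.

    Power is modeled as ``m * frequency + b`` using every trial and
    timepoint as data; the fit is subtracted before averaging over
    trials.  Windows are centered (offline convention); returned times
    mark window centers on the trials' local axis starting at ``t0_s``.

    Returns ``(times, frequencies, matrix, coefficients)`` with
    ``matrix`` of shape (n_frequencies, n_times).
    """
    trials = np.atleast_2d(np.asarray(trials, float))
    n_win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    if freqs.size < 2:
        raise ValueError("spectrogram window yields a single frequency bin")
    segs = sliding_window_view(trials, n_win, axis=1)[:, ::step]  # (tr, nt, n_win)
    power = _mt_power(segs, fs, n_tapers)  # (tr, nt, n_freq)
    f_flat = np.broadcast_to(freqs, power.shape).ravel()
    p_flat = power.ravel()
    slope, intercept = np.polyfit(f_flat, p_flat, 1)
    detrended = power - (slope * freqs + intercept)
    mat = detrended.mean(axis=0).T  # (n_freq, n_times)
    times = t0_s + (n_win / 2 + step * np.arange(mat.shape[1])) / fs
    return times, freqs, mat, DetrendCoefficients(float(slope), float(intercept))


def zscored_psd(
    psd_matrix: np.ndarray,
    frequencies: np.ndarray,
    labels: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Per-target mean of trial PSDs z-scored frequency-wise across trials.

    Each column (frequency) of the (n_trials, n_freq) matrix is
    standardized by its mean M and standard deviation S over all trials,
    then rows are averaged within each label value.  Frequencies with
    zero variance across trials are dropped with a warning.

    Returns ``(frequencies_retained, {label: mean_zscored_psd})``.
    """
    X = np.asarray(psd_matrix, float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n_trials >= 2, n_frequencies) PSD matrix")
    M = X.mean(axis=0)
    S = X.std(axis=0, ddof=0)
    keep = S > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance frequency bin(s)",
            stacklevel=2,
        )
    Z = (X[:, keep] - M[keep]) / S[keep]
    out = {lab: Z[labels == lab].mean(axis=0) for lab in np.unique(labels)}
    return np.asarray(frequencies)[keep], out
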