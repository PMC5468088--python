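"""Synthetic session generator with ground truth for recovery testing.

Emulates the statistical structure the analysis chain assumes, for a
single recording day containing a center-out (CO) block and a
neurofeedback-reach (NR) block:

- LFP: 1/f^alpha background (spectral shaping of white noise) plus
  transient 25-40 Hz bursts under a plateau envelope with raised-cosine
  (Hann) onset/offset ramps.  Burst prevalence scales with the trial's
  condition (CO, or NR beta target 1-4), emulating higher on-beta
  occupancy for higher beta targets.  Optionally a 1-10 Hz component
  whose power co-modulates (sign-configurable) with burst state.
- Kinematics: near-zero hand speed with jitter before the movement
  onset time (MOT), then a Gaussian bell speed profile toward the
  reach target.  The bell is placed so the projected speed crosses 20%
  of its peak exactly at the true MOT, which is drawn per condition
  from a truncated normal -- so condition-level MOT ordering (the
  study's behavioral effect) is configured directly, not through a
  per-trial closed loop.
- Spikes: per-unit inhomogeneous Poisson with
  rate(t) = max(0, baseline + slope * log10(beta envelope(t))
                 + step * 1[t >= MOT]),
  sampled by thinning.  Per-unit slopes (Hz per log10-amplitude) and
  movement-onset rate steps (Hz) are drawn from configurable normal
  distributions and recorded in the ground truth.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from betapop.burst_detection import beta_amplitude
from betapop.data_model import EventTable, Session, Trial, TrialKinematics

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_lfp",
    "generate_kinematics",
    "generate_spikes",
    "generate_session",
]

CONDITIONS = ("CO", 1, 2, 3, 4)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic day.

    Burst rates are bursts/s per condition; MOT means are seconds from
    the go cue, truncated to (0, 0.7).  ``unit_beta_slope_*`` are Hz per
    log10-amplitude, negative by default (firing decreases during
    beta), and ``unit_mo_step_*`` are Hz added after movement onset.
    """

    seed: int = 0
    fs: float = 1000.0
    n_channels: int = 3

    # trial layout (seconds): go cue sits pre_go_s into each trial
    pre_go_s: float = 1.6
    post_go_s: float = 1.4
    gap_s: float = 0.2

    n_trials_co: int = 40
    n_trials_per_target: int = 40

    # LFP background + bursts
    background_exponent: float = 1.0
    background_scale: float = 10.0  # signal RMS, arbitrary units
    burst_rate_co: float = 0.4
    burst_rates_nr: tuple[float, float, float, float] = (0.25, 0.4, 0.55, 0.7)
    burst_duration_range: tuple[float, float] = (0.2, 0.5)
    burst_carrier_range: tuple[float, float] = (27.0, 37.0)  # inside filter skirts
    burst_ramp_s: float = 0.05
    burst_amplitude_gain: float = 3.0  # x background beta-band RMS
    lowfreq_coupling: float = 0.0  # 1-10 Hz power co-modulation with bursts

    # spiking
    n_units: int = 15
    unit_baseline_rate: float = 20.0
    unit_beta_slope_mean: float = -6.0
    unit_beta_slope_sd: float = 2.5
    unit_mo_step_mean: float = 10.0
    unit_mo_step_sd: float = 3.0

    # kinematics
    mot_mean_co: float = 0.28
    mot_means_nr: tuple[float, float, float, float] = (0.25, 0.28, 0.31, 0.34)
    mot_sd: float = 0.08
    reach_peak_speed: float = 15.0  # cm/s
    reach_distance: float = 6.5  # cm
    speed_jitter: float = 0.1  # cm/s pre-movement noise
    bell_width_s: float = 0.12

    # NR pacing metadata
    mean_time_to_beta_target_s: float = 7.0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        rates = (self.burst_rate_co, *self.burst_rates_nr)
        if any(r < 0 for r in rates):
            raise ValueError("burst rates must be >= 0")
        if self.burst_duration_range[0] < 0.125:
            warnings.warn(
                "burst durations below 125 ms are undetectable by design",
                stacklevel=2,
            )
        for m in (self.mot_mean_co, *self.mot_means_nr):
            if not (0.0 < m < 0.7):
                raise ValueError("MOT means must lie in (0, 0.7)")

    @property
    def trial_len_s(self) -> float:
        return self.pre_go_s + self.post_go_s

    @property
    def trial_stride_s(self) -> float:
        return self.trial_len_s + self.gap_s

    def burst_rate(self, condition) -> float:
        if condition == "CO":
            return self.burst_rate_co
        return self.burst_rates_nr[int(condition) - 1]

    def mot_mean(self, condition) -> float:
        if condition == "CO":
            return self.mot_mean_co
        return self.mot_means_nr[int(condition) - 1]


@dataclass
class GroundTruth:
    """Generator-side record of what the analyses should recover."""

    burst_intervals: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    mot_s: dict[int, float] = field(default_factory=dict)  # true MOT re go cue
    condition: dict[int, object] = field(default_factory=dict)
    unit_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    unit_steps: np.ndarray = field(default_factory=lambda: np.empty(0))
    clamp_warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# LFP


def _shaping(n: int, fs: float, exponent: float) -> np.ndarray:
    """Amplitude shaping |H(f)| ~ f^(-alpha/2) on the rfft grid, DC zeroed."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    return shape


def _background(
    n: int, fs: float, exponent: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^alpha noise with RMS ``scale`` via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * _shaping(n, fs, exponent)
    sig = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(sig**2))
    return sig * (scale / rms) if rms > 0 else sig


def background_beta_rms(config: GeneratorConfig, n: int = 4096) -> float:
    """Expected RMS of the background within the 25-40 Hz band.

    Computed from the imposed amplitude shaping (no noise realization
    involved).
    """
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    s2 = _shaping(n, config.fs, config.background_exponent) ** 2
    total = s2.sum()
    band = s2[(freqs >= 25.0) & (freqs <= 40.0)].sum()
    return config.background_scale * float(np.sqrt(band / total))


def background_envelope_mean(config: GeneratorConfig) -> float:
    """Expected mean of the background beta amplitude envelope.

    The band-passed background is approximately Gaussian, so its
    Hilbert envelope is Rayleigh with scale equal to the band RMS and
    mean sqrt(pi/2) times that.  ``burst_amplitude_gain`` is expressed
    in this unit: a gain of 3 means the burst's peak envelope is three
    times the typical background envelope.
    """
    return float(np.sqrt(np.pi / 2.0)) * background_beta_rms(config)


def _burst_envelope(n: int, ramp: int) -> np.ndarray:
    """Plateau envelope with raised-cosine onset/offset ramps."""
    env = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = up
        env[n - r :] = up[::-1]
    return env


def _draw_bursts(
    rate: float,
    duration: float,
    dur_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Non-overlapping burst intervals from a Poisson count process."""
    n_bursts = rng.poisson(rate * duration)
    intervals: list[tuple[float, float]] = []
    for _ in range(n_bursts):
        d = rng.uniform(*dur_range)
        start = rng.uniform(0.0, max(duration - d, 1e-9))
        if all(start >= e or start + d <= s for s, e in intervals):
            intervals.append((start, start + d))
    return sorted(intervals)


def generate_lfp(
    config: GeneratorConfig,
    condition,
    duration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """One trial's multi-channel LFP plus the true burst intervals.

    The returned signal has shape (n_samples, n_channels): independent
    1/f backgrounds per channel, with each burst (a 25-40 Hz carrier at
    a per-burst random frequency and phase, peak amplitude
    ``burst_amplitude_gain`` times the background beta-band RMS) added
    to every channel.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    config.validate()
    n = int(round(duration * config.fs))
    sig = np.column_stack(
        [
            _background(
                n, config.fs, config.background_exponent, config.background_scale, rng
            )
            for _ in range(config.n_channels)
        ]
    )
    intervals = _draw_bursts(
        config.burst_rate(condition), duration, config.burst_duration_range, rng
    )
    amp = config.burst_amplitude_gain * background_envelope_mean(config)
    t = np.arange(n) / config.fs
    burst_indicator = np.zeros(n)
    for start, end in intervals:
        i0, i1 = int(round(start * config.fs)), int(round(end * config.fs))
        i1 = min(i1, n)
        freq = rng.uniform(*config.burst_carrier_range)
        phase = rng.uniform(0.0, 2 * np.pi)
        env = _burst_envelope(i1 - i0, int(round(config.burst_ramp_s * config.fs)))
        carrier = amp * env * np.cos(2 * np.pi * freq * t[i0:i1] + phase)
        sig[i0:i1] += carrier[:, None]
        burst_indicator[i0:i1] = env
    if config.lowfreq_coupling != 0.0:
        lf_freq = rng.uniform(2.0, 9.0)
        lf_phase = rng.uniform(0.0, 2 * np.pi)
        lf_amp = 0.5 * config.background_scale * (
            1.0 + config.lowfreq_coupling * burst_indicator
        )
        lf_amp = np.clip(lf_amp, 0.0, None)
        sig += (lf_amp * np.cos(2 * np.pi * lf_freq * t + lf_phase))[:, None]
    return sig, intervals


# ---------------------------------------------------------------------------
# Kinematics


def _truncnorm(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def generate_kinematics(
    config: GeneratorConfig,
    condition,
    rng: np.random.Generator,
    target_direction: tuple[float, float] = (1.0, 0.0),
) -> tuple[TrialKinematics, float]:
    """One trial's hand kinematics on a local axis (0 = go cue).

    The projected speed is a Gaussian bell of width ``bell_width_s``
    and peak ``reach_peak_speed`` whose 20%-of-peak crossing sits
    exactly at the true MOT, plus small jitter; before the crossing the
    bell tail stays under 20% of peak by monotonicity.  Returns the
    kinematics (samples spanning [-pre_go_s+0.1, +post_go_s] around the
    go cue) and the true MOT.
    """
    mot = _truncnorm(config.mot_mean(condition), config.mot_sd, 0.0, 0.7, rng)
    fs = config.fs
    t = np.arange(-config.pre_go_s + 0.1, config.post_go_s, 1.0 / fs)
    w = config.bell_width_s
    center = mot + w * np.sqrt(2.0 * np.log(5.0))  # 20% crossing at mot
    speed = config.reach_peak_speed * np.exp(-((t - center) ** 2) / (2 * w**2))
    speed = speed + rng.normal(0.0, config.speed_jitter, t.size)
    u = np.asarray(target_direction, float)
    u = u / np.linalg.norm(u)
    vx = speed * u[0] + rng.normal(0.0, config.speed_jitter / 2, t.size)
    vy = speed * u[1] + rng.normal(0.0, config.speed_jitter / 2, t.size)
    x = np.cumsum(vx) / fs
    y = np.cumsum(vy) / fs
    kin = TrialKinematics(x=x, y=y, vx=vx, vy=vy, fs=fs, t0_s=float(t[0]))
    return kin, mot


# ---------------------------------------------------------------------------
# Spikes


def generate_spikes(
    config: GeneratorConfig,
    envelope: np.ndarray,
    mot_s: float,
    rng: np.random.Generator,
    slopes: np.ndarray | None = None,
    steps: np.ndarray | None = None,
    clamp_report: list[str] | None = None,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains for one trial, by thinning.

    ``envelope`` is the trial's beta amplitude envelope at ``config.fs``
    and ``mot_s`` the movement onset in trial-local seconds (``inf`` for
    a trial with no movement).  Per-unit rate:
    max(0, baseline + slope * log10(envelope) + step * 1[t >= mot]).
    Returns per-unit arrays of spike times in trial-local seconds.
    """
    envelope = np.asarray(envelope, float)
    n = envelope.size
    fs = config.fs
    if slopes is None:
        slopes = np.zeros(config.n_units)
    if steps is None:
        steps = np.zeros(config.n_units)
    floor = max(np.min(envelope[envelope > 0], initial=1e-12), 1e-12)
    log_env = np.log10(np.maximum(envelope, floor))
    t = np.arange(n) / fs
    post = (t >= mot_s).astype(float)
    trains: list[np.ndarray] = []
    for u in range(len(slopes)):
        rate = config.unit_baseline_rate + slopes[u] * log_env + steps[u] * post
        clamped = rate < 0
        if clamped.mean() > 0.5:
            msg = f"unit {u}: rate clamped at 0 for {100 * clamped.mean():.0f}% of samples"
            if clamp_report is not None:
                clamp_report.append(msg)
            else:
                warnings.warn(msg, stacklevel=2)
        rate = np.maximum(rate, 0.0)
        rmax = float(rate.max())
        if rmax <= 0:
            trains.append(np.empty(0))
            continue
        n_cand = rng.poisson(rmax * n / fs)
        cand = np.sort(rng.uniform(0.0, n / fs, n_cand))
        idx = np.minimum((cand * fs).astype(int), n - 1)
        keep = rng.uniform(0.0, 1.0, n_cand) < rate[idx] / rmax
        trains.append(cand[keep])
    return trains


# ---------------------------------------------------------------------------
# Session assembly


def generate_session(
    config: GeneratorConfig, session_id: str = "synthetic"
) -> tuple[Session, GroundTruth]:
    """Assemble a full synthetic day: CO block followed by the NR block.

    Returns the :class:`~betapop.data_model.Session` and the
    :class:`GroundTruth` needed for recovery tests.  Deterministic under
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs

    conditions: list = ["CO"] * config.n_trials_co
    nr_targets = np.tile([1, 2, 3, 4], config.n_trials_per_target)
    conditions += list(rng.permutation(nr_targets))

    n_trials = len(conditions)
    stride = config.trial_stride_s
    n_total = int(round((n_trials * stride) * fs)) if n_trials else int(fs)

    truth = GroundTruth(
        unit_slopes=rng.normal(
            config.unit_beta_slope_mean, config.unit_beta_slope_sd, config.n_units
        ),
        unit_steps=rng.normal(
            config.unit_mo_step_mean, config.unit_mo_step_sd, config.n_units
        ),
    )

    lfp = np.column_stack(
        [
            _background(
                n_total, fs, config.background_exponent, config.background_scale, rng
            )
            for _ in range(config.n_channels)
        ]
    ) if n_trials else np.zeros((n_total, config.n_channels))

    trials: list[Trial] = []
    kin_map: dict[int, TrialKinematics] = {}
    events_rows = []
    spike_times: list[list[np.ndarray]] = [[] for _ in range(config.n_units)]
    amp = config.burst_amplitude_gain * background_envelope_mean(config)

    for i, condition in enumerate(conditions):
        t_start = i * stride
        go_cue = t_start + config.pre_go_s
        i0 = int(round(t_start * fs))
        i1 = int(round((t_start + config.trial_len_s) * fs))

        # bursts confined to the trial extent
        intervals = _draw_bursts(
            config.burst_rate(condition),
            config.trial_len_s,
            config.burst_duration_range,
            rng,
        )
        tloc = np.arange(i1 - i0) / fs
        for s, e in intervals:
            j0, j1 = int(round(s * fs)), min(int(round(e * fs)), i1 - i0)
            freq = rng.uniform(*config.burst_carrier_range)
            phase = rng.uniform(0.0, 2 * np.pi)
            env = _burst_envelope(j1 - j0, int(round(config.burst_ramp_s * fs)))
            carrier = amp * env * np.cos(2 * np.pi * freq * tloc[j0:j1] + phase)
            lfp[i0 + j0 : i0 + j1] += carrier[:, None]

        # kinematics and true MOT
        angle = rng.uniform(0.0, 2 * np.pi)
        direction = (np.cos(angle), np.sin(angle))
        kin, mot = generate_kinematics(config, condition, rng, direction)
        kin = replace(kin, t0_s=kin.t0_s + go_cue)  # shift to session clock
        kin_map[i] = kin

        trial = Trial(
            trial_id=i,
            beta_target=None if condition == "CO" else int(condition),
            reach_target=(
                config.reach_distance * direction[0],
                config.reach_distance * direction[1],
            ),
            go_cue_s=go_cue,
            outcome="rewarded",
            reward_s=go_cue + config.post_go_s - 0.1,
            time_to_beta_target_s=(
                None
                if condition == "CO"
                else float(
                    np.clip(rng.exponential(config.mean_time_to_beta_target_s), 0.5, 60.0)
                )
            ),
        )
        trials.append(trial)
        events_rows += [
            {"trial_id": i, "event_name": "trial_start", "time_s": t_start},
            {"trial_id": i, "event_name": "go_cue", "time_s": go_cue},
            {"trial_id": i, "event_name": "reward", "time_s": trial.reward_s},
        ]
        truth.burst_intervals[i] = [(t_start + s, t_start + e) for s, e in intervals]
        truth.mot_s[i] = mot
        truth.condition[i] = condition

        # spikes driven by the realized beta envelope of channel 0
        env_tr = beta_amplitude(lfp[i0:i1, 0], fs)
        trains = generate_spikes(
            config,
            env_tr,
            config.pre_go_s + mot,
            rng,
            truth.unit_slopes,
            truth.unit_steps,
            clamp_report=truth.clamp_warnings,
        )
        for u, tr in enumerate(trains):
            spike_times[u].append(tr + t_start)

    session = Session(
        session_id=session_id,
        fs_lfp=fs,
        task_kind="NR",
        trials=trials,
        lfp={f"ch{c:02d}": lfp[:, c] for c in range(config.n_channels)},
        spikes={
            f"u{u:02d}": (
                np.concatenate(spike_times[u]) if spike_times[u] else np.empty(0)
            )
            for u in range(config.n_units)
        },
        kinematics=kin_map,
        events=EventTable(
            pd.DataFrame(events_rows, columns=["trial_id", "event_name", "time_s"])
        ),
        units=pd.DataFrame(
            {
                "unit_id": [f"u{u:02d}" for u in range(config.n_units)],
                "channel": ["ch00"] * config.n_units,
                "kind": ["single"] * config.n_units,
            }
        ),
    )
    session.validate()
    return session, truth
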