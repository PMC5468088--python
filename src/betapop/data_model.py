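"""Session container and on-disk I/O shared by every analysis stage.

A :class:`Session` bundles one recording day: continuous multi-channel
LFP at ``fs_lfp`` (1 kHz by default), per-unit spike event times, per-
trial 2-D hand kinematics, and the trial/event tables.  All times are in
seconds, zero-referenced to the start of the session recording; per-
trial alignment (:func:`extract_trial_windows`) produces a local axis
with 0 at the alignment event.  Kinematics are in cm and cm/s.

On disk a session is a directory::

    session/
      signals.h5   # groups lfp/chNN, kin/trialNN/{x,y,vx,vy}, spikes/<unit>
      trials.csv   # trial_id,beta_target,reach_x,reach_y,go_cue_s,outcome,...
      events.csv   # trial_id,event_name,time_s
      units.csv    # unit_id,channel,kind
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "TrialKinematics",
    "EventTable",
    "Session",
    "SessionLoadError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "extract_trial_windows",
]

#: Valid trial outcomes.
OUTCOMES = ("rewarded", "timeout", "hold_error")


class SessionLoadError(IOError):
    """A required session file is missing or unreadable."""


class SessionValidationError(ValueError):
    """Session contents violate a structural invariant."""


@dataclass
class Trial:
    """One behavioral trial.

    ``beta_target`` is the ordinal neurofeedback target 1-4 for NR
    trials and ``None`` for CO (center-out) trials; ``task`` is derived
    from it.  Times are session-clock seconds.
    """

    trial_id: int
    beta_target: int | None
    reach_target: tuple[float, float]
    go_cue_s: float
    outcome: str
    reward_s: float | None = None
    time_to_beta_target_s: float | None = None

    @property
    def task(self) -> str:
        return "CO" if self.beta_target is None else "NR"

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise SessionValidationError(
                f"trial {self.trial_id}: unknown outcome {self.outcome!r}"
            )
        if self.beta_target is not None and self.beta_target not in (1, 2, 3, 4):
            raise SessionValidationError(
                f"trial {self.trial_id}: beta_target must be in 1..4, "
                f"got {self.beta_target}"
            )
        if self.outcome == "rewarded":
            if self.reward_s is None or not (self.go_cue_s < self.reward_s):
                raise SessionValidationError(
                    f"trial {self.trial_id}: rewarded trial requires "
                    f"go_cue_time < reward_time"
                )


@dataclass
class TrialKinematics:
    """Hand position (cm) and velocity (cm/s) for one trial.

    Samples start at session time ``t0_s`` with rate ``fs`` Hz.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    fs: float
    t0_s: float

    def times(self) -> np.ndarray:
        """Session-clock sample times."""
        return self.t0_s + np.arange(self.x.size) / self.fs

    @property
    def velocity(self) -> np.ndarray:
        """(t, 2) velocity array."""
        return np.column_stack([self.vx, self.vy])


@dataclass
class EventTable:
    """Long-form event log: rows of (trial_id, event_name, time_s)."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["trial_id", "event_name", "time_s"]
        )
    )

    def validate(self, trial_ids: set[int]) -> None:
        bad = set(self.rows["trial_id"]) - trial_ids
        if bad:
            raise SessionValidationError(
                f"events reference unknown trial_id(s): {sorted(bad)}"
            )
        for tid, grp in self.rows.groupby("trial_id"):
            t = grp["time_s"].to_numpy(float)
            if np.any(np.diff(t) < 0):
                raise SessionValidationError(
                    f"event times decrease within trial {tid}"
                )

    def for_trial(self, trial_id: int) -> pd.DataFrame:
        return self.rows[self.rows["trial_id"] == trial_id]


@dataclass
class Session:
    """Container for one recording day."""

    session_id: str
    fs_lfp: float = 1000.0
    task_kind: str = "NR"  # NR variant of the day: CO, NR or NR2D
    trials: list[Trial] = field(default_factory=list)
    lfp: dict[str, np.ndarray] = field(default_factory=dict)
    spikes: dict[str, np.ndarray] = field(default_factory=dict)
    kinematics: dict[int, TrialKinematics] = field(default_factory=dict)
    events: EventTable = field(default_factory=EventTable)
    units: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["unit_id", "channel", "kind"])
    )

    @property
    def duration_s(self) -> float:
        if not self.lfp:
            return 0.0
        return max(a.size for a in self.lfp.values()) / self.fs_lfp

    def trials_by_task(self, task: str) -> list[Trial]:
        return [t for t in self.trials if t.task == task]

    def validate(self) -> None:
        if not (self.fs_lfp > 0):
            raise SessionValidationError("fs_lfp must be > 0")
        ids = [t.trial_id for t in self.trials]
        if len(ids) != len(set(ids)):
            raise SessionValidationError("duplicate trial_id")
        if self.units["unit_id"].duplicated().any():
            raise SessionValidationError("duplicate unit_id in units table")
        extent = self.duration_s
        for trial in self.trials:
            trial.validate()
            if self.lfp and not (0.0 <= trial.go_cue_s <= extent):
                raise SessionValidationError(
                    f"trial {trial.trial_id}: go_cue_s {trial.go_cue_s:.3f} "
                    f"outside recording extent {extent:.3f}"
                )
        self.events.validate(set(ids))
        unknown_kin = set(self.kinematics) - set(ids)
        if unknown_kin:
            raise SessionValidationError(
                f"kinematics reference unknown trial_id(s): {sorted(unknown_kin)}"
            )
        table_units = set(self.units["unit_id"].astype(str))
        unknown_units = set(self.spikes) - table_units
        if table_units and unknown_units:
            raise SessionValidationError(
                f"spike trains without units.csv row: {sorted(unknown_units)}"
            )


# ---------------------------------------------------------------------------
# I/O

_TRIAL_COLS = [
    "trial_id",
    "beta_target",
    "reach_x",
    "reach_y",
    "go_cue_s",
    "outcome",
    "reward_s",
    "time_to_beta_target_s",
]


def _fmt(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` to directory ``path`` (created if needed).

    The layout is deterministic: keys are written in sorted order and
    CSV floats use ``repr`` round-trip formatting, so writing the same
    session twice yields byte-identical tables.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in sorted(session.trials, key=lambda t: t.trial_id):
        rows.append(
            {
                "trial_id": t.trial_id,
                "beta_target": "" if t.beta_target is None else t.beta_target,
                "reach_x": _fmt(t.reach_target[0]),
                "reach_y": _fmt(t.reach_target[1]),
                "go_cue_s": _fmt(t.go_cue_s),
                "outcome": t.outcome,
                "reward_s": _fmt(t.reward_s),
                "time_to_beta_target_s": _fmt(t.time_to_beta_target_s),
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLS).to_csv(path / "trials.csv", index=False)

    ev = session.events.rows.sort_values(
        ["trial_id", "time_s", "event_name"], kind="stable"
    )
    ev.to_csv(path / "events.csv", index=False, float_format="%.9g")
    session.units.sort_values("unit_id", kind="stable").to_csv(
        path / "units.csv", index=False
    )

    with h5py.File(path / "signals.h5", "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["fs_lfp"] = float(session.fs_lfp)
        f.attrs["task_kind"] = session.task_kind
        g = f.create_group("lfp")
        for ch in sorted(session.lfp):
            d = g.create_dataset(ch, data=np.asarray(session.lfp[ch], float))
            d.attrs["fs"] = float(session.fs_lfp)
        g = f.create_group("spikes")
        for uid in sorted(session.spikes):
            g.create_dataset(uid, data=np.asarray(session.spikes[uid], float))
        g = f.create_group("kin")
        for tid in sorted(session.kinematics):
            kin = session.kinematics[tid]
            sub = g.create_group(f"trial{tid:04d}")
            sub.attrs["fs"] = float(kin.fs)
            sub.attrs["t0_s"] = float(kin.t0_s)
            for name in ("x", "y", "vx", "vy"):
                sub.create_dataset(name, data=np.asarray(getattr(kin, name), float))


def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionLoadError(f"missing session file: {path}")
    return path


def read_session(path: str | Path) -> Session:
    """Load a session directory written by :func:`write_session`.

    Raises :class:`SessionLoadError` naming the first missing file, or
    :class:`SessionValidationError` if referential integrity fails.
    """
    path = Path(path)
    trials_df = pd.read_csv(_require(path / "trials.csv"))
    events_df = pd.read_csv(_require(path / "events.csv"))
    units_df = pd.read_csv(_require(path / "units.csv"))

    trials = []
    for _, row in trials_df.iterrows():
        bt = row["beta_target"]
        trials.append(
            Trial(
                trial_id=int(row["trial_id"]),
                beta_target=None if pd.isna(bt) else int(bt),
                reach_target=(float(row["reach_x"]), float(row["reach_y"])),
                go_cue_s=float(row["go_cue_s"]),
                outcome=str(row["outcome"]),
                reward_s=None if pd.isna(row["reward_s"]) else float(row["reward_s"]),
                time_to_beta_target_s=(
                    None
                    if pd.isna(row["time_to_beta_target_s"])
                    else float(row["time_to_beta_target_s"])
                ),
            )
        )

    session = Session(session_id="", trials=trials, events=EventTable(events_df))
    session.units = units_df
    with h5py.File(_require(path / "signals.h5"), "r") as f:
        session.session_id = str(f.attrs["session_id"])
        session.fs_lfp = float(f.attrs["fs_lfp"])
        session.task_kind = str(f.attrs["task_kind"])
        for ch in f["lfp"]:
            session.lfp[ch] = f["lfp"][ch][()]
        for uid in f["spikes"]:
            session.spikes[uid] = f["spikes"][uid][()]
        for key in f["kin"]:
            sub = f["kin"][key]
            tid = int(key.removeprefix("trial"))
            session.kinematics[tid] = TrialKinematics(
                x=sub["x"][()],
                y=sub["y"][()],
                vx=sub["vx"][()],
                vy=sub["vy"][()],
                fs=float(sub.attrs["fs"]),
                t0_s=float(sub.attrs["t0_s"]),
            )
    session.validate()
    return session


def sessions_equal(a: Session, b: Session) -> bool:
    """Equality up to floating-point representation (used by round-trip tests)."""
    if (a.session_id, a.fs_lfp, a.task_kind) != (b.session_id, b.fs_lfp, b.task_kind):
        return False
    if len(a.trials) != len(b.trials):
        return False
    for ta, tb in zip(
        sorted(a.trials, key=lambda t: t.trial_id),
        sorted(b.trials, key=lambda t: t.trial_id),
    ):
        if dataclasses.astuple(ta) != dataclasses.astuple(tb):
            return False
    for attr in ("lfp", "spikes"):
        da, db = getattr(a, attr), getattr(b, attr)
        if set(da) != set(db):
            return False
        if not all(np.array_equal(da[k], db[k]) for k in da):
            return False
    if set(a.kinematics) != set(b.kinematics):
        return False
    for tid, ka in a.kinematics.items():
        kb = b.kinematics[tid]
        if (ka.fs, ka.t0_s) != (kb.fs, kb.t0_s):
            return False
        for name in ("x", "y", "vx", "vy"):
            if not np.array_equal(getattr(ka, name), getattr(kb, name)):
                return False
    return True


# ---------------------------------------------------------------------------
# Trial-aligned windowing


@dataclass
class WindowResult:
    """Aligned per-trial signal slices plus an exclusion report."""

    data: np.ndarray  # (n_trials, n_samples) or (n_trials, n_samples, n_channels)
    trial_ids: list[int]
    times: np.ndarray  # local axis, 0 at the alignment event
    dropped: list[tuple[int, str]]


def extract_trial_windows(
    session: Session,
    align: str = "go_cue",
    pre_s: float = 1.5,
    post_s: float = 1.0,
    channels: list[str] | None = None,
    mot_s: dict[int, float] | None = None,
    trials: list[Trial] | None = None,
) -> WindowResult:
    """Slice the session LFP into per-trial windows around an event.

    ``align`` is ``"go_cue"`` or ``"movement_onset"`` (the latter needs
    ``mot_s``: movement-onset time per trial, seconds relative to the go
    cue).  Windows cover ``[event - pre_s, event + post_s)``; every
    retained slice has exactly ``round((pre_s + post_s) * fs)`` samples.
    Trials whose window exceeds the recording are dropped and reported.
    """
    if align not in ("go_cue", "movement_onset"):
        raise ValueError(f"unknown alignment {align!r}")
    if align == "movement_onset" and mot_s is None:
        raise ValueError("align='movement_onset' requires mot_s per trial")
    channels = sorted(session.lfp) if channels is None else channels
    if not channels:
        raise ValueError("session has no LFP channels")
    fs = session.fs_lfp
    n_samples = int(round((pre_s + post_s) * fs))
    n_total = min(session.lfp[ch].size for ch in channels)

    slices, kept, dropped = [], [], []
    for trial in trials if trials is not None else session.trials:
        t_event = trial.go_cue_s
        if align == "movement_onset":
            m = mot_s.get(trial.trial_id)
            if m is None or not np.isfinite(m):
                dropped.append((trial.trial_id, "undefined movement onset"))
                continue
            t_event = trial.go_cue_s + m
        start = int(round((t_event - pre_s) * fs))
        if start < 0 or start + n_samples > n_total:
            dropped.append((trial.trial_id, "window exceeds recording"))
            continue
        block = np.stack(
            [session.lfp[ch][start : start + n_samples] for ch in channels], axis=-1
        )
        slices.append(block[:, 0] if len(channels) == 1 else block)
        kept.append(trial.trial_id)

    if not kept:
        raise ValueError("no trials retained: every window exceeds the recording")
    times = (np.arange(n_samples) - int(round(pre_s * fs))) / fs
    return WindowResult(
        data=np.stack(slices), trial_ids=kept, times=times, dropped=dropped
    )
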