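"""End-to-end orchestration: simulate -> analyze -> report.

``run_pipeline`` executes the stages of the analysis chain on a
synthetic (or previously written) session, writes each stage's outputs
as CSV under the output directory, and records a manifest with the
config snapshot, seed, and per-stage output checksums.  A single
global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence``, so stages are independently
reproducible and deterministic stages yield identical checksums across
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from betapop import burst_detection, chance_sim, spectral, trend_stats
from betapop import kinematics as kin_mod
from betapop import population_decoder as decoder
from betapop import unit_analysis
from betapop.data_model import Session, extract_trial_windows, write_session
from betapop.synthetic_data import GeneratorConfig, GroundTruth, generate_session

__all__ = ["RunManifest", "run_pipeline", "load_config", "run_day_analyses"]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # stage -> path
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a TOML config; unknown or missing-by-typo keys raise by name."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    flat = {}
    for key, value in raw.items():
        if isinstance(value, dict):
            flat.update(value)
        else:
            flat[key] = value
    valid = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(flat) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("burst_rates_nr", "mot_means_nr", "burst_duration_range"):
        if key in flat:
            flat[key] = tuple(flat[key])
    return GeneratorConfig(**flat)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


# ---------------------------------------------------------------------------
# Reusable day-level analysis (also used by the acceptance script)


def run_day_analyses(
    session: Session,
    truth: GroundTruth | None = None,
    seed: int = 0,
    nf_channel: str = "ch00",
) -> dict:
    """Run every analysis stage on one session; return in-memory results."""
    results: dict = {}
    fs = session.fs_lfp

    # --- burst labels on the neurofeedback channel, day-level threshold
    rewarded = [t for t in session.trials if t.outcome == "rewarded"]
    win = extract_trial_windows(session, "go_cue", 1.5, 1.0, channels=[nf_channel])
    envs = {
        tid: burst_detection.beta_amplitude(row, fs)
        for tid, row in zip(win.trial_ids, win.data)
    }
    aggregate = np.concatenate(
        [envs[t.trial_id] for t in rewarded if t.trial_id in envs]
    )
    labels = {
        tid: burst_detection.on_beta_labels(env, aggregate, fs=fs)
        for tid, env in envs.items()
    }
    results["beta_labels"] = labels
    results["beta_envelopes"] = envs
    results["window_trial_ids"] = win.trial_ids

    cond = {
        t.trial_id: ("CO" if t.beta_target is None else t.beta_target)
        for t in session.trials
    }
    pct = {}
    for c in ("CO", 1, 2, 3, 4):
        vals = [
            burst_detection.percent_on_beta(labels[tid])
            for tid in labels
            if cond[tid] == c
        ]
        if vals:
            pct[c] = float(np.mean(vals))
    results["percent_on_beta"] = pct

    # --- movement onset times
    mot = {}
    for t in session.trials:
        k = session.kinematics.get(t.trial_id)
        if k is None:
            continue
        res = kin_mod.movement_onset_time(
            k.velocity, (0.0, 0.0), t.reach_target, k.times() - t.go_cue_s
        )
        mot[t.trial_id] = res.mot_s
    mot_arr = np.array([mot.get(t.trial_id, np.nan) for t in session.trials])
    mask, mot_report = kin_mod.filter_trials_by_mot(mot_arr)
    results["mot_s"] = mot
    results["mot_mask"] = mask
    results["mot_report"] = mot_report

    # --- Cuzick trend of MOT across beta targets (retained NR trials)
    nr_idx = [
        i
        for i, t in enumerate(session.trials)
        if t.beta_target is not None and mask[i]
    ]
    if nr_idx:
        vals = mot_arr[nr_idx]
        labs = np.array([session.trials[i].beta_target for i in nr_idx])
        if np.unique(labs).size >= 2 and np.ptp(vals) > 0:
            results["mot_trend"] = trend_stats.cuzick_trend_test(vals, labs)

    return results


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(
    config: GeneratorConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Simulate a session, run all analysis stages, write outputs + report.

    ``config`` is a :class:`GeneratorConfig` or a TOML config path.
    ``seed`` overrides ``config.seed`` when given.
    """
    if not isinstance(config, GeneratorConfig):
        config = load_config(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed)

    def save(stage: str, df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest.outputs[stage] = str(path)
        manifest.checksums[stage] = _sha256(path)
        return path

    # stage 1: simulate + persist the session
    session, truth = generate_session(config)
    session_dir = out / "session"
    write_session(session, session_dir)
    manifest.outputs["simulate"] = str(session_dir)
    manifest.checksums["simulate"] = _sha256(session_dir / "trials.csv")
    manifest.warnings += truth.clamp_warnings

    day = run_day_analyses(session, truth, seed=config.seed)

    # stage 2: burst summary
    save(
        "bursts",
        pd.DataFrame(
            [
                {"condition": str(c), "mean_percent_on_beta": v}
                for c, v in day["percent_on_beta"].items()
            ]
        ),
        "bursts_summary.csv",
    )

    # stage 3: kinematics
    mot = day["mot_s"]
    save(
        "kinematics",
        pd.DataFrame(
            [
                {
                    "trial_id": t.trial_id,
                    "beta_target": t.beta_target,
                    "mot_s": mot.get(t.trial_id, np.nan),
                    "kept": bool(day["mot_mask"][i]),
                }
                for i, t in enumerate(session.trials)
            ]
        ),
        "kinematics.csv",
    )

    # stage 4: trend statistics
    trend_rows = []
    if "mot_trend" in day:
        tr = day["mot_trend"]
        trend_rows.append(
            {
                "metric": "mot_s",
                "T": tr.T,
                "expected": tr.expected,
                "variance": tr.variance,
                "z": tr.z,
                "p": tr.p,
                "n": tr.n,
            }
        )
    save("trend", pd.DataFrame(trend_rows), "trend.csv")

    # stage 5: unit slopes (CO vs NR) and split-half stability
    fs = session.fs_lfp
    unit_rows = []
    slopes = {}
    for task in ("CO", "NR"):
        trials = [
            t
            for t in session.trials_by_task(task)
            if t.trial_id in day["beta_envelopes"]
        ]
        if not trials:
            continue
        counts, env = _task_counts_and_envelope(session, trials, day)
        maps = unit_analysis.beta_rate_mapping(counts, env, task=task)
        slopes[task] = np.array([m.slope for m in maps])
        s1, s2 = unit_analysis.split_half_slopes(counts, env, task=task)
        r = float(np.corrcoef(s1, s2)[0, 1]) if s1.size >= 3 else np.nan
        for u, m in enumerate(maps):
            unit_rows.append(
                {
                    "unit": u,
                    "task": task,
                    "slope_hz_per_log10amp": m.slope,
                    "split_half_r": r,
                    "true_slope": truth.unit_slopes[u],
                }
            )
    save("units", pd.DataFrame(unit_rows), "unit_slopes.csv")

    # stage 6: decoder
    decoder_rows = []
    chunks = _session_chunks(session, day)
    if chunks is not None:
        co_chunks, all_chunks = chunks
        trials_sorted = np.unique(co_chunks.trial_index)
        cutoff = trials_sorted[int(len(trials_sorted) * 2 / 3) - 1]
        train = co_chunks.subset(co_chunks.trial_index <= cutoff)
        held = co_chunks.subset(co_chunks.trial_index > cutoff)
        clf = decoder.train_mo_classifier(train)
        clf.threshold = decoder.select_threshold(clf, held)
        dist = decoder.mo_distance(clf, all_chunks)
        sel_slow_pre = (~all_chunks.post_mo) & (~all_chunks.fast)
        for state, m in (
            ("on_beta", sel_slow_pre & all_chunks.on_beta),
            ("off_beta", sel_slow_pre & ~all_chunks.on_beta),
        ):
            if m.any():
                decoder_rows.append(
                    {
                        "state": state,
                        "mean_distance": float(dist[m].mean()),
                        "n_chunks": int(m.sum()),
                        "threshold": clf.threshold,
                    }
                )
    save("decoder", pd.DataFrame(decoder_rows), "decoder.csv")

    # report
    report = _render_report(manifest, day, slopes, decoder_rows)
    report_path = out / "report.md"
    report_path.write_text(report)
    manifest.outputs["report"] = str(report_path)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _task_counts_and_envelope(session, trials, day):
    """1 ms spike-count matrix + matching beta envelope over (-1.5, 1) s."""
    fs = session.fs_lfp
    n = int(round(2.5 * fs))
    unit_ids = sorted(session.spikes)
    blocks, envs = [], []
    for t in trials:
        start = t.go_cue_s - 1.5
        counts = np.zeros((n, len(unit_ids)))
        for u, uid in enumerate(unit_ids):
            st = session.spikes[uid]
            rel = st[(st >= start) & (st < start + n / fs)] - start
            idx = np.minimum((rel * fs).astype(int), n - 1)
            np.add.at(counts[:, u], idx, 1.0)
        blocks.append(counts)
        envs.append(day["beta_envelopes"][t.trial_id][:n])
    return np.vstack(blocks), np.concatenate(envs)


def _session_chunks(session, day, bin_s=0.025):
    """CO chunks (for training) and all-trial chunks with labels."""
    fs = session.fs_lfp
    trials = [t for t in session.trials if t.trial_id in day["beta_envelopes"]]
    if not trials:
        return None
    co_ids = [t.trial_id for t in trials if t.beta_target is None]
    if len(co_ids) < 3:
        return None
    n = int(round(2.5 * fs))
    n_bins = int(round(2.5 / bin_s))
    unit_ids = sorted(session.spikes)

    counts = np.zeros((len(trials), n_bins, len(unit_ids)))
    beta = np.zeros((len(trials), n_bins), bool)
    fast = np.zeros((len(trials), n_bins), bool)
    mots = np.full(len(trials), np.inf)
    for i, t in enumerate(trials):
        start = t.go_cue_s - 1.5
        for u, uid in enumerate(unit_ids):
            st = session.spikes[uid]
            rel = st[(st >= start) & (st < start + 2.5)] - start
            idx = np.minimum((rel / bin_s).astype(int), n_bins - 1)
            np.add.at(counts[i, :, u], idx, 1.0)
        beta[i] = burst_detection.bin_labels(
            day["beta_labels"][t.trial_id].labels[:n], bin_s, fs
        ).astype(bool)
        kin = session.kinematics.get(t.trial_id)
        if kin is not None:
            speed = np.hypot(kin.vx, kin.vy)
            t_kin = kin.times() - t.go_cue_s
            sel = (t_kin >= -1.5) & (t_kin < 1.0)
            lab = kin_mod.speed_labels(speed[sel], kin.fs, bin_s)
            fast[i, : lab.size] = lab.astype(bool)
        m = day["mot_s"].get(t.trial_id, np.nan)
        mots[i] = m if np.isfinite(m) else np.inf

    co_mask = np.array([t.beta_target is None for t in trials])
    mean = counts[co_mask].reshape(-1, len(unit_ids)).mean(axis=0)
    sd = counts[co_mask].reshape(-1, len(unit_ids)).std(axis=0)
    all_chunks = decoder.make_chunks(
        counts, mots, beta, fast, bin_s=bin_s, zscore_mean=mean, zscore_sd=sd
    )
    co_chunks = decoder.make_chunks(
        counts[co_mask],
        mots[co_mask],
        beta[co_mask],
        fast[co_mask],
        bin_s=bin_s,
        zscore_mean=mean,
        zscore_sd=sd,
    )
    return co_chunks, all_chunks


def _render_report(manifest, day, slopes, decoder_rows) -> str:
    lines = ["# Pipeline report", ""]
    lines.append(f"Seed: {manifest.seed}")
    lines.append("")
    lines.append("## On-beta occupancy by condition")
    for c, v in day["percent_on_beta"].items():
        lines.append(f"- {c}: {v:.1f}% on-beta")
    if "mot_trend" in day:
        tr = day["mot_trend"]
        lines += [
            "",
            "## MOT trend across beta targets",
            f"- Cuzick z = {tr.z:.3f}, p = {tr.p:.3g}, n = {tr.n}",
        ]
    if slopes:
        lines += ["", "## Beta-to-rate slopes (mean across units, Hz/log10-amp)"]
        for task, s in slopes.items():
            lines.append(f"- {task}: {np.mean(s):.2f}")
    if decoder_rows:
        lines += ["", "## Decoder distance (slow PreMO chunks)"]
        for row in decoder_rows:
            lines.append(
                f"- {row['state']}: mean distance {row['mean_distance']:.4f} "
                f"(n={row['n_chunks']})"
            )
    if manifest.warnings:
        lines += ["", "## Warnings"] + [f"- {w}" for w in manifest.warnings]
    return "\n".join(lines) + "\n"
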