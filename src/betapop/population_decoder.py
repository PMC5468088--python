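"""Logistic population decoding of movement onset from spike-count chunks.

Spiking in the (-1.5, +1.0) s window around the go cue is binned at
25 ms (100 bins per trial), z-scored per unit with the unit's CO-task
mean and standard deviation, and concatenated with two bins of history
into "chunks" of 3 x n_units features (98 chunks per trial; the first
two bins lack history).  A chunk is PreMO when its last bin ends before
the trial's movement onset, PostMO otherwise; its on/off-beta and
slow/fast labels are the majority over its three bins.

A logistic regression classifier (standard logistic link, mild L2
penalty) trained on the first two-thirds of CO trials yields p(PostMO)
per chunk; the signed distance to the movement-onset threshold is
p(PostMO) - threshold (negative = PreMO side), measured in probability
space.  The threshold maximizes percent-correct on held-out CO chunks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ChunkMatrix",
    "MoClassifier",
    "make_chunks",
    "train_mo_classifier",
    "mo_distance",
    "select_threshold",
    "onoff_beta_distance_comparison",
    "select_chosen_units",
]

HISTORY_BINS = 2  # chunk = current bin + this many previous bins


@dataclass
class ChunkMatrix:
    """History-concatenated, z-scored spike-count observations."""

    X: np.ndarray  # (n_chunks, (HISTORY_BINS+1) * n_units)
    post_mo: np.ndarray  # bool per chunk
    on_beta: np.ndarray  # bool per chunk
    fast: np.ndarray  # bool per chunk
    trial_index: np.ndarray  # originating trial per chunk
    t_end: np.ndarray  # last-bin end time re go cue, s
    n_units: int
    excluded_units: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "ChunkMatrix":
        return ChunkMatrix(
            X=self.X[mask],
            post_mo=self.post_mo[mask],
            on_beta=self.on_beta[mask],
            fast=self.fast[mask],
            trial_index=self.trial_index[mask],
            t_end=self.t_end[mask],
            n_units=self.n_units,
            excluded_units=self.excluded_units,
        )

    def unit_features(self, unit: int) -> np.ndarray:
        """(n_chunks, HISTORY_BINS+1) feature block of one unit."""
        lags = HISTORY_BINS + 1
        return self.X[:, [lag * self.n_units + unit for lag in range(lags)]]


@dataclass
class MoClassifier:
    """Fitted logistic movement-onset classifier with its MO threshold."""

    model: LogisticRegression
    threshold: float = 0.5

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    @property
    def weights(self) -> np.ndarray:
        return self.model.coef_[0]

    def prob_post_mo(self, X: np.ndarray) -> np.ndarray:
        """p(PostMO) per chunk; p(PreMO) = 1 - p(PostMO)."""
        post_col = int(np.flatnonzero(self.model.classes_ == 1)[0])
        return self.model.predict_proba(X)[:, post_col]


def make_chunks(
    counts: np.ndarray,
    mot_s: np.ndarray,
    beta_bin_labels: np.ndarray,
    speed_fast_labels: np.ndarray,
    window: tuple[float, float] = (-1.5, 1.0),
    bin_s: float = 0.025,
    zscore_mean: np.ndarray | None = None,
    zscore_sd: np.ndarray | None = None,
) -> ChunkMatrix:
    """Build the chunk matrix from binned spike counts.

    ``counts`` is (n_trials, n_bins, n_units) 25 ms spike counts over
    the alignment window; ``mot_s`` the per-trial movement onset
    relative to the go cue (use +inf for pure pre-movement segments,
    -inf or a pre-window value for all-PostMO).  ``zscore_mean``/``sd``
    are the per-unit CO-task statistics; when omitted they are computed
    from ``counts`` itself.  Units with zero variance are excluded from
    the features and reported on the result.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 3:
        raise ValueError("counts must be (n_trials, n_bins, n_units)")
    n_trials, n_bins, n_units = counts.shape
    if n_bins <= HISTORY_BINS:
        raise ValueError("need more bins than history lags")
    mot_s = np.asarray(mot_s, float)
    beta = np.asarray(beta_bin_labels, bool)
    fast = np.asarray(speed_fast_labels, bool)

    if zscore_mean is None:
        zscore_mean = counts.reshape(-1, n_units).mean(axis=0)
    if zscore_sd is None:
        zscore_sd = counts.reshape(-1, n_units).std(axis=0)
    zscore_mean = np.asarray(zscore_mean, float)
    zscore_sd = np.asarray(zscore_sd, float)
    keep = zscore_sd > 0
    excluded = list(np.flatnonzero(~keep))
    z = (counts[..., keep] - zscore_mean[keep]) / zscore_sd[keep]
    n_kept = int(keep.sum())

    lags = HISTORY_BINS + 1
    n_chunks = n_bins - HISTORY_BINS  # e.g. 100 bins -> 98 chunks
    # features ordered lag-major: [bin-2 units..., bin-1 units..., bin units...]
    feats = np.concatenate(
        [z[:, lag : lag + n_chunks, :] for lag in range(lags)], axis=2
    )
    X = feats.reshape(n_trials * n_chunks, lags * n_kept)

    last_bin = np.arange(HISTORY_BINS, n_bins)
    t_end_local = window[0] + (last_bin + 1) * bin_s  # end time of the last bin
    t_end = np.tile(t_end_local, n_trials)
    post = t_end >= np.repeat(mot_s, n_chunks)

    def majority(labels: np.ndarray) -> np.ndarray:
        stack = np.stack(
            [labels[:, lag : lag + n_chunks] for lag in range(lags)], axis=0
        )
        return (stack.sum(axis=0) * 2 > lags).reshape(-1)

    return ChunkMatrix(
        X=X,
        post_mo=post,
        on_beta=majority(beta),
        fast=majority(fast),
        trial_index=np.repeat(np.arange(n_trials), n_chunks),
        t_end=t_end,
        n_units=n_kept,
        excluded_units=excluded,
    )


def train_mo_classifier(
    chunks: ChunkMatrix, C: float = 100.0, threshold: float = 0.5
) -> MoClassifier:
    """Fit the logistic PreMO/PostMO classifier (mild ridge penalty).

    Train on the chunks you pass in -- conventionally those of the
    first two-thirds of the CO trials, in trial order.
    """
    y = chunks.post_mo.astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    model.fit(chunks.X, y)
    return MoClassifier(model=model, threshold=threshold)


def mo_distance(classifier: MoClassifier, chunks: ChunkMatrix | np.ndarray) -> np.ndarray:
    """Signed distance to the MO threshold: p(PostMO) - threshold."""
    X = chunks.X if isinstance(chunks, ChunkMatrix) else np.asarray(chunks)
    return classifier.prob_post_mo(X) - classifier.threshold


def select_threshold(
    classifier: MoClassifier, held_out: ChunkMatrix, grid_step: float = 0.005
) -> float:
    """Probability threshold maximizing percent-correct on held-out chunks.

    Sweeps a uniform grid; ties resolve to the threshold closest to
    0.5 (so a degenerate constant predictor returns 0.5).
    """
    p = classifier.prob_post_mo(held_out.X)
    y = held_out.post_mo
    thresholds = np.round(np.arange(grid_step, 1.0, grid_step), 10)
    acc = np.array([np.mean((p > thr) == y) for thr in thresholds])
    best = acc.max()
    candidates = thresholds[acc >= best - 1e-12]
    return float(candidates[np.argmin(np.abs(candidates - 0.5))])


def onoff_beta_distance_comparison(
    days: list[dict],
) -> tuple[pd.DataFrame, dict]:
    """Per-day mean signed distance for slow PreMO chunks, on- vs off-beta.

    Each entry of ``days`` maps ``{"distances", "post_mo", "on_beta",
    "fast"}`` to per-chunk arrays for one day (one task).  Days missing
    either beta state among slow PreMO chunks are dropped and reported.
    Returns the per-day table and a paired t-test across days.
    """
    rows, dropped = [], []
    for d, day in enumerate(days):
        dist = np.asarray(day["distances"], float)
        sel = (~np.asarray(day["post_mo"], bool)) & (~np.asarray(day["fast"], bool))
        on = sel & np.asarray(day["on_beta"], bool)
        off = sel & ~np.asarray(day["on_beta"], bool)
        if on.sum() == 0 or off.sum() == 0:
            dropped.append(d)
            continue
        rows.append(
            {
                "day": d,
                "mean_on": float(dist[on].mean()),
                "mean_off": float(dist[off].mean()),
                "n_on": int(on.sum()),
                "n_off": int(off.sum()),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        diffs = df["mean_on"].to_numpy() - df["mean_off"].to_numpy()
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0  # no difference on any day
        else:
            t, p = stats.ttest_rel(df["mean_on"], df["mean_off"])
        test = {"t": float(t), "p": float(p), "n_days": len(df), "dropped": dropped}
    else:
        test = {"t": float("nan"), "p": float("nan"), "n_days": len(df), "dropped": dropped}
    return df, test


def _single_unit_scores(
    chunks: ChunkMatrix, unit: int, train_frac: float, C: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Held-out p(PostMO) for one unit's 3-lag features; None if untrainable."""
    Xu = chunks.unit_features(unit)
    trials = chunks.trial_index
    cutoff_trial = np.quantile(np.unique(trials), train_frac, method="lower")
    train = trials <= cutoff_trial
    y = chunks.post_mo.astype(int)
    if np.unique(y[train]).size < 2 or np.unique(y[~train]).size < 2:
        return None
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    model.fit(Xu[train], y[train])
    post_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(Xu[~train])[:, post_col], ~train


def select_chosen_units(
    chunks_by_task: dict[str, ChunkMatrix],
    metrics: dict[str, np.ndarray] | None = None,
    train_frac: float = 2 / 3,
    alpha: float = 0.05,
    C: float = 100.0,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Partition units into 'chosen' vs 'unchosen' by single-unit decoding.

    A unit is chosen when, in *both* tasks, (1) its single-unit
    classifier's held-out p(PostMO) is significantly lower for actual
    PreMO than PostMO chunks (one-sided Mann-Whitney at ``alpha``), and
    (2) its mean held-out score for on-beta slow chunks is lower than
    for off-beta slow chunks.  Group differences on any supplied
    per-unit ``metrics`` (weight, beta-to-rate slope, mean rate, ...)
    are assessed with the Kruskal-Wallis test; comparisons are skipped
    (empty table) when no unit is chosen.
    """
    tasks = list(chunks_by_task)
    n_units = chunks_by_task[tasks[0]].n_units
    rows = []
    for u in range(n_units):
        crit1_all, crit2_all = [], []
        for task in tasks:
            ch = chunks_by_task[task]
            res = _single_unit_scores(ch, u, train_frac, C)
            if res is None:
                crit1_all.append(False)
                crit2_all.append(False)
                continue
            scores, held = res
            y = ch.post_mo[held]
            p1 = stats.mannwhitneyu(
                scores[~y], scores[y], alternative="less"
            ).pvalue if y.any() and (~y).any() else 1.0
            crit1_all.append(bool(p1 < alpha))
            slow = ~ch.fast[held]
            on = slow & ch.on_beta[held]
            off = slow & ~ch.on_beta[held]
            if on.any() and off.any():
                crit2_all.append(bool(scores[on].mean() < scores[off].mean()))
            else:
                crit2_all.append(False)
        rows.append(
            {
                "unit": u,
                "crit_premo_separation": all(crit1_all),
                "crit_onbeta_lower": all(crit2_all),
                "chosen": all(crit1_all) and all(crit2_all),
            }
        )
    details = pd.DataFrame(rows)
    chosen = details["chosen"].to_numpy()

    comp_rows = []
    if metrics and chosen.any() and (~chosen).any():
        for name, values in metrics.items():
            values = np.asarray(values, float)
            stat, p = stats.kruskal(values[chosen], values[~chosen])
            comp_rows.append(
                {
                    "metric": name,
                    "H": float(stat),
                    "p": float(p),
                    "mean_chosen": float(values[chosen].mean()),
                    "mean_unchosen": float(values[~chosen].mean()),
                }
            )
    return chosen, details, pd.DataFrame(comp_rows)
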