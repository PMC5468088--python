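"""Rank-based trend testing across ordered groups and related regressions.

Cuzick's test for trend assesses whether a metric (e.g. movement onset
time) increases or decreases across ordinally scored groups (e.g. the
four beta targets scored 1..4).  With midranks r_i of the pooled
values, group scores l_j and group sizes n_j:

    T      = sum_j l_j * (rank sum of group j)
    E[T]   = (N + 1) / 2 * sum_j l_j n_j
    Var[T] = [sum_j n_j (l_j - l_bar)^2] * [sum_i (r_i - r_bar)^2] / (N - 1)
    Z      = (T - E[T]) / sqrt(Var[T])

The variance form above is the exact permutation variance of the linear
rank statistic; without ties it reduces to the textbook
(N+1)/12 * (N sum l^2 n - (sum l n)^2), and with ties it incorporates
the standard rank-variance tie correction automatically.  Z is compared
to the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TrendResult",
    "OrderedGroups",
    "cuzick_trend_test",
    "relabel_by_quantile",
    "residual_trend",
    "model_comparison",
]


@dataclass
class OrderedGroups:
    """Per-trial metric values with ordinal group labels and scores."""

    values: np.ndarray
    labels: np.ndarray
    scores: dict | None = None  # label -> numeric score; default 1..k by label order


@dataclass
class TrendResult:
    """Cuzick trend statistic and its normal-approximation p-value."""

    T: float
    expected: float
    variance: float
    z: float
    p: float
    tails: int
    n: int


def cuzick_trend_test(
    values: np.ndarray | OrderedGroups,
    labels: np.ndarray | None = None,
    scores: dict | None = None,
    tails: int = 2,
) -> TrendResult:
    """Cuzick's nonparametric test for ordered group trend.

    ``scores`` maps each group label to its numeric score; by default
    labels are scored by their sorted order (1..k).  ``tails`` selects a
    one- or two-tailed normal p-value (one-tailed: upper tail of Z).
    """
    if isinstance(values, OrderedGroups):
        scores = values.scores if scores is None else scores
        values, labels = values.values, values.labels
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ValueError("values and labels must have equal length")
    N = values.size
    if N < 3:
        raise ValueError("need at least 3 observations")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 non-empty groups")
    if scores is None:
        scores = {lab: j + 1 for j, lab in enumerate(uniq)}
    l = np.asarray([scores[lab] for lab in labels], float)

    ranks = stats.rankdata(values)  # midranks
    T = float(np.sum(l * ranks))
    l_bar = l.mean()
    r_bar = ranks.mean()
    expected = float(N * l_bar * r_bar)
    var = float(np.sum((l - l_bar) ** 2) * np.sum((ranks - r_bar) ** 2) / (N - 1))
    if var <= 0:
        raise ValueError("degenerate data: zero trend variance (all values tied?)")
    z = (T - expected) / np.sqrt(var)
    if tails == 2:
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(z)
    return TrendResult(
        T=T, expected=expected, variance=var, z=float(z), p=float(p), tails=tails, n=N
    )


def relabel_by_quantile(metric: np.ndarray, k: int = 4) -> np.ndarray:
    """Ordinal labels 1..k by quantile membership of each value.

    Label j contains values in the ((j-1)/k, j/k] quantile band;
    boundary values go to the lower group, so group sizes differ by at
    most 1 up to ties.  Invariant under any monotone transform of the
    metric (depends on ranks only).
    """
    metric = np.asarray(metric, float)
    n = metric.size
    if n < k:
        raise ValueError(f"need at least k={k} values")
    if np.ptp(metric) == 0:
        raise ValueError("all values equal: quantile labels undefined")
    max_ranks = stats.rankdata(metric, method="max")
    labels = np.ceil(max_ranks * k / n).astype(int)
    return np.clip(labels, 1, k)


def residual_trend(
    mot: np.ndarray,
    time_to_target: np.ndarray,
    labels: np.ndarray,
    scores: dict | None = None,
    tails: int = 2,
) -> tuple[TrendResult, dict]:
    """Trend test on movement-onset times residualized on time-to-target.

    Fits ``mot ~ time_to_target`` by least squares, forms
    MOT_res = MOT - MOT_pred, and runs Cuzick's test on the residuals
    with the original group labels.  Also reports the regression
    slope's two-sided t-test.
    """
    mot = np.asarray(mot, float)
    ttt = np.asarray(time_to_target, float)
    if np.ptp(ttt) == 0:
        raise ValueError("constant predictor: regression undefined")
    X = sm.add_constant(ttt)
    fit = sm.OLS(mot, X).fit()
    residuals = mot - fit.fittedvalues
    trend = cuzick_trend_test(residuals, labels, scores=scores, tails=tails)
    slope_report = {
        "slope": float(fit.params[1]),
        "slope_t": float(fit.tvalues[1]),
        "slope_p": float(fit.pvalues[1]),
        "r_squared": float(fit.rsquared),
    }
    return trend, slope_report


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return rss, rank


def model_comparison(
    y: np.ndarray,
    predictors: dict[str, np.ndarray],
    models: list[tuple[str, ...]] | None = None,
    nested_pairs: list[tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
):
    """R-squared per linear model and F-tests for nested pairs.

    ``models`` lists predictor-name tuples (each fit with an
    intercept); by default every single predictor plus the first
    predictor paired with each of the others (e.g. mot ~ beta,
    mot ~ gamma, mot ~ LF, mot ~ beta+gamma, mot ~ beta+LF).  Nested
    pairs default to each multi-predictor model against its contained
    single-predictor models; F uses (q, n - p - 1) degrees of freedom
    where q is the number of added coefficients.

    Returns ``(models_df, ftests_df)`` pandas DataFrames.
    """
    import pandas as pd

    y = np.asarray(y, float)
    n = y.size
    names = list(predictors)
    cols = {k: np.asarray(v, float) for k, v in predictors.items()}
    for k, v in cols.items():
        if v.size != n:
            raise ValueError(f"predictor {k!r} length mismatch")

    if models is None:
        models = [(nm,) for nm in names]
        models += [(names[0], nm) for nm in names[1:]]
    if nested_pairs is None:
        nested_pairs = []
        for m in models:
            if len(m) > 1:
                for sub in models:
                    if len(sub) < len(m) and set(sub) <= set(m):
                        nested_pairs.append((sub, m))

    tss = float(np.sum((y - y.mean()) ** 2))
    results = {}
    warnings_list = []
    for m in models:
        X = np.column_stack([np.ones(n)] + [cols[nm] for nm in m])
        cond = np.linalg.cond(X)
        if cond > 1e8:
            warnings_list.append(
                f"model {'+'.join(m)}: ill-conditioned design (cond={cond:.2e})"
            )
        rss, rank = _ols_rss(y, X)
        results[m] = {"rss": rss, "rank": rank}

    models_df = pd.DataFrame(
        [
            {
                "model": "+".join(m),
                "n_predictors": len(m),
                "r_squared": 1.0 - results[m]["rss"] / tss if tss > 0 else np.nan,
                "rss": results[m]["rss"],
            }
            for m in models
        ]
    )

    frows = []
    for reduced, full in nested_pairs:
        rss_r = results[reduced]["rss"]
        rss_f = results[full]["rss"]
        p_full = len(full)
        q = len(full) - len(reduced)
        df_den = n - p_full - 1
        if df_den <= 0:
            raise ValueError("not enough observations for nested F-test")
        num = max(rss_r - rss_f, 0.0) / q
        den = rss_f / df_den
        F = num / den if den > 0 else np.inf
        frows.append(
            {
                "reduced": "+".join(reduced),
                "full": "+".join(full),
                "F": F,
                "df_num": q,
                "df_den": df_den,
                "p": float(stats.f.sf(F, q, df_den)),
            }
        )
    ftests_df = pd.DataFrame(frows)
    models_df.attrs["warnings"] = warnings_list
    return models_df, ftests_df
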