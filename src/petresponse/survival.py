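"""Survival comparison of disease-control vs progressive-disease groups.

Kaplan-Meier estimation goes through lifelines.  Group comparison uses a
*randomization* log-rank test: the standard observed-minus-expected
statistic with hypergeometric variance is referred to its permutation
distribution over random relabelings of group membership (5000 Monte
Carlo permutations by default, add-one p-value correction).  Group means
of percent changes are compared with a bootstrap t-test: both samples are
re-centered to the pooled mean (shifted null), resampled with
replacement, and the Welch t statistic's bootstrap distribution yields a
two-sided p by symmetric tail doubling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve and median.

    ``median_months`` is the smallest time with S(t) <= 0.5, or ``None``
    when the curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    median_months: float | None

    @property
    def median_label(self) -> str:
        return "not reached" if self.median_months is None else f"{self.median_months:g}"


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate from times and event indicators."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("at least one record is required")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    median = kmf.median_survival_time_
    return KMEstimate(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median_months=None if np.isinf(median) else float(median),
    )


def _logrank_components(times, events, labels):
    """(O, E, V) of the log-rank statistic for each row of ``labels``.

    ``labels`` is an (m, n) boolean matrix, one relabeling per row
    (True = group A).  Times must be sorted ascending.
    """
    n = times.size
    uniq_first = np.unique(times, return_index=True)[1]
    d = np.add.reduceat(events.astype(float), uniq_first)
    n_at_risk = (n - uniq_first).astype(float)

    lab = labels.astype(float)
    suffix = np.cumsum(lab[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, uniq_first]
    d1 = np.add.reduceat(lab * events, uniq_first, axis=1)

    observed = d1.sum(axis=1)
    expected = (d * n1 / n_at_risk).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * (n1 / n_at_risk) * (1.0 - n1 / n_at_risk) * (
            (n_at_risk - d) / (n_at_risk - 1.0)
        )
    var_terms = np.where(n_at_risk > 1.0, var_terms, 0.0)
    variance = var_terms.sum(axis=1)
    return observed, expected, variance


def logrank_statistic(times_a, events_a, times_b, events_b) -> float:
    """Chi-square-form log-rank statistic (O - E)^2 / V for two groups."""
    times = np.concatenate([np.asarray(times_a, float), np.asarray(times_b, float)])
    events = np.concatenate(
        [np.asarray(events_a, bool), np.asarray(events_b, bool)]
    )
    labels = np.zeros(times.size, dtype=bool)
    labels[: len(np.asarray(times_a))] = True
    order = np.argsort(times, kind="stable")
    o, e, v = _logrank_components(times[order], events[order], labels[order][None, :])
    if v[0] <= 0:
        return 0.0
    return float((o[0] - e[0]) ** 2 / v[0])


def logrank_permutation(
    times_a, events_a, times_b, events_b, n_perm: int = 5000, seed: int = 0
) -> float:
    """Permutation p-value for the log-rank comparison of two groups.

    Group labels are randomly reassigned ``n_perm`` times with (time,
    event) pairs kept intact; p = (1 + #{permuted >= observed}) /
    (1 + n_perm).  Reproducible under ``seed``.
    """
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([times_a, times_b])
    events = np.concatenate(
        [np.asarray(events_a, bool), np.asarray(events_b, bool)]
    )
    labels = np.zeros(times.size, dtype=bool)
    labels[: times_a.size] = True

    order = np.argsort(times, kind="stable")
    times_sorted, events_sorted = times[order], events[order]
    labels_sorted = labels[order]

    o, e, v = _logrank_components(times_sorted, events_sorted, labels_sorted[None, :])
    observed = (o[0] - e[0]) ** 2 / v[0] if v[0] > 0 else 0.0

    rng = np.random.default_rng(seed)
    perm_labels = rng.permuted(
        np.tile(labels_sorted, (n_perm, 1)), axis=1
    )
    o, e, v = _logrank_components(times_sorted, events_sorted, perm_labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = np.where(v > 0, (o - e) ** 2 / v, 0.0)
    exceed = int((stats >= observed - 1e-12).sum())
    return (1 + exceed) / (1 + n_perm)


def _welch_t(mean_x, var_x, nx, mean_y, var_y, ny):
    denom = np.sqrt(var_x / nx + var_y / ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_x - mean_y) / denom
    return np.where(denom > 0, t, 0.0)


def bootstrap_t(x, y, n_boot: int = 5000, seed: int = 0) -> float:
    """Two-sided bootstrap t-test p-value for a difference in means.

    Shifted-null scheme: both samples are centered to the pooled mean,
    resampled with replacement, and the Welch t statistic recomputed;
    the two-sided p doubles the smaller add-one-corrected tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return 1.0 if x.mean() == y.mean() else 1.0 / (1 + n_boot)
    t_obs = float(
        _welch_t(x.mean(), x.var(ddof=1), x.size, y.mean(), y.var(ddof=1), y.size)
    )
    pooled = np.concatenate([x, y]).mean()
    xs = x - x.mean() + pooled
    ys = y - y.mean() + pooled
    rng = np.random.default_rng(seed)
    bx = xs[rng.integers(0, x.size, size=(n_boot, x.size))]
    by = ys[rng.integers(0, y.size, size=(n_boot, y.size))]
    t_boot = _welch_t(
        bx.mean(axis=1), bx.var(axis=1, ddof=1), x.size,
        by.mean(axis=1), by.var(axis=1, ddof=1), y.size,
    )
    p_hi = (1 + int((t_boot >= t_obs).sum())) / (1 + n_boot)
    p_lo = (1 + int((t_boot <= t_obs).sum())) / (1 + n_boot)
    return min(1.0, 2.0 * min(p_hi, p_lo))


def compare_survival(
    records: pd.DataFrame, n_perm: int = 5000, seed: int = 0
) -> dict:
    """KM medians and permutation log-rank p for a DC vs PD survival table.

    ``records`` needs columns ``time_months``, ``event``, ``group``.
    """
    out: dict = {"seed": seed, "n_perm": n_perm}
    for group in ("DC", "PD"):
        sub = records[records["group"] == group]
        out[f"n_{group}"] = int(len(sub))
        if len(sub):
            km = km_estimate(sub["time_months"], sub["event"])
            out[f"median_{group}"] = km.median_label
    dc = records[records["group"] == "DC"]
    pd_ = records[records["group"] == "PD"]
    if len(dc) and len(pd_):
        out["logrank_p"] = logrank_permutation(
            dc["time_months"], dc["event"], pd_["time_months"], pd_["event"],
            n_perm=n_perm, seed=seed,
        )
    return out


def km_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format KM step functions per group, for plotting or export."""
    rows = []
    for group, sub in records.groupby("group", sort=True):
        km = km_estimate(sub["time_months"], sub["event"])
        for t, s in zip(km.times, km.survival):
            rows.append({"group": group, "time_months": float(t), "survival": float(s)})
    return pd.DataFrame(rows, columns=["group", "time_months", "survival"])


def summarize_changes(
    changes: pd.DataFrame, n_boot: int = 5000, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Per-group mean +/- SD of percent change per metric, with bootstrap-t p.

    ``changes`` needs columns ``patient_id``, ``group`` (DC/PD),
    ``metric`` and ``pct_change``.  Returns a summary frame (one row per
    metric x group; SD is NaN and flagged when a group has < 2 patients)
    and a dict of per-metric p-values (NaN when a group is too small).
    """
    if changes.empty or "metric" not in changes:
        return (
            pd.DataFrame(columns=["metric", "group", "n", "mean", "sd", "flag"]),
            {},
        )
    rows = []
    pvalues: dict[str, float] = {}
    for metric, by_metric in changes.groupby("metric", sort=True):
        samples = {}
        for group, sub in by_metric.groupby("group", sort=True):
            values = sub["pct_change"].to_numpy(dtype=float)
            samples[group] = values
            rows.append({
                "metric": metric,
                "group": group,
                "n": int(values.size),
                "mean": float(values.mean()) if values.size else np.nan,
                "sd": float(values.std(ddof=1)) if values.size >= 2 else np.nan,
                "flag": "" if values.size >= 2 else "fewer than 2 patients",
            })
        if all(samples.get(g, np.empty(0)).size >= 2 for g in ("DC", "PD")):
            pvalues[str(metric)] = bootstrap_t(
                samples["DC"], samples["PD"], n_boot=n_boot, seed=seed
            )
        else:
            pvalues[str(metric)] = float("nan")
    return pd.DataFrame(rows, columns=["metric", "group", "n", "mean", "sd", "flag"]), pvalues
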