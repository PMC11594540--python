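"""Condition-level aggregation of profiles and dose-vs-control statistics.

Profiles are averaged pointwise within a condition, with the standard error
of the mean computed across the chosen unit of replication: individual nuclei
(appropriate for pre-expansion data, where every nucleus is an independent
image) or replicates (expanded plates, where nuclei within a gel share the
device/gel and the replicate mean is the independent unit). Each treated
condition is compared against the control by an independent two-sample
t-test per metric, Student's pooled-variance by default with Welch as an
option, at alpha = 0.05 and with no multiplicity correction by default
(a Benjamini-Hochberg option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .edgemetrics import EdgeMetrics, extract_metrics
from .ringprof import RadialProfile

__all__ = [
    "ConditionSummary",
    "ComparisonResult",
    "aggregate_condition",
    "compare_to_control",
    "dose_response_table",
    "METRIC_NAMES",
    "plot_condition_profiles",
]

METRIC_NAMES = ("outer_slope", "inner_slope", "peak_curvature")


@dataclass
class ConditionSummary:
    condition: str
    mean_profile: np.ndarray
    sem_profile: np.ndarray
    replicate_metrics: list[EdgeMetrics]  # one per unit (nucleus or replicate)
    n_units: int
    unit: str = "nucleus"


@dataclass
class ComparisonResult:
    condition: str
    metric: str
    t_statistic: float
    p_value: float
    significant: bool = field(init=False)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.significant = bool(self.p_value < self.alpha)


def _profile_values(profiles) -> np.ndarray:
    rows = [p.values if isinstance(p, RadialProfile) else np.asarray(p, float) for p in profiles]
    return np.vstack(rows)


def aggregate_condition(
    profiles,
    unit: str = "nucleus",
    replicate_ids=None,
    condition: str = "",
    domain_cap: float = 0.4,
    smoothing: int = 0,
) -> ConditionSummary:
    """Pointwise mean and SEM of profiles across the chosen unit.

    For ``unit="replicate"``, per-replicate profiles are first averaged over
    their nuclei (``replicate_ids`` assigns each profile to a replicate), and
    the edge metrics are computed on those replicate-mean profiles; for
    ``unit="nucleus"`` metrics are per-nucleus. At least two units are
    required for a SEM.
    """
    values = _profile_values(profiles)
    if unit == "replicate":
        if replicate_ids is None:
            raise ValueError("replicate_ids required when unit='replicate'")
        replicate_ids = np.asarray(replicate_ids)
        if len(replicate_ids) != len(values):
            raise ValueError("replicate_ids must match profiles in length")
        units = np.vstack(
            [values[replicate_ids == r].mean(axis=0) for r in pd.unique(replicate_ids)]
        )
    elif unit == "nucleus":
        units = values
    else:
        raise ValueError(f"unknown unit {unit!r}")
    n = units.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units to form a SEM")
    mean = units.mean(axis=0)
    sem = units.std(axis=0, ddof=1) / np.sqrt(n)
    metrics = [extract_metrics(row, domain_cap=domain_cap, smoothing=smoothing) for row in units]
    return ConditionSummary(
        condition=condition,
        mean_profile=mean,
        sem_profile=sem,
        replicate_metrics=metrics,
        n_units=n,
        unit=unit,
    )


def compare_to_control(
    treated,
    control,
    variant: str = "student",
    condition: str = "",
    metric: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided independent two-sample t-test of treated vs control values."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("each group must contain at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if treated.std() == 0 and control.std() == 0 and treated.mean() == control.mean():
        t, p = 0.0, 1.0  # degenerate but well-defined: no evidence of a difference
    else:
        t, p = stats.ttest_ind(treated, control, equal_var=(variant == "student"))
    return ComparisonResult(
        condition=condition, metric=metric, t_statistic=float(t), p_value=float(p), alpha=alpha
    )


def dose_response_table(
    summaries,
    control_label: str,
    variant: str = "student",
    metrics=METRIC_NAMES,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """One comparison per non-control condition per metric.

    Returns a tidy frame (condition, metric, t, p, significant). No
    multiplicity correction is applied unless ``correction="bh"``
    (Benjamini-Hochberg on all p-values in the table).
    """
    by_label = {s.condition: s for s in summaries}
    if control_label not in by_label:
        raise ValueError(f"control condition {control_label!r} missing")
    control = by_label[control_label]
    rows = []
    for s in summaries:
        if s.condition == control_label:
            continue
        for m in metrics:
            res = compare_to_control(
                [getattr(em, m) for em in s.replicate_metrics],
                [getattr(em, m) for em in control.replicate_metrics],
                variant=variant,
                condition=s.condition,
                metric=m,
                alpha=alpha,
            )
            rows.append(
                {
                    "condition": res.condition,
                    "metric": res.metric,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                }
            )
    table = pd.DataFrame(rows, columns=["condition", "metric", "t_statistic", "p_value", "significant"])
    if correction == "bh" and len(table):
        reject, p_adj = _benjamini_hochberg(table["p_value"].to_numpy(), alpha)
        table["p_adjusted"] = p_adj
        table["significant"] = reject
    elif correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    return table


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(p)
    m = len(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    return p_adj < alpha, p_adj


def plot_condition_profiles(summaries, ax=None, cutoff: float | None = None):
    """Mean +/- SEM profile band per condition (layout of a dose-series figure)."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 3.5))
    for s in summaries:
        u = np.linspace(0, 1, len(s.mean_profile))
        if cutoff is not None:
            keep = u <= cutoff
            u = u[keep]
            mean, sem = s.mean_profile[keep], s.sem_profile[keep]
        else:
            mean, sem = s.mean_profile, s.sem_profile
        ax.plot(u, mean, label=s.condition)
        ax.fill_between(u, mean - sem, mean + sem, alpha=0.25)
    ax.set_xlabel("relative distance from edge of dilated mask")
    ax.set_ylabel("relative intensity")
    ax.legend(fontsize="small")
    return ax
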