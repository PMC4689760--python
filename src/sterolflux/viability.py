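"""Plate-viability analysis: vehicle normalization, Welch t, ANOVA + Dunnett.

The study design has independent experiments each carried out in technical
triplicate; technical replicates are averaged within experiment before
testing, so n is the number of independent experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .multcomp import dunnett_critical_value, dunnett_pvalues

__all__ = [
    "DunnettComparison",
    "DunnettResult",
    "normalize_viability",
    "aggregate_experiments",
    "welch_t",
    "anova_dunnett",
    "significance_stars",
]

VEHICLE = "vehicle"

_REQUIRED = {"cell_line", "treatment", "replicate", "experiment", "signal"}


@dataclass
class DunnettComparison:
    treatment: str
    mean_difference: float
    t_statistic: float
    p_adjusted: float
    ci_lo: float
    ci_hi: float


@dataclass
class DunnettResult:
    control: str
    alpha: float
    f_statistic: float
    anova_p: float
    df_error: int
    comparisons: list[DunnettComparison] = field(default_factory=list)

    @property
    def family_size(self) -> int:
        return len(self.comparisons)


def normalize_viability(table: pd.DataFrame, vehicle: str = VEHICLE) -> pd.DataFrame:
    """Express each record as a fraction of its experiment's vehicle mean.

    Normalization is per (cell line, experiment); the vehicle group mean is
    1 by construction, so the operation is idempotent. A missing vehicle
    group is an error.
    """
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    if (table["signal"] < 0).any():
        raise ValueError("negative luminescence counts")
    table = table.copy()
    out = []
    for (line, experiment), chunk in table.groupby(["cell_line", "experiment"]):
        vehicle_rows = chunk[chunk["treatment"] == vehicle]
        if vehicle_rows.empty:
            raise ValueError(
                f"no {vehicle!r} control for cell line {line!r}, experiment {experiment!r}"
            )
        reference = vehicle_rows["signal"].mean()
        if reference <= 0:
            raise ValueError(f"non-positive vehicle mean in experiment {experiment!r}")
        chunk = chunk.assign(viability=chunk["signal"] / reference)
        out.append(chunk)
    return pd.concat(out, ignore_index=True)


def aggregate_experiments(table: pd.DataFrame, value: str = "viability") -> pd.DataFrame:
    """Average technical replicates within each experiment."""
    return (
        table.groupby(["cell_line", "treatment", "experiment"], as_index=False)[value]
        .mean()
    )


def welch_t(a, b) -> tuple[float, float, float]:
    """Two-tailed unpaired Welch t-test: returns (t, Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples; Welch test undefined")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def anova_dunnett(groups: dict, control, alpha: float = 0.05,
                  control_label: str = VEHICLE) -> DunnettResult:
    """One-way ANOVA plus Dunnett two-sided many-to-one comparisons.

    ``groups`` maps treatment label -> sample array; ``control`` is the
    shared control sample. Uses the pooled-variance model; adjusted
    p-values and simultaneous (1 - alpha) CIs come from the multivariate-t
    max-|t| distribution (see :mod:`sterolflux.multcomp`).
    """
    control = np.asarray(control, dtype=float)
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if not samples:
        raise ValueError("need at least one treatment group")
    if control.size < 2 or any(s.size < 2 for s in samples.values()):
        raise ValueError("every group needs n >= 2")
    everything = np.concatenate([control, *samples.values()])
    if np.ptp(everything) == 0:
        raise ValueError("all observations identical; no variance to test")

    f_stat, anova_p = stats.f_oneway(control, *samples.values())

    n_total = everything.size
    k_plus_1 = len(samples) + 1
    df_error = n_total - k_plus_1
    pooled = (
        ((control - control.mean()) ** 2).sum()
        + sum(((s - s.mean()) ** 2).sum() for s in samples.values())
    ) / df_error
    ns = np.array([s.size for s in samples.values()])
    t_stats = np.array(
        [
            (s.mean() - control.mean()) / np.sqrt(pooled * (1 / s.size + 1 / control.size))
            for s in samples.values()
        ]
    )
    p_adj = dunnett_pvalues(t_stats, df_error, ns, control.size)
    crit = dunnett_critical_value(alpha, df_error, ns, control.size)
    comparisons = []
    for (label, s), t_i, p_i in zip(samples.items(), t_stats, p_adj):
        halfwidth = crit * np.sqrt(pooled * (1 / s.size + 1 / control.size))
        diff = float(s.mean() - control.mean())
        comparisons.append(
            DunnettComparison(
                treatment=label,
                mean_difference=diff,
                t_statistic=float(t_i),
                p_adjusted=float(p_i),
                ci_lo=diff - float(halfwidth),
                ci_hi=diff + float(halfwidth),
            )
        )
    return DunnettResult(
        control=control_label,
        alpha=alpha,
        f_statistic=float(f_stat),
        anova_p=float(anova_p),
        df_error=int(df_error),
        comparisons=comparisons,
    )


def significance_stars(p: float) -> str:
    """Star legend used throughout: # <=0.1, * <=0.05, ** <=0.01, *** <=0.001."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "#"
    return "ns"
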