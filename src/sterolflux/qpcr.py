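"""Multi-reference-gene relative qPCR expression and fold-change tests.

Relative expression of a target gene in one sample is
``E_gene^(-Cq_gene)`` divided by the geometric mean of ``E_ref^(-Cq_ref)``
over the reference genes (RPL13A, RPS18, ACTB, GAPDH in the study design).
With all efficiencies equal to 2 this reduces to the familiar
``2^-(Cq_gene - mean Cq_refs)``. Group comparisons are made on log2-scale
per-replicate values (variance stabilizing) with a Welch two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "ExpressionResult",
    "validate_cq_table",
    "reference_normalizer",
    "relative_expression",
    "fold_change_test",
    "analyze_expression",
]

DEFAULT_REFERENCE_GENES = ("RPL13A", "RPS18", "ACTB", "GAPDH")
DEFAULT_EFFICIENCY = 2.0

_REQUIRED_COLUMNS = {"gene", "sample", "condition", "replicate", "cq"}


@dataclass
class ExpressionResult:
    gene: str
    baseline: str
    comparison: str
    log2_fold: float
    sem: float
    p_value: float
    n_baseline: int
    n_comparison: int

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


def validate_cq_table(table: pd.DataFrame, ref_genes=DEFAULT_REFERENCE_GENES) -> pd.DataFrame:
    """Check the long-format Cq table and fill the default efficiency."""
    missing = _REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    table = table.copy()
    if "efficiency" not in table.columns:
        table["efficiency"] = DEFAULT_EFFICIENCY
    table["efficiency"] = table["efficiency"].fillna(DEFAULT_EFFICIENCY)
    if ((table["cq"] <= 0) | (table["cq"] >= 45)).any():
        raise ValueError("Cq values must lie in (0, 45)")
    if ((table["efficiency"] <= 1) | (table["efficiency"] > 2.2)).any():
        raise ValueError("amplification efficiencies must lie in (1, 2.2]")
    present = table.groupby("sample")["gene"].apply(set)
    for sample, genes in present.items():
        lacking = set(ref_genes) - genes
        if lacking:
            raise ValueError(f"sample {sample!r} lacks reference genes {sorted(lacking)}")
    return table


def reference_normalizer(sample_slice: pd.DataFrame, ref_genes=DEFAULT_REFERENCE_GENES) -> float:
    """Per-sample normalization factor from the reference genes.

    Geometric mean of efficiency^(-Cq) across the reference genes;
    equivalently 2^(-mean Cq) when all efficiencies are 2.
    """
    quantities = []
    for gene in ref_genes:
        rows = sample_slice[sample_slice["gene"] == gene]
        if rows.empty:
            raise ValueError(f"reference gene {gene!r} missing from sample")
        eff = rows["efficiency"].iloc[0] if "efficiency" in rows else DEFAULT_EFFICIENCY
        quantities.append(float(eff) ** (-float(rows["cq"].iloc[0])))
    return float(np.exp(np.mean(np.log(quantities))))


def relative_expression(
    table: pd.DataFrame, gene: str, ref_genes=DEFAULT_REFERENCE_GENES
) -> pd.DataFrame:
    """Per-sample relative quantity of one gene against the reference set.

    Samples missing the target gene are dropped with a warning column-free
    message; the result keeps sample, condition and replicate identifiers.
    """
    table = validate_cq_table(table, ref_genes)
    rows = []
    for sample, chunk in table.groupby("sample"):
        target = chunk[chunk["gene"] == gene]
        if target.empty:
            import warnings

            warnings.warn(f"sample {sample!r} lacks gene {gene!r}; dropped", stacklevel=2)
            continue
        normalizer = reference_normalizer(chunk, ref_genes)
        eff = float(target["efficiency"].iloc[0])
        quantity = eff ** (-float(target["cq"].iloc[0])) / normalizer
        rows.append(
            {
                "gene": gene,
                "sample": sample,
                "condition": target["condition"].iloc[0],
                "replicate": target["replicate"].iloc[0],
                "relative_expression": quantity,
            }
        )
    if not rows:
        raise ValueError(f"gene {gene!r} absent from every sample")
    return pd.DataFrame(rows)


def fold_change_test(
    table: pd.DataFrame,
    gene: str,
    baseline: str,
    comparison: str,
    ref_genes=DEFAULT_REFERENCE_GENES,
) -> ExpressionResult:
    """Log2 fold change of ``comparison`` over ``baseline`` with a Welch t-test.

    The fold is the difference of mean per-replicate log2 relative
    expressions; the test runs on those same log2 values, two-tailed,
    without assuming equal variances.
    """
    rel = relative_expression(table, gene, ref_genes)
    log2_a = np.log2(rel.loc[rel["condition"] == baseline, "relative_expression"].to_numpy())
    log2_b = np.log2(rel.loc[rel["condition"] == comparison, "relative_expression"].to_numpy())
    if log2_a.size < 2 or log2_b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    fold = float(log2_b.mean() - log2_a.mean())
    sem = float(np.sqrt(log2_b.var(ddof=1) / log2_b.size + log2_a.var(ddof=1) / log2_a.size))
    if log2_a.var(ddof=1) == 0 and log2_b.var(ddof=1) == 0:
        if fold == 0:
            p = 1.0
        else:
            raise ValueError("zero variance in both groups; t-test undefined")
    else:
        p = float(stats.ttest_ind(log2_b, log2_a, equal_var=False).pvalue)
    return ExpressionResult(
        gene=gene, baseline=baseline, comparison=comparison,
        log2_fold=fold, sem=sem, p_value=p,
        n_baseline=int(log2_a.size), n_comparison=int(log2_b.size),
    )


def analyze_expression(
    table: pd.DataFrame,
    genes,
    baseline: str,
    comparison: str,
    ref_genes=DEFAULT_REFERENCE_GENES,
) -> pd.DataFrame:
    """Fold-change table across genes.

    Per-gene p-values are unadjusted (matching per-gene significance
    marking); a Benjamini-Hochberg ``q_value`` column is added as clearly
    supplementary output.
    """
    results = [fold_change_test(table, g, baseline, comparison, ref_genes) for g in genes]
    out = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "log2_fold": [r.log2_fold for r in results],
            "sem": [r.sem for r in results],
            "p_value": [r.p_value for r in results],
            "n_baseline": [r.n_baseline for r in results],
            "n_comparison": [r.n_comparison for r in results],
        }
    )
    out["q_value_bh"] = stats.false_discovery_control(out["p_value"].to_numpy())
    return out
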