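"""Differential screening of multi-tissue miRNA expression banks.

The input is a log2 expression matrix (miRNA x array) with a per-array
annotation sidecar assigning each array to a tissue (healthy kidney,
bladder, prostate, or ccRCC kidney).  Screening compares ccRCC arrays
against healthy kidney arrays miRNA by miRNA, choosing the test through
the normality gate (t-test when both groups pass the Lilliefors KS test,
Mann-Whitney otherwise) and classifying by fold and significance:
over-expressed at log2 difference >= 1.73 (3.3-fold), under-expressed at
<= -0.77 (1.7-fold), both at p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diagnostics import ks_normal

__all__ = [
    "TISSUES",
    "ExpressionMatrix",
    "read_expression_matrix",
    "screen_differential",
]

TISSUES = ("kidney", "bladder", "prostate", "ccRCC_kidney")

UP_THRESHOLD = 1.73  # log2, = 3.3-fold
DOWN_THRESHOLD = 0.77  # log2, = 1.7-fold


@dataclass
class ExpressionMatrix:
    """log2 expression values (rows = miRNAs, columns = arrays) plus a
    per-array annotation table (columns: tissue, optionally sex)."""

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate miRNA identifiers: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite (no missing values)")
        unannotated = self.values.columns.difference(self.annotations.index)
        if len(unannotated):
            raise ValueError(f"arrays without annotation: {list(unannotated)[:5]}")
        bad = set(self.annotations["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)} (expected {TISSUES})")

    def arrays_for(self, tissue: str) -> list[str]:
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r} (expected one of {TISSUES})")
        keep = self.annotations.index[self.annotations["tissue"] == tissue]
        return [a for a in self.values.columns if a in set(keep)]


def read_expression_matrix(matrix_path, annotations_path) -> ExpressionMatrix:
    """TSV loaders: matrix with miRNA IDs in the first column and array
    IDs in the header; sidecar with columns array_id, tissue[, sex]."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotations_path, sep="\t").set_index("array_id")
    return ExpressionMatrix(values, ann)


def screen_differential(
    expr: ExpressionMatrix,
    case_tissue: str = "ccRCC_kidney",
    control_tissue: str = "kidney",
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
    alpha: float = 0.05,
    equal_var: bool = True,
    fdr_correct: bool = False,
) -> pd.DataFrame:
    """Per-miRNA differential screen between two tissues.

    Returns one row per miRNA (sorted by descending log2 difference) with
    columns mirna, log2_delta, p_value, test_used, classification.  The
    log2 difference is mean(case) - mean(control) of the log2 values.
    Classification demands both the fold threshold and p < alpha; by
    default no multiple-testing correction is applied (Benjamini-Hochberg
    behind ``fdr_correct``).
    """
    case_cols = expr.arrays_for(case_tissue)
    control_cols = expr.arrays_for(control_tissue)
    for name, cols in ((case_tissue, case_cols), (control_tissue, control_cols)):
        if len(cols) < 3:
            raise ValueError(f"group {name!r} has {len(cols)} arrays; need >= 3")
    if down_threshold < 0 or up_threshold < 0:
        raise ValueError("thresholds are magnitudes and must be nonnegative")

    case = expr.values[case_cols].to_numpy(dtype=float)
    control = expr.values[control_cols].to_numpy(dtype=float)
    rows = []
    for i, mirna in enumerate(expr.values.index):
        a, b = case[i], control[i]
        delta = float(a.mean() - b.mean())
        degenerate = np.std(a) == 0 and np.std(b) == 0
        if degenerate and a[0] == b[0]:
            test, p = "mann_whitney", 1.0
        elif ks_normal(a, alpha) and ks_normal(b, alpha):
            test = "unpaired_t"
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        else:
            test = "mann_whitney"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((str(mirna), delta, p, test))
    out = pd.DataFrame(rows, columns=["mirna", "log2_delta", "p_value", "test_used"])
    p_eff = (
        multipletests(out["p_value"], method="fdr_bh")[1]
        if fdr_correct
        else out["p_value"]
    )
    out["classification"] = "unclassified"
    out.loc[(out["log2_delta"] >= up_threshold) & (p_eff < alpha), "classification"] = (
        "overexpressed"
    )
    out.loc[
        (out["log2_delta"] <= -down_threshold) & (p_eff < alpha), "classification"
    ] = "underexpressed"
    return out.sort_values("log2_delta", ascending=False, kind="stable").reset_index(
        drop=True
    )
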