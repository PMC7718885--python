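"""The urinary parameter panel: derivative transform, subset search, scoring.

Three test miRNAs (miR-122, miR-1271, miR-15b) and three internal
controls (miR-16, cel-miR-39, miRTC) measured in urine give 12
parameters per subject: the three raw Ct values and the nine dCt
normalizations (each test miRNA against each control).

Each parameter is re-expressed as a *derivative* against the ccRCC
training range (mean m, SD s of the ccRCC group):

* parameters whose ccRCC mean is LOWER than the healthy mean:
  D = value - (m + s)
* parameters whose ccRCC mean is HIGHER than the healthy mean:
  D = (m - s) - value

so that a negative derivative always lies in the diseased range.  Summing
the derivatives of a chosen parameter subset yields a per-subject panel
score; scores below the cutoff (-6.7 by default) call the subject
diseased.  The subset itself is found by exhaustive enumeration of all
subsets of sizes 7-11 (1,585 of them), ranked by training AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import DiagnosticMetrics, roc_auc, sens_spec_at_cutoff

__all__ = [
    "TEST_MIRNAS",
    "NORMALIZERS",
    "PARAMETER_DEFS",
    "SEVEN_PARAM_SUBSET",
    "DEFAULT_CUTOFF",
    "ParameterMatrix",
    "TrainingReference",
    "DerivativeMatrix",
    "PanelModel",
    "PanelResult",
    "build_parameter_matrix",
    "fit_reference",
    "derivative",
    "derivative_matrix",
    "panel_sum",
    "classify",
    "choose_cutoff",
    "search_best_panel",
    "fit_panel",
    "score_cohort",
]

TEST_MIRNAS = ("miR-122", "miR-1271", "miR-15b")
NORMALIZERS = ("miR-16", "miRTC", "cel-miR-39")

#: fixed parameter mapping: index -> (target, normalizer or None)
PARAMETER_DEFS: dict[int, tuple[str, Optional[str]]] = {
    1: ("miR-122", None),
    2: ("miR-1271", None),
    3: ("miR-15b", None),
    4: ("miR-122", "miR-16"),
    5: ("miR-122", "miRTC"),
    6: ("miR-122", "cel-miR-39"),
    7: ("miR-1271", "miR-16"),
    8: ("miR-1271", "miRTC"),
    9: ("miR-1271", "cel-miR-39"),
    10: ("miR-15b", "miR-16"),
    11: ("miR-15b", "miRTC"),
    12: ("miR-15b", "cel-miR-39"),
}

#: the seven-parameter panel behind the 7p-urinary score
SEVEN_PARAM_SUBSET: tuple[int, ...] = (2, 4, 5, 7, 8, 11, 12)

DEFAULT_CUTOFF = -6.7
CASE_GROUP = "ccRCC"
CONTROL_GROUP = "HS"


def _param_cols(indices: Iterable[int]) -> list[str]:
    return [f"p{i}" for i in indices]


@dataclass
class ParameterMatrix:
    """Subject x parameter (Ct or dCt) values plus group labels."""

    values: pd.DataFrame  # columns p1..p12, index = subject
    groups: pd.Series  # index = subject, values in {ccRCC, HS}

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValueError("values and groups indexed by different subjects")
        if self.values.isna().any().any():
            raise ValueError("parameter matrix has missing cells after QC")

    def case_mask(self) -> np.ndarray:
        return (self.groups == CASE_GROUP).to_numpy()


@dataclass
class TrainingReference:
    """Per-parameter ccRCC mean m, SD s, and direction of the group shift.

    ``direction`` is 'lower' when the ccRCC mean is below the healthy mean
    for that parameter and 'higher' otherwise; equal means default to
    'lower' with a warning (deterministic behaviour on degenerate data).
    """

    table: pd.DataFrame  # index p1..p12, columns m, s, direction

    def __post_init__(self) -> None:
        missing = {"m", "s", "direction"} - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table missing columns {sorted(missing)}")
        if (self.table["s"] < 0).any():
            raise ValueError("negative SD in training reference")

    def to_dict(self) -> dict:
        return {
            p: {
                "m": float(r["m"]),
                "s": float(r["s"]),
                "direction": str(r["direction"]),
            }
            for p, r in self.table.iterrows()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingReference":
        return cls(pd.DataFrame.from_dict(d, orient="index")[["m", "s", "direction"]])


@dataclass
class DerivativeMatrix:
    """Subject x parameter derivatives; negative values = diseased range."""

    values: pd.DataFrame
    groups: pd.Series


def build_parameter_matrix(cohort: pd.DataFrame) -> ParameterMatrix:
    """Consensus Ct table -> the 12-parameter matrix.

    ``cohort`` is a wide frame indexed by subject with one column per
    target (the three test miRNAs and three internal controls) and a
    ``group`` column.  Subjects failing the miR-16 gate (``gate_ok``
    column, when present) are dropped.  dCt parameters are target Ct
    minus normalizer Ct.
    """
    df = cohort
    if "gate_ok" in df.columns:
        df = df[df["gate_ok"].astype(bool)]
    needed = set(TEST_MIRNAS) | set(NORMALIZERS)
    for subject in df.index:
        for target in sorted(needed):
            if target not in df.columns or pd.isna(df.at[subject, target]):
                raise ValueError(f"subject {subject!r} is missing target {target!r}")
    out = pd.DataFrame(index=df.index)
    for idx, (target, normalizer) in PARAMETER_DEFS.items():
        col = df[target] if normalizer is None else df[target] - df[normalizer]
        out[f"p{idx}"] = col.astype(float)
    return ParameterMatrix(out, df["group"].astype(str))


def fit_reference(params: ParameterMatrix) -> TrainingReference:
    """Fit the ccRCC training range (mean, sample SD) and shift direction.

    The mean and SD come from the ccRCC group only; the direction flag
    compares the ccRCC mean with the healthy mean.
    """
    case = params.case_mask()
    n_case, n_control = int(case.sum()), int((~case).sum())
    if n_case < 2 or n_control < 2:
        raise ValueError(
            f"need >=2 subjects per group (got {n_case} ccRCC, {n_control} HS)"
        )
    cc = params.values.loc[case]
    hs = params.values.loc[~case]
    rows = {}
    for col in params.values.columns:
        m = float(cc[col].mean())
        s = float(cc[col].std(ddof=1))
        hs_mean = float(hs[col].mean())
        if m == hs_mean:
            warnings.warn(
                f"{col}: equal group means; direction defaults to 'lower'",
                stacklevel=2,
            )
        direction = "lower" if m <= hs_mean else "higher"
        rows[col] = {"m": m, "s": s, "direction": direction}
    return TrainingReference(pd.DataFrame.from_dict(rows, orient="index"))


def derivative(value: float, m: float, s: float, direction: str) -> float:
    """Direction-dependent derivative; negative = diseased range."""
    if direction == "lower":
        return float(value) - (m + s)
    if direction == "higher":
        return (m - s) - float(value)
    raise ValueError(f"unknown direction {direction!r}")


def derivative_matrix(params: ParameterMatrix, ref: TrainingReference) -> DerivativeMatrix:
    out = pd.DataFrame(index=params.values.index)
    for col in params.values.columns:
        r = ref.table.loc[col]
        if r["direction"] == "lower":
            out[col] = params.values[col] - (r["m"] + r["s"])
        else:
            out[col] = (r["m"] - r["s"]) - params.values[col]
    return DerivativeMatrix(out, params.groups)


def _validate_subset(subset: Iterable[int]) -> tuple[int, ...]:
    subset = tuple(sorted(set(int(i) for i in subset)))
    if not subset:
        raise ValueError("parameter subset must be nonempty")
    bad = [i for i in subset if i not in PARAMETER_DEFS]
    if bad:
        raise ValueError(f"parameter indices outside 1-12: {bad}")
    return subset


def panel_sum(derivs: DerivativeMatrix, subset: Iterable[int]) -> pd.Series:
    """Per-subject panel score: the sum of derivatives over ``subset``."""
    subset = _validate_subset(subset)
    return derivs.values[_param_cols(subset)].sum(axis=1)


def classify(score, cutoff: float = DEFAULT_CUTOFF):
    """Score below the cutoff (strict) -> diseased, else healthy."""
    arr = np.asarray(score, dtype=float)
    out = np.where(arr < cutoff, "diseased", "healthy")
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


def choose_cutoff(scores, labels) -> float:
    """Cutoff for a new cohort: the midpoint between the adjacent
    case/control scores that maximizes Youden's J (positive = low)."""
    cut, _ = _youden_cutoff(
        np.asarray(scores, dtype=float), np.asarray(labels, dtype=bool)
    )
    return cut


def _youden_cutoff(s: np.ndarray, lab: np.ndarray) -> tuple[float, float]:
    """(cutoff, J): lowest midpoint between adjacent distinct scores that
    maximizes Youden's J, classification = score strictly below cutoff."""
    uniq = np.unique(s)
    if uniq.size < 2:
        return float(uniq[0]), 0.0
    cuts = 0.5 * (uniq[:-1] + uniq[1:])
    case_sorted = np.sort(s[lab])
    ctrl_sorted = np.sort(s[~lab])
    sens = np.searchsorted(case_sorted, cuts, side="left") / case_sorted.size
    fpr = np.searchsorted(ctrl_sorted, cuts, side="left") / ctrl_sorted.size
    j = sens - fpr
    i = int(np.argmax(j))  # argmax takes the first (lowest) maximizer
    return float(cuts[i]), float(j[i])


@dataclass
class PanelModel:
    """Everything needed to score a new subject: training reference,
    parameter subset, and cutoff.  Round-trips through JSON."""

    reference: TrainingReference
    subset: tuple[int, ...]
    cutoff: float = DEFAULT_CUTOFF

    def to_json(self, **meta) -> str:
        payload = {
            "schema": "uromir-panel-model/1",
            "subset": list(self.subset),
            "cutoff": self.cutoff,
            "reference": self.reference.to_dict(),
        }
        payload.update(meta)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PanelModel":
        d = json.loads(text)
        return cls(
            TrainingReference.from_dict(d["reference"]),
            tuple(d["subset"]),
            float(d["cutoff"]),
        )


@dataclass
class PanelResult:
    subset: tuple[int, ...]
    scores: pd.Series
    cutoff: float
    metrics: DiagnosticMetrics
    n_tied_at_max: int = 1  # subsets sharing the maximal AUC


def _auc_positive_low(scores: np.ndarray, case: np.ndarray) -> float:
    """Concordance AUC (ties 1/2) with low scores indicating disease."""
    ranks = stats.rankdata(scores)
    n1 = int(case.sum())
    n0 = len(scores) - n1
    # sum of case ranks counts P(case > x) pairs; invert for positive-low
    u_high = ranks[case].sum() - n1 * (n1 + 1) / 2.0
    return 1.0 - u_high / (n1 * n0)


def search_best_panel(
    derivs: DerivativeMatrix,
    sizes: Iterable[int] = range(7, 12),
    criterion: str = "auc",
    cutoff: Optional[float] = None,
) -> PanelResult:
    """Exhaustive subset search over the given panel sizes.

    Every subset of each requested size is enumerated (1,585 subsets for
    sizes 7-11 of 12 parameters) and ranked by training AUC with the
    per-subject score as the derivative sum (lower = diseased).  Ties are
    broken deterministically: higher AUC, then higher Youden J at the
    J-optimal cutoff, then smaller subset, then lexicographic index
    order.  The number of subsets sharing the maximal AUC is recorded.
    """
    if criterion != "auc":
        raise ValueError(f"unsupported criterion {criterion!r}")
    sizes = sorted(set(int(k) for k in sizes))
    if not sizes:
        raise ValueError("empty panel-size list")
    if any(k < 1 or k > len(PARAMETER_DEFS) for k in sizes):
        raise ValueError("panel sizes must lie in 1..12")
    case = (derivs.groups == CASE_GROUP).to_numpy()
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("need >=2 subjects per group for the subset search")

    mat = derivs.values[_param_cols(PARAMETER_DEFS)].to_numpy()
    col_of = {i: k for k, i in enumerate(PARAMETER_DEFS)}

    best = None  # (auc, J, -size, subset) maximized lexicographically-ish
    best_scores = None
    n_at_max, max_auc = 0, -np.inf
    for size in sizes:
        for subset in combinations(sorted(PARAMETER_DEFS), size):
            scores = mat[:, [col_of[i] for i in subset]].sum(axis=1)
            auc = _auc_positive_low(scores, case)
            if auc > max_auc + 1e-12:
                max_auc, n_at_max = auc, 1
            elif abs(auc - max_auc) <= 1e-12:
                n_at_max += 1
            _, j = _youden_cutoff(scores, case)
            key = (auc, j, -size, tuple(-i for i in subset))
            if best is None or key > best[0]:
                best = (key, subset)
                best_scores = scores
    subset = best[1]
    score_series = pd.Series(best_scores, index=derivs.values.index, name="score")
    cut = choose_cutoff(best_scores, case) if cutoff is None else cutoff
    metrics = sens_spec_at_cutoff(score_series.to_numpy(), case, cutoff=cut)
    return PanelResult(tuple(subset), score_series, cut, metrics, n_tied_at_max=n_at_max)


def fit_panel(
    cohort: pd.DataFrame,
    sizes: Iterable[int] = range(7, 12),
    cutoff: Optional[float] = None,
) -> tuple[PanelModel, PanelResult, DerivativeMatrix]:
    """End-to-end training: consensus Ct table -> fitted panel model.

    Returns the serializable model, the in-sample search result and the
    derivative matrix.  When ``cutoff`` is None the Youden-midpoint rule
    picks it from the training scores.
    """
    params = build_parameter_matrix(cohort)
    ref = fit_reference(params)
    derivs = derivative_matrix(params, ref)
    result = search_best_panel(derivs, sizes=sizes, cutoff=cutoff)
    model = PanelModel(ref, result.subset, result.cutoff)
    return model, result, derivs


def score_cohort(model: PanelModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted panel model to a (new) consensus Ct cohort."""
    params = build_parameter_matrix(cohort)
    derivs = derivative_matrix(params, model.reference)
    scores = panel_sum(derivs, model.subset)
    return pd.DataFrame(
        {
            "group": params.groups,
            "score": scores,
            "call": classify(scores.to_numpy(), model.cutoff),
        }
    )
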