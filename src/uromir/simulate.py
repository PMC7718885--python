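"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators, both fully deterministic given their seed:

* a urinary qPCR cohort -- per-subject Ct for the three test miRNAs and
  three internal controls, drawn as independent normals per target with
  a case-group mean shift, truncated to the instrument's working range
  [10, 38], plus optional absent calls (Ct = 40);
* a multi-tissue expression bank -- log2 microarray-like values with
  per-miRNA baselines, mild tissue specificity, and planted over/under-
  expression in the ccRCC tissue.

The default cohort emulates the discovery study's conditions: control
Ct means near the observed population medians (31.46 / 28.31 / 29.48
for miR-122 / miR-1271 / miR-15b), case shifts of -3.9, -1.74 and -0.86
cycles for the test miRNAs, and -1, -4 and -6 cycles for miR-16,
cel-miR-39 and miRTC (the divergent internal-control behaviour observed
in ccRCC urine).  Per-target SDs are chosen to be consistent with the
reported group-comparison p-values at n = 13 vs 14.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .expression import TISSUES, ExpressionMatrix

__all__ = [
    "TargetSpec",
    "CohortSpec",
    "BankSpec",
    "SimulatedBank",
    "default_cohort_spec",
    "null_cohort_spec",
    "simulate_urinary_cohort",
    "default_bank_spec",
    "simulate_expression_bank",
]

CT_LOW, CT_HIGH = 10.0, 38.0
ABSENT_CT = 40.0


@dataclass(frozen=True)
class TargetSpec:
    """Noise model for one assay target (Ct scale, cycles)."""

    control_mean: float
    sd: float
    case_shift: float = 0.0  # negative = lower Ct = more abundant in cases
    absent_rate_case: float = 0.0
    absent_rate_control: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")
        for r in (self.absent_rate_case, self.absent_rate_control):
            if not 0.0 <= r <= 1.0:
                raise ValueError("absent rates must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    n_case: int
    n_control: int
    targets: Mapping[str, TargetSpec]
    seed: int
    subject_sd: float = 0.0  # optional shared per-subject offset (urine concentration)


#: per-target defaults emulating the discovery conditions
_DEFAULT_TARGETS: dict[str, TargetSpec] = {
    "miR-122": TargetSpec(31.46, 3.0, -3.9, absent_rate_control=0.2),
    "miR-1271": TargetSpec(28.31, 2.0, -1.74),
    "miR-15b": TargetSpec(29.48, 2.5, -0.86),
    "miR-16": TargetSpec(27.0, 2.5, -1.0),
    "cel-miR-39": TargetSpec(30.0, 5.0, -4.0),
    "miRTC": TargetSpec(23.0, 4.0, -6.0),
}


def default_cohort_spec(
    n_case: int = 13, n_control: int = 14, seed: int = 0, subject_sd: float = 0.0
) -> CohortSpec:
    """Study-like cohort: informative shifts on every target."""
    return CohortSpec(n_case, n_control, dict(_DEFAULT_TARGETS), seed, subject_sd)


def null_cohort_spec(
    n_case: int = 13, n_control: int = 14, seed: int = 0
) -> CohortSpec:
    """Same noise, no group shifts, no absent calls (null hypothesis)."""
    targets = {
        t: replace(s, case_shift=0.0, absent_rate_case=0.0, absent_rate_control=0.0)
        for t, s in _DEFAULT_TARGETS.items()
    }
    return CohortSpec(n_case, n_control, targets, seed)


def simulate_urinary_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a consensus-Ct cohort table (post-QC shape).

    Returns a wide frame indexed by subject with one Ct column per
    target, a ``group`` column (ccRCC / HS) and ``gate_ok`` always True
    (the generator emulates samples that passed the miR-16 gate).
    """
    if spec.n_case < 2 or spec.n_control < 2:
        raise ValueError("need n_case >= 2 and n_control >= 2")
    rng = np.random.default_rng(spec.seed)
    subjects = [f"ccRCC {i + 1}" for i in range(spec.n_case)] + [
        f"HS {i + 1}" for i in range(spec.n_control)
    ]
    is_case = np.array([True] * spec.n_case + [False] * spec.n_control)
    n = len(subjects)
    out = pd.DataFrame(index=pd.Index(subjects, name="subject"))
    out["group"] = np.where(is_case, "ccRCC", "HS")
    subject_offset = (
        rng.normal(0.0, spec.subject_sd, size=n) if spec.subject_sd > 0 else np.zeros(n)
    )
    for target, ts in spec.targets.items():
        mean = ts.control_mean + np.where(is_case, ts.case_shift, 0.0)
        ct = rng.normal(mean, ts.sd, size=n) + subject_offset
        ct = np.clip(ct, CT_LOW, CT_HIGH)
        absent_p = np.where(is_case, ts.absent_rate_case, ts.absent_rate_control)
        absent = rng.random(n) < absent_p
        ct[absent] = ABSENT_CT
        out[target] = ct
    out["gate_ok"] = True
    return out


@dataclass(frozen=True)
class BankSpec:
    """Expression-bank generator settings (log2 scale)."""

    n_mirnas: int = 340
    arrays_per_tissue: Mapping[str, int] = field(
        default_factory=lambda: {
            "kidney": 104,
            "bladder": 9,
            "prostate": 21,
            "ccRCC_kidney": 32,
        }
    )
    baseline_range: tuple[float, float] = (4.0, 12.0)
    tissue_sd: float = 0.5  # spread of per-miRNA tissue-specific offsets
    noise_sd: float = 0.5  # per-array noise (within-tissue, log2)
    n_over: int = 10
    over_effect: float = 2.0
    n_under: int = 10
    under_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_over + self.n_under > self.n_mirnas:
            raise ValueError("planted subsets exceed the number of miRNAs")


@dataclass
class SimulatedBank:
    matrix: ExpressionMatrix
    overexpressed: list[str]
    underexpressed: list[str]


def default_bank_spec(**overrides) -> BankSpec:
    return BankSpec(**overrides)


def simulate_expression_bank(spec: BankSpec) -> SimulatedBank:
    """Draw a log2 expression bank with planted ccRCC effects.

    Planted over-expressed miRNAs get +over_effect and under-expressed
    ones -under_effect added to the ccRCC tissue mean; the two planted
    subsets are disjoint by construction.
    """
    for t, k in spec.arrays_per_tissue.items():
        if t not in TISSUES:
            raise ValueError(f"unknown tissue {t!r}")
        if k < 3:
            raise ValueError(f"tissue {t!r} has {k} arrays; need >= 3")
    rng = np.random.default_rng(spec.seed)
    mirnas = [f"miR-sim-{i + 1}" for i in range(spec.n_mirnas)]
    over = mirnas[: spec.n_over]
    under = mirnas[spec.n_over : spec.n_over + spec.n_under]

    lo, hi = spec.baseline_range
    baseline = rng.uniform(lo, hi, size=spec.n_mirnas)
    cols, tissues = [], []
    for tissue, k in spec.arrays_per_tissue.items():
        for j in range(k):
            cols.append(f"{tissue}_{j + 1}")
            tissues.append(tissue)

    values = np.empty((spec.n_mirnas, len(cols)))
    # tissue specificity separates kidney, bladder and prostate; the ccRCC
    # tissue IS kidney tissue, so it shares the kidney offset and differs
    # only by the planted effects
    tissue_offset = {
        t: rng.normal(0.0, spec.tissue_sd, size=spec.n_mirnas)
        for t in spec.arrays_per_tissue
        if t != "ccRCC_kidney"
    }
    tissue_offset["ccRCC_kidney"] = tissue_offset.get(
        "kidney", np.zeros(spec.n_mirnas)
    )
    effect = np.zeros(spec.n_mirnas)
    effect[: spec.n_over] = spec.over_effect
    effect[spec.n_over : spec.n_over + spec.n_under] = -spec.under_effect
    for j, tissue in enumerate(tissues):
        mean = baseline + tissue_offset[tissue]
        if tissue == "ccRCC_kidney":
            mean = mean + effect
        values[:, j] = rng.normal(mean, spec.noise_sd)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=mirnas, columns=cols),
        pd.DataFrame({"tissue": tissues}, index=pd.Index(cols, name="array_id")),
    )
    return SimulatedBank(matrix, over, under)
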