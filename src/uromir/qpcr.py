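"""qPCR cycle-threshold (Ct) quality control and relative quantification.

Conventions implemented here follow common clinical-qPCR practice for
urine and tissue assays:

* replicates whose melting curve deviates from the expected product are
  treated as "no amplification" and excluded from aggregation;
* an assay whose aggregated Ct exceeds the detection limit (38 cycles)
  must be repeated; if the repeat also exceeds the limit the target is
  called absent and its Ct is set to 40 by convention;
* tissue assays are reliable only when the RNU6-2 reference shows
  Ct < 30, urine assays only when endogenous miR-16 shows Ct < 35;
* relative quantification uses the delta-delta-Ct fold change 2**(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtAssay",
    "ConsensusCt",
    "DeltaCt",
    "GATE_THRESHOLDS",
    "consolidate_ct",
    "gate_sample",
    "delta_ct",
    "fold_change_ddct",
    "consolidate_table",
]

#: reliability gates: reference target -> strict Ct upper bound
GATE_THRESHOLDS: dict[str, float] = {"RNU6-2": 30.0, "miR-16": 35.0}

ABSENT_CT = 40.0


@dataclass
class CtAssay:
    """One RT-qPCR assay (typically a triplicate) for one subject/target.

    ``replicate_cts`` holds one Ct per well; ``None`` marks a well with no
    amplification.  ``melt_ok`` flags wells whose melting curve matched the
    expected product; failing wells are excluded as no-amplification.
    """

    subject: str
    target: str
    replicate_cts: Sequence[Optional[float]]
    melt_ok: Optional[Sequence[bool]] = None

    def valid_cts(self) -> np.ndarray:
        melt = self.melt_ok if self.melt_ok is not None else [True] * len(self.replicate_cts)
        if len(melt) != len(self.replicate_cts):
            raise ValueError("melt_ok length differs from replicate_cts")
        vals = [
            ct
            for ct, ok in zip(self.replicate_cts, melt)
            if ok and ct is not None and np.isfinite(ct)
        ]
        if any(v <= 0 for v in vals):
            raise ValueError(f"non-positive Ct in assay {self.subject}/{self.target}")
        return np.asarray(vals, dtype=float)


@dataclass
class ConsensusCt:
    subject: str
    target: str
    ct: float
    absent: bool = False

    def __post_init__(self) -> None:
        if self.absent and self.ct != ABSENT_CT:
            raise ValueError("absent calls must carry the conventional Ct of 40")


@dataclass
class DeltaCt:
    """Target minus reference Ct; flags whether an absent call (Ct=40)
    entered the arithmetic so downstream users can censor."""

    value: float
    involves_absent: bool = False

    def __float__(self) -> float:
        return self.value


def _aggregate(assay: CtAssay, how: str) -> Optional[float]:
    vals = assay.valid_cts()
    if vals.size == 0:
        return None
    return float(np.median(vals)) if how == "median" else float(vals.mean())


def consolidate_ct(
    first: CtAssay,
    repeat: Optional[CtAssay] = None,
    ct_limit: float = 38.0,
    absent_value: float = ABSENT_CT,
    aggregate: str = "mean",
) -> ConsensusCt:
    """Aggregate replicates and apply the repeat/absent convention.

    The first assay's melt-passing replicates are averaged; if the
    aggregate exceeds ``ct_limit`` the repeat assay decides: a repeat
    aggregate within the limit is accepted, otherwise (or when both
    assays show no amplification at all) the target is called absent at
    the conventional Ct of 40.
    """
    agg1 = _aggregate(first, aggregate)
    if agg1 is not None and agg1 <= ct_limit:
        return ConsensusCt(first.subject, first.target, agg1)
    if repeat is None:
        raise ValueError(
            f"repeat required: first assay for {first.subject}/{first.target} "
            f"{'showed no amplification' if agg1 is None else f'aggregated to Ct {agg1:.2f} > {ct_limit}'}"
        )
    if repeat.subject != first.subject or repeat.target != first.target:
        raise ValueError("repeat assay does not match first assay's subject/target")
    agg2 = _aggregate(repeat, aggregate)
    if agg2 is not None and agg2 <= ct_limit:
        return ConsensusCt(first.subject, first.target, agg2)
    return ConsensusCt(first.subject, first.target, absent_value, absent=True)


def gate_sample(control_ct: ConsensusCt, threshold: Optional[float] = None) -> bool:
    """Sample-reliability gate on a reference assay (strict inequality).

    RNU6-2 gates tissue samples at Ct < 30; miR-16 gates urine samples at
    Ct < 35.  Passing an explicit threshold that contradicts the control's
    canonical one is a labelled error.
    """
    canonical = GATE_THRESHOLDS.get(control_ct.target)
    if canonical is None:
        raise ValueError(
            f"{control_ct.target!r} is not a reliability-gate control "
            f"(expected one of {sorted(GATE_THRESHOLDS)})"
        )
    if threshold is None:
        threshold = canonical
    elif threshold != canonical:
        raise ValueError(
            f"threshold {threshold} conflicts with the {control_ct.target} gate ({canonical})"
        )
    return (not control_ct.absent) and control_ct.ct < threshold


def delta_ct(target: ConsensusCt, control: ConsensusCt) -> DeltaCt:
    """dCt = target Ct - reference Ct for the same subject."""
    if target.subject != control.subject:
        raise ValueError(
            f"subject mismatch: {target.subject!r} vs {control.subject!r}"
        )
    return DeltaCt(target.ct - control.ct, involves_absent=target.absent or control.absent)


def fold_change_ddct(delta_case, delta_reference) -> float:
    """Linear fold change 2**-(dCt_case - dCt_reference)."""
    ddct = float(delta_case) - float(delta_reference)
    if not np.isfinite(ddct):
        raise ValueError("non-finite ddCt")
    return float(2.0 ** (-ddct))


def consolidate_table(
    table: pd.DataFrame,
    mode: str = "urine",
    ct_limit: float = 38.0,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Long-format Ct table -> per-subject consensus Ct table with gate flag.

    Expects columns subject_id, group, target, run (1=first, 2=repeat),
    replicate, ct (empty/NaN = no amplification), melt_ok.  Returns a wide
    frame indexed by subject with one column per target, a ``group``
    column, and a boolean ``gate_ok`` column from the mode's reference
    control (miR-16 for urine, RNU6-2 for tissue).
    """
    required = {"subject_id", "group", "target", "run", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    gate_target = "miR-16" if mode == "urine" else "RNU6-2"

    records: dict[str, dict] = {}
    for (subject, target), sub in table.groupby(["subject_id", "target"], sort=False):
        runs = {}
        for run, rsub in sub.groupby("run"):
            cts = [None if pd.isna(v) else float(v) for v in rsub["ct"]]
            melt = (
                rsub["melt_ok"].astype(bool).tolist()
                if "melt_ok" in rsub.columns
                else None
            )
            runs[int(run)] = CtAssay(str(subject), str(target), cts, melt)
        cons = consolidate_ct(
            runs[1], runs.get(2), ct_limit=ct_limit, aggregate=aggregate
        )
        rec = records.setdefault(str(subject), {"group": sub["group"].iloc[0]})
        rec[str(target)] = cons.ct
        rec[f"_absent_{target}"] = cons.absent

    wide = pd.DataFrame.from_dict(records, orient="index")
    wide.index.name = "subject"
    if gate_target not in wide.columns:
        raise ValueError(f"gate control {gate_target!r} missing from table")
    wide["gate_ok"] = [
        gate_sample(
            ConsensusCt(str(s), gate_target, wide.at[s, gate_target], wide.at[s, f"_absent_{gate_target}"])
        )
        for s in wide.index
    ]
    return wide[[c for c in wide.columns if not c.startswith("_absent_")]]
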