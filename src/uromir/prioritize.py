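"""Prioritizing tissue-overexpressed miRNAs as candidate urinary markers.

A miRNA over-expressed by ccRCC is a promising *urinary* marker only if
its signal is not drowned by the background shed from healthy kidney,
bladder and (in men) prostate, and only if its expression is consistent
across subjects.  The score captures this with five weighted terms:

    score = w1*(ccRCC - kidney)            # over-expression, dominant
          + w2*(kidney - bladder)          # low bladder background
          + w3*(kidney - prostate)         # low prostate background (men)
          - w4*SD_kidney                   # inter-subject spread, kidney
          - w5*SD_ccRCC                    # inter-subject spread, tumour

all on the log2 scale.  Only the over-expression weight (3) is fixed by
convention; the remaining weights are ordered by importance (the kidney
SD penalty outweighs the tumour SD penalty) and configurable.  In female
mode the prostate term is dropped.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "TissueProfile",
    "ScoreWeights",
    "MarkerScoreBreakdown",
    "compute_marker_score",
    "rank_markers",
    "profiles_from_bank",
    "load_weights",
]


@dataclass
class TissueProfile:
    """Per-miRNA expression summary across the four tissues (log2)."""

    mirna: str
    mean_ccrcc: float
    mean_kidney: float
    mean_bladder: float
    mean_prostate: Optional[float]  # None = absent; female mode only
    sd_kidney: float
    sd_ccrcc: float

    def __post_init__(self) -> None:
        if self.sd_kidney < 0 or self.sd_ccrcc < 0:
            raise ValueError(f"{self.mirna}: negative SD in tissue profile")


@dataclass
class ScoreWeights:
    """Nonnegative term weights; defaults keep w1 = 3 and w4 > w5."""

    w1: float = 3.0
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 2.0
    w5: float = 1.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in (self.w1, self.w2, self.w3, self.w4, self.w5)):
            raise ValueError("weights must be nonnegative")


@dataclass
class MarkerScoreBreakdown:
    mirna: str
    term1: float
    term2: float
    term3: float
    term4: float
    term5: float
    score: float
    sex_mode: str


def compute_marker_score(
    profile: TissueProfile,
    weights: ScoreWeights = ScoreWeights(),
    sex_mode: str = "male",
) -> MarkerScoreBreakdown:
    """Score one miRNA's promise as a urinary ccRCC marker.

    Male mode uses all five terms; female mode zeroes the prostate term.
    Male mode with an absent prostate mean is a labelled error.
    """
    if sex_mode not in ("male", "female"):
        raise ValueError(f"sex_mode must be 'male' or 'female', got {sex_mode!r}")
    term1 = weights.w1 * (profile.mean_ccrcc - profile.mean_kidney)
    term2 = weights.w2 * (profile.mean_kidney - profile.mean_bladder)
    if sex_mode == "male":
        if profile.mean_prostate is None:
            raise ValueError(
                f"{profile.mirna}: prostate mean absent; male-mode scoring impossible"
            )
        term3 = weights.w3 * (profile.mean_kidney - profile.mean_prostate)
    else:
        term3 = 0.0
    term4 = weights.w4 * profile.sd_kidney
    term5 = weights.w5 * profile.sd_ccrcc
    score = term1 + term2 + term3 - term4 - term5
    if not np.isfinite(score):
        raise ValueError(f"{profile.mirna}: non-finite score")
    return MarkerScoreBreakdown(
        profile.mirna, term1, term2, term3, term4, term5, score, sex_mode
    )


def rank_markers(breakdowns: Sequence[MarkerScoreBreakdown]) -> list[MarkerScoreBreakdown]:
    """Descending by score; ties broken lexicographically by identifier."""
    if not breakdowns:
        raise ValueError("cannot rank an empty list of marker scores")
    return sorted(breakdowns, key=lambda b: (-b.score, b.mirna))


def profiles_from_bank(expr: ExpressionMatrix) -> list[TissueProfile]:
    """Summarize an expression bank into per-miRNA tissue profiles.

    Means per tissue; sample SDs (n-1) for the kidney and ccRCC groups.
    A tissue with no arrays yields an absent mean (prostate only; any
    other missing tissue is an error downstream).
    """
    cols = {t: expr.arrays_for(t) for t in ("kidney", "bladder", "prostate", "ccRCC_kidney")}
    for t in ("kidney", "bladder", "ccRCC_kidney"):
        if len(cols[t]) < 2:
            raise ValueError(f"tissue {t!r} has {len(cols[t])} arrays; need >= 2")
    profiles = []
    for mirna, row in expr.values.iterrows():
        prostate = (
            float(row[cols["prostate"]].mean()) if cols["prostate"] else None
        )
        profiles.append(
            TissueProfile(
                mirna=str(mirna),
                mean_ccrcc=float(row[cols["ccRCC_kidney"]].mean()),
                mean_kidney=float(row[cols["kidney"]].mean()),
                mean_bladder=float(row[cols["bladder"]].mean()),
                mean_prostate=prostate,
                sd_kidney=float(row[cols["kidney"]].std(ddof=1)),
                sd_ccrcc=float(row[cols["ccRCC_kidney"]].std(ddof=1)),
            )
        )
    return profiles


def load_weights(path) -> ScoreWeights:
    """Read a [weights] section (keys w1..w5) from a TOML config."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    section = cfg.get("weights", {})
    return ScoreWeights(**{k: float(v) for k, v in section.items()})


def breakdowns_to_frame(breakdowns: Sequence[MarkerScoreBreakdown]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": b.mirna,
                "term1": b.term1,
                "term2": b.term2,
                "term3": b.term3,
                "term4": b.term4,
                "term5": b.term5,
                "score": b.score,
                "sex_mode": b.sex_mode,
            }
            for b in breakdowns
        ]
    )
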