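"""Packaged discovery-cohort fixtures.

The discovery cohort comprises 13 ccRCC patients and 14 healthy subjects
(HS).  Two small TSVs ship with the package, holding the published
per-subject values at their printed 2-decimal precision:

* ``discovery_derivatives.tsv`` -- the 27 x 12 matrix of Ct/dCt
  derivatives (columns p1..p12);
* ``discovery_panel_sums.tsv`` -- the per-subject 7p-urinary score
  (sum of derivatives over parameters {2,4,5,7,8,11,12}).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .panel import DerivativeMatrix

__all__ = ["load_discovery_derivatives", "load_discovery_panel_sums"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("uromir.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_discovery_derivatives() -> DerivativeMatrix:
    """The 27-subject derivative matrix as a :class:`DerivativeMatrix`."""
    df = _read("discovery_derivatives.tsv").set_index("subject")
    return DerivativeMatrix(df.drop(columns="group"), df["group"])


def load_discovery_panel_sums() -> pd.DataFrame:
    """Per-subject published panel sums (columns group, score)."""
    return _read("discovery_panel_sums.tsv").set_index("subject")
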