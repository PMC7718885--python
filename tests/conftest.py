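import numpy as np
import pandas as pd
import pytest

from uromir.datasets import load_discovery_derivatives, load_discovery_panel_sums
from uromir.expression import ExpressionMatrix


@pytest.fixture(scope="session")
def discovery_derivs():
    return load_discovery_derivatives()


@pytest.fixture(scope="session")
def discovery_sums():
    return load_discovery_panel_sums()


def make_bank(per_mirna: dict[str, dict[str, list[float]]]) -> ExpressionMatrix:
    """Build a tiny ExpressionMatrix from {mirna: {tissue: [values]}}."""
    tissues, cols = [], []
    first = next(iter(per_mirna.values()))
    for tissue, vals in first.items():
        for j in range(len(vals)):
            cols.append(f"{tissue}_{j + 1}")
            tissues.append(tissue)
    rows = {
        m: np.concatenate([np.asarray(d[t], dtype=float) for t in first])
        for m, d in per_mirna.items()
    }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    ann = pd.DataFrame({"tissue": tissues}, index=pd.Index(cols, name="array_id"))
    return ExpressionMatrix(values, ann)
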