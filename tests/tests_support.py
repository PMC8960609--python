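"""Small data builders shared between test modules."""

import numpy as np
import pandas as pd

from lncsurv.datatypes import ExpressionMatrix


def expression_from(values: np.ndarray, unit: str = "fpkm") -> ExpressionMatrix:
    g, n = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i:04d}" for i in range(g)],
            columns=[f"S{j:05d}" for j in range(n)],
        ),
        unit,
    )


def make_counts_fixture(seed: int) -> ExpressionMatrix:
    """4-sample, 200-gene Poisson counts with one composition-biased sample."""
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 20.0, size=(200, 1))
    counts = rng.poisson(base * np.ones((1, 4))).astype(float)
    counts[:10, 2] *= 8
    counts[counts == 0] = 1
    return expression_from(counts, unit="counts")
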