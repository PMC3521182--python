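"""Within-sample rank transformation of expression profiles.

Batch effects and cross-platform differences distort the absolute expression
values a sample reports, but they largely preserve the relative ordering of
genes within that sample.  Replacing each sample's values with their
within-sample ranks therefore yields a representation that is exactly
invariant under any strictly increasing per-sample distortion.

Ranks are ascending (lowest expression → rank 1) and ties receive the average
of the ranks they span, so the per-sample rank sum is always G(G+1)/2 for G
features.  Each sample is ranked independently: transforming a test instance
requires no information from any other sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["rank_sample", "rank_matrix"]


def rank_sample(values: np.ndarray) -> np.ndarray:
    """Rank one sample's expression vector (ascending, average ties)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty expression vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression vector contains non-finite values")
    return rankdata(values, method="average")


def rank_matrix(matrix: pd.DataFrame, *, normalize: bool = False) -> pd.DataFrame:
    """Apply :func:`rank_sample` independently to every sample (column).

    With ``normalize=True`` ranks are divided by the number of features G,
    mapping them into (0, 1]; this only rescales distance- or margin-based
    classifiers and never changes orderings.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot rank an empty matrix")
    if not np.all(np.isfinite(matrix.to_numpy())):
        raise ValueError("expression matrix contains non-finite values")
    ranked = pd.DataFrame(
        rankdata(matrix.to_numpy(), method="average", axis=0),
        index=matrix.index,
        columns=matrix.columns,
    )
    if normalize:
        ranked /= matrix.shape[0]
    return ranked
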