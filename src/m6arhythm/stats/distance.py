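"""Sample-by-sample resemblance matrices for the multivariate tests."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def distance_matrix(table: pd.DataFrame, normalise: bool = True) -> pd.DataFrame:
    """Euclidean distances between samples (rows) over variables (columns).

    With ``normalise`` each variable is z-scored first (the usual
    treatment when response variables sit on different scales);
    zero-variance variables are dropped with a warning. Rows with missing
    values are removed listwise with a warning.
    """
    data = table.copy()
    if data.isna().any().any():
        n0 = len(data)
        data = data.dropna()
        logger.warning("listwise-deleted %d sample(s) with missing values", n0 - len(data))
    if normalise:
        keep = []
        for col in data.columns:
            sd = data[col].std(ddof=1)
            if sd == 0 or np.isnan(sd):
                logger.warning("variable %r has zero variance; dropped", col)
                continue
            data[col] = (data[col] - data[col].mean()) / sd
            keep.append(col)
        data = data[keep]
    if data.shape[1] == 0:
        raise ValueError("no variables left to compute distances on")
    d = squareform(pdist(data.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=data.index, columns=data.index)
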