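"""ANOVA assumption diagnostics: normality and variance homogeneity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class DiagnosticsReport:
    shapiro_w: float
    shapiro_p: float
    levene_stat: Optional[float]
    levene_p: Optional[float]
    degenerate: bool = False


def assumption_checks(
    residuals,
    groups: Optional[Sequence] = None,
) -> DiagnosticsReport:
    """Shapiro-Wilk normality on the residuals; mean-centred Levene across groups.

    ``groups`` is an optional list of per-group residual vectors. All
    residuals identical -> the tests are undefined and the report is
    flagged degenerate.
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(resid) == 0.0:
        return DiagnosticsReport(np.nan, np.nan, None, None, degenerate=True)
    w, p_w = sps.shapiro(resid)
    lev_stat = lev_p = None
    if groups is not None:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if np.ptp(np.concatenate(arrays)) == 0.0:
            return DiagnosticsReport(float(w), float(p_w), None, None, degenerate=True)
        stat, p = sps.levene(*arrays, center="mean")
        lev_stat, lev_p = float(stat), float(p)
    return DiagnosticsReport(float(w), float(p_w), lev_stat, lev_p)
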