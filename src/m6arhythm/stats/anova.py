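"""Balanced two-way fixed-effects ANOVA (closed-form sums of squares)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import TwoWayDesign

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    table: pd.DataFrame  # rows: A, B, A x B, Error, Total
    zero_error_variance: bool = False


def anova_two_way(response, design: TwoWayDesign) -> AnovaResult:
    """Two-way crossed ANOVA on one response variable.

    Uses the balanced-design identity: effect SS from marginal and cell
    means, error SS from within-cell deviations; F ratios against the
    error mean square with p-values from the F distribution. Zero
    within-cell variance is flagged (F becomes infinite).
    """
    y = np.asarray(response, dtype=float)
    if y.shape[0] != design.n:
        raise ValueError("response length does not match design")
    a = np.array(design.a, dtype=object)
    b = np.array(design.b, dtype=object)
    grand = y.mean()
    na, nb = len(design.a_levels), len(design.b_levels)
    r = design.replicates

    a_means = {la: y[a == la].mean() for la in design.a_levels}
    b_means = {lb: y[b == lb].mean() for lb in design.b_levels}
    cell_means = {
        (la, lb): y[(a == la) & (b == lb)].mean()
        for la in design.a_levels
        for lb in design.b_levels
    }

    ss_a = nb * r * sum((m - grand) ** 2 for m in a_means.values())
    ss_b = na * r * sum((m - grand) ** 2 for m in b_means.values())
    ss_ab = r * sum(
        (cell_means[(la, lb)] - a_means[la] - b_means[lb] + grand) ** 2
        for la in design.a_levels
        for lb in design.b_levels
    )
    fitted = np.array([cell_means[(la, lb)] for la, lb in zip(a, b)])
    ss_err = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - grand) ** 2))

    dfs = design.df
    names = list(dfs)
    df_a, df_b, df_ab, df_err = (dfs[k] for k in names[:4])
    zero_var = ss_err == 0.0
    if zero_var:
        logger.warning("zero within-cell variance; F ratios are infinite")
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    rows = []
    for name, ss, dfv in zip(names[:3], (ss_a, ss_b, ss_ab), (df_a, df_b, df_ab)):
        ms = ss / dfv
        f = np.inf if zero_var and ss > 0 else (ms / ms_err if ms_err > 0 else np.nan)
        p = float(sps.f.sf(f, dfv, df_err)) if np.isfinite(f) else (0.0 if f == np.inf else np.nan)
        rows.append({"source": name, "df": dfv, "SS": ss, "MS": ms, "F": f, "p": p})
    rows.append({"source": "Error", "df": df_err, "SS": ss_err, "MS": ms_err,
                 "F": np.nan, "p": np.nan})
    rows.append({"source": "Total", "df": dfs["Total"], "SS": ss_tot, "MS": np.nan,
                 "F": np.nan, "p": np.nan})
    return AnovaResult(pd.DataFrame(rows), zero_error_variance=zero_var)
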