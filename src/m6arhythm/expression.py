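"""RT-qPCR relative quantification: -dCT profiles, primer efficiency, correlations.

Relative transcript abundance is expressed as

    -dCT = CT_RG - CT_GOI,

per biological sample after averaging technical replicates, so larger
values mean higher abundance of the gene of interest relative to the
reference gene. Per time point the profile reports mean, standard error
(sample SD over biological replicates / sqrt(n)) and n.

Primer amplification efficiency comes from the slope of the standard
curve of CT against log10 template concentration:

    E = 10^(-1/slope),        efficiency% = (E - 1) * 100,

so a perfect doubling per cycle (slope -3.3219) is 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: technical replicates farther than this from their median are dropped (cycles)
TECH_OUTLIER_WINDOW = 0.5


def _average_tech_reps(ct_table: pd.DataFrame, outlier_window: float) -> pd.DataFrame:
    """Mean CT per (species, gene, time_h, bio_rep) after outlier removal."""

    def agg(vals: pd.Series) -> float:
        med = vals.median()
        kept = vals[(vals - med).abs() <= outlier_window]
        if len(kept) < len(vals):
            logger.warning("dropped %d outlier technical replicate(s)", len(vals) - len(kept))
        return kept.mean()

    return (
        ct_table.groupby(["species", "gene", "time_h", "bio_rep"])["ct"]
        .agg(agg)
        .reset_index()
    )


def neg_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    outlier_window: float = TECH_OUTLIER_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample -dCT values and the aggregated per-time-point profile.

    Technical replicates are averaged first (after the median-window QC);
    each biological sample then contributes one -dCT per gene of
    interest. Samples missing the reference gene are dropped with a
    logged warning (their n is not counted).

    Returns ``(samples, profile)``: samples has columns species, gene,
    time_h, bio_rep, neg_delta_ct; profile has species, gene, time_h,
    mean_neg_dct, se, n.
    """
    if (ct_table["ct"] <= 0).any():
        raise ValueError("CT values must be > 0")
    means = _average_tech_reps(ct_table, outlier_window)
    rg = means[means["gene"] == reference_gene].rename(columns={"ct": "ct_rg"})
    goi = means[means["gene"] != reference_gene]
    merged = goi.merge(
        rg[["species", "time_h", "bio_rep", "ct_rg"]],
        on=["species", "time_h", "bio_rep"],
        how="left",
    )
    missing = merged["ct_rg"].isna()
    if missing.any():
        for _, row in merged[missing].iterrows():
            logger.warning(
                "sample (%s, %s, t=%s, rep %s) lacks reference gene %s; dropped",
                row["species"], row["gene"], row["time_h"], row["bio_rep"], reference_gene,
            )
        merged = merged[~missing]
    merged = merged.assign(neg_delta_ct=merged["ct_rg"] - merged["ct"])
    samples = merged[["species", "gene", "time_h", "bio_rep", "neg_delta_ct"]].reset_index(
        drop=True
    )
    profile = (
        samples.groupby(["species", "gene", "time_h"])["neg_delta_ct"]
        .agg(
            mean_neg_dct="mean",
            se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return samples, profile


@dataclass(frozen=True)
class DilutionSeries:
    """Fitted primer standard curve (CT vs log10 relative concentration)."""

    points: tuple[tuple[float, float], ...]
    slope: float
    r2: float
    efficiency: float
    efficiency_percent: int
    valid: bool


def fit_efficiency(points) -> DilutionSeries:
    """Fit a dilution series and report amplification efficiency.

    ``points`` is an iterable of (log10_relative_conc, ct); replicate CTs
    at the same concentration are averaged. Requires >= 5 distinct
    concentrations. A non-negative slope is flagged invalid
    (amplification must reduce CT as template concentration rises).
    """
    df = pd.DataFrame(list(points), columns=["log10_conc", "ct"])
    mean_ct = df.groupby("log10_conc")["ct"].mean().reset_index()
    if len(mean_ct) < 5:
        raise ValueError(
            f"dilution series needs at least five distinct points, got {len(mean_ct)}"
        )
    fit = sps.linregress(mean_ct["log10_conc"], mean_ct["ct"])
    slope, r2 = fit.slope, fit.rvalue**2
    valid = slope < 0
    if not valid:
        logger.warning("dilution-series slope %.3f >= 0; efficiency invalid", slope)
        eff = float("nan")
        pct = 0
    else:
        eff = 10.0 ** (-1.0 / slope)
        pct = int(round((eff - 1.0) * 100.0))
    return DilutionSeries(
        tuple(zip(mean_ct["log10_conc"], mean_ct["ct"])), slope, r2, eff, pct, valid
    )


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int


def correlate_profiles(
    samples_a: pd.DataFrame,
    samples_b: pd.DataFrame,
) -> CorrelationResult:
    """Pearson correlation of two genes' per-sample -dCT values.

    Samples are paired by (species, time_h, bio_rep); only complete pairs
    enter. Two-sided p from the t distribution with n - 2 df.
    """
    merged = samples_a.merge(
        samples_b,
        on=["species", "time_h", "bio_rep"],
        suffixes=("_a", "_b"),
    )
    n = len(merged)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    x = merged["neg_delta_ct_a"].to_numpy()
    y = merged["neg_delta_ct_b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the profiles; correlation undefined")
    r, p = sps.pearsonr(x, y)
    gene_a = samples_a["gene"].iloc[0] if "gene" in samples_a else "a"
    gene_b = samples_b["gene"].iloc[0] if "gene" in samples_b else "b"
    return CorrelationResult(gene_a, gene_b, float(r), float(p), n)


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    peak_time_h: float
    r2: float


def fit_cosinor(time_h, values, period_h: float = 24.0) -> CosinorFit:
    """Least-squares cosinor fit; returns mesor, amplitude and acrophase (hours).

    The model ``y = M + A*cos(2*pi*(t - phi)/period)`` is linearised onto
    cosine and sine regressors, so the fit is closed-form.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(values, dtype=float)
    w = 2.0 * np.pi * t / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = beta
    amplitude = float(np.hypot(bc, bs))
    phi = (period_h / (2.0 * np.pi)) * np.arctan2(bs, bc)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return CosinorFit(float(mesor), amplitude, float(phi % period_h), float(r2))
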