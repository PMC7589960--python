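"""Global m6A quantification from colorimetric ELISA plates.

The assay's standard curve relates optical density to m6A mass; sample
m6A content follows

    m6A (ng) = (sample OD - NC OD) / slope,
    m6A%     = m6A (ng) / input RNA (ng) * 100,

with the slope taken from an origin-forced least-squares fit of
background-subtracted OD on known ng (the quantification formula uses
only a slope and the negative-control OD, so no intercept is estimated).
Background-subtracted ODs below zero clamp to 0 ng with a QC flag so a
full plate always processes end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class InvalidAssayError(ValueError):
    """Standard curve unusable (non-positive slope)."""


@dataclass(frozen=True)
class StandardCurve:
    points: tuple[tuple[float, float], ...]  # (known_ng, mean_od)
    nc_od: float
    slope: float  # OD per ng
    r2: float


@dataclass(frozen=True)
class M6aMeasurement:
    species: str
    time_h: float
    tech_ods: tuple[float, ...]
    input_rna_ng: float
    m6a_ng: float
    m6a_percent: float
    below_background: bool = False


def fit_standard_curve(standard_wells: pd.DataFrame, nc_wells: pd.DataFrame) -> StandardCurve:
    """Fit the plate standard curve.

    ``standard_wells`` needs columns known_ng and od (duplicates are
    averaged per concentration); ``nc_wells`` needs od. Requires >= 4
    distinct known_ng values and >= 1 NC well; raises
    :class:`InvalidAssayError` if the fitted slope is <= 0.
    """
    if len(nc_wells) < 1:
        raise ValueError("need at least one negative-control well")
    nc_od = float(nc_wells["od"].mean())
    points = standard_wells.groupby("known_ng")["od"].mean().reset_index()
    if len(points) < 4:
        raise ValueError(
            f"standard curve needs at least four dilution points, got {len(points)}"
        )
    x = points["known_ng"].to_numpy(dtype=float)
    y = points["od"].to_numpy(dtype=float) - nc_od
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise InvalidAssayError(f"standard-curve slope {slope:.4g} <= 0")
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return StandardCurve(tuple(zip(points["known_ng"], points["od"])), nc_od, slope, r2)


def quantify_m6a(
    curve: StandardCurve,
    sample_wells: pd.DataFrame,
    input_rna_ng: float = 100.0,
) -> M6aMeasurement:
    """Quantify one sample's m6A mass and percentage from its technical replicates."""
    if input_rna_ng <= 0:
        raise ValueError("input_rna_ng must be > 0")
    if sample_wells.empty:
        raise ValueError("no sample wells given")
    species = str(sample_wells["species"].iloc[0]) if "species" in sample_wells else ""
    time_h = float(sample_wells["time_h"].iloc[0]) if "time_h" in sample_wells else float("nan")
    ods = tuple(float(v) for v in sample_wells["od"])
    mean_od = float(np.mean(ods))
    delta = mean_od - curve.nc_od
    below = delta < 0
    if below:
        logger.warning(
            "sample (%s, t=%s): OD %.4f below background %.4f; clamped to 0 ng",
            species, time_h, mean_od, curve.nc_od,
        )
    m6a_ng = max(0.0, delta) / curve.slope
    return M6aMeasurement(
        species, time_h, ods, input_rna_ng, m6a_ng,
        m6a_ng / input_rna_ng * 100.0, below,
    )


def quantify_plate(plate: pd.DataFrame, input_rna_ng: float = 100.0) -> tuple[pd.DataFrame, StandardCurve]:
    """Quantify every sample on an ELISA plate table.

    The plate table uses the simulator's layout (columns well, role,
    known_ng, species, time_h, tech_rep, od). Returns a per-sample
    DataFrame (species, time_h, m6a_ng, m6a_percent, below_background)
    and the fitted curve. A (species, time) pair with no wells cannot
    occur here by construction; missing wells for a requested sample are
    the caller's responsibility.
    """
    curve = fit_standard_curve(
        plate[plate["role"] == "standard"], plate[plate["role"] == "nc"]
    )
    rows = []
    samples = plate[plate["role"] == "sample"]
    for (species, time_h), wells in samples.groupby(["species", "time_h"], sort=True):
        m = quantify_m6a(curve, wells, input_rna_ng)
        rows.append(
            {
                "species": species,
                "time_h": time_h,
                "m6a_ng": m.m6a_ng,
                "m6a_percent": m.m6a_percent,
                "below_background": m.below_background,
            }
        )
    return pd.DataFrame(rows), curve
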