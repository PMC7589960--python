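"""Synthetic colorimetric ELISA plates for global m6A quantification.

Well optical densities follow a linear standard curve with additive
Gaussian noise:

    OD = nc_od + curve_slope * m6a_ng + noise,

standards run in duplicate (>= 4 dilution points plus a negative
control), samples in two technical replicates. A sample's true m6A mass
is ``true_percent / 100 * input_rna_ng``, the inverse of the
quantification formulas applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

ELISA_COLUMNS = ["well", "role", "known_ng", "species", "time_h", "tech_rep", "od"]


@dataclass(frozen=True)
class ElisaSpec:
    """Plate model: curve geometry, standards, and per-sample ground truth.

    ``true_percent`` maps (species, time_h) to the ground-truth m6A
    percentage of the input RNA. ``curve_slope`` is in OD per ng,
    ``noise_sd`` in OD units.
    """

    curve_slope: float
    nc_od: float
    standard_points: tuple[float, ...]
    true_percent: Mapping[tuple[str, float], float]
    input_rna_ng: float = 100.0
    noise_sd: float = 0.0
    n_standard_rep: int = 2
    n_sample_tech: int = 2

    def __post_init__(self) -> None:
        if self.curve_slope <= 0:
            raise ValueError("curve_slope must be > 0")
        if len(set(self.standard_points)) < 4:
            raise ValueError("standard curve needs at least four dilution points")
        if self.input_rna_ng <= 0:
            raise ValueError("input_rna_ng must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_elisa_plate(spec: ElisaSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate one plate (columns well, role, known_ng, species, time_h, tech_rep, od)."""
    rng = np.random.default_rng(seed)
    rows = []
    well = 0

    def next_well() -> str:
        nonlocal well
        well += 1
        return f"W{well:02d}"

    for ng in spec.standard_points:
        for rep in range(1, spec.n_standard_rep + 1):
            od = spec.nc_od + spec.curve_slope * ng + rng.normal(0.0, spec.noise_sd)
            rows.append((next_well(), "standard", ng, "", np.nan, rep, od))
    rows.append(
        (next_well(), "nc", 0.0, "", np.nan, 1,
         spec.nc_od + rng.normal(0.0, spec.noise_sd))
    )
    for (species, time_h), pct in spec.true_percent.items():
        m6a_ng = pct / 100.0 * spec.input_rna_ng
        for rep in range(1, spec.n_sample_tech + 1):
            od = spec.nc_od + spec.curve_slope * m6a_ng + rng.normal(0.0, spec.noise_sd)
            rows.append((next_well(), "sample", np.nan, species, time_h, rep, od))
    return pd.DataFrame(rows, columns=ELISA_COLUMNS)
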