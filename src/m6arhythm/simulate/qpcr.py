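"""Synthetic diel RT-qPCR CT tables with cosinor structure.

For a gene of interest the expected threshold cycle follows a 24-h
cosinor,

    CT_GOI(t) = baseline - amplitude * cos(2*pi*(t - peak_time)/24),

so transcript abundance (-dCT) peaks at ``peak_time``. The reference gene
is flat at ``reference_baseline_ct``. Biological replicates add Gaussian
noise with sd ``noise_sd`` to both genes; technical replicates add
independent Gaussian noise (default sd 0.1 cycles). Time is decimal hours
since local midnight; no date handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CT_COLUMNS = ["species", "gene", "time_h", "bio_rep", "tech_rep", "ct"]


@dataclass(frozen=True)
class RhythmSpec:
    """Cosinor parameters of one gene x species diel profile (units: CT cycles, hours)."""

    gene: str
    species: str
    baseline_ct: float
    amplitude_ct: float
    peak_time: float
    noise_sd: float = 0.3
    reference_baseline_ct: float = 20.0

    def __post_init__(self) -> None:
        if self.amplitude_ct < 0:
            raise ValueError("amplitude_ct must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.peak_time < 24.0:
            raise ValueError("peak_time must lie in [0, 24)")

    def expected_goi_ct(self, time_h: float) -> float:
        return self.baseline_ct - self.amplitude_ct * np.cos(
            2.0 * np.pi * (time_h - self.peak_time) / 24.0
        )

    def true_neg_delta_ct(self, time_h: float) -> float:
        """Ground-truth -dCT = CT_RG - CT_GOI at time ``time_h``."""
        return self.reference_baseline_ct - self.expected_goi_ct(time_h)


@dataclass(frozen=True)
class DielDesign:
    """Sampling design: which species, which clock times, how many replicates."""

    species: tuple[str, ...]
    time_points_h: tuple[float, ...]
    n_bio: int = 3
    n_tech: int = 3
    reference_gene: str = "eIF4A"
    tech_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not self.species or not self.time_points_h:
            raise ValueError("design needs at least one species and one time point")
        for t in self.time_points_h:
            if not 0.0 <= t < 24.0:
                raise ValueError(f"time point {t} outside [0, 24)")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")


def generate_diel_ct(
    design: DielDesign,
    rhythms: list[RhythmSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a CT table (columns species, gene, time_h, bio_rep, tech_rep, ct).

    One reference-gene measurement set is emitted per biological sample
    and shared by all genes of interest of that species, mirroring a real
    plate layout. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[RhythmSpec]] = {}
    for spec in rhythms:
        by_species.setdefault(spec.species, []).append(spec)
    for sp in design.species:
        if sp not in by_species:
            raise ValueError(f"no RhythmSpec given for species {sp!r}")
        ref_cts = {s.reference_baseline_ct for s in by_species[sp]}
        if len(ref_cts) != 1:
            raise ValueError(
                f"species {sp!r}: rhythms disagree on reference_baseline_ct"
            )

    rows = []
    for sp in design.species:
        specs = by_species[sp]
        ref_ct = specs[0].reference_baseline_ct
        # biological noise is assumed shared across genes only through the
        # sample's RG reading; each gene draws its own biological deviate
        for t in design.time_points_h:
            for b in range(1, design.n_bio + 1):
                rg_level = ref_ct + rng.normal(0.0, specs[0].noise_sd)
                for k in range(1, design.n_tech + 1):
                    rows.append(
                        (sp, design.reference_gene, t, b,
                         k, rg_level + rng.normal(0.0, design.tech_noise_sd))
                    )
                for spec in specs:
                    goi_level = spec.expected_goi_ct(t) + rng.normal(0.0, spec.noise_sd)
                    for k in range(1, design.n_tech + 1):
                        rows.append(
                            (sp, spec.gene, t, b,
                             k, goi_level + rng.normal(0.0, design.tech_noise_sd))
                        )
    return pd.DataFrame(rows, columns=CT_COLUMNS)
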