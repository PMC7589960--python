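import numpy as np
import pytest

from m6arhythm.simulate import DielDesign, FamilySpec, RhythmSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def three_family_specs():
    """3 families x 2 species x 2 copies each (12 proteins)."""
    return [
        FamilySpec(
            family_name=name,
            copies_per_species={"SpA": 2, "SpB": 2},
            ancestral_length=60,
        )
        for name in ("FAM1", "FAM2", "FAM3")
    ]


@pytest.fixture()
def faro_design():
    """Interspecific diel design: 2 species x 6 time points x 3 bio reps."""
    return DielDesign(
        species=("Cnodosa", "Zmarina"),
        time_points_h=(0.0, 4.5, 6.5, 13.0, 20.5, 22.0),
    )


@pytest.fixture()
def night_peak_rhythm():
    return RhythmSpec(
        gene="MTA", species="Cnodosa", baseline_ct=27.0, amplitude_ct=1.2,
        peak_time=0.0, noise_sd=0.3, reference_baseline_ct=20.0,
    )
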