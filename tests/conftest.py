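"""Shared fixtures: small matrices, toy genomes, and seeded hypothesis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motifatlas import (
    Background,
    FixtureSpec,
    LogOddsMatrix,
    PlantSpec,
    calibrate_z,
    matrix_from_consensus,
    simulate_alignment,
    simulate_reference,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motif12():
    """Informative 12-mer matrix (certainty 0.97 per position)."""
    return matrix_from_consensus("M12", "TF12", "TGACGTCATTGA")


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture(scope="session")
def planted_world(motif12):
    """20 kb fixture: one conserved plant, one reference-only decoy."""
    spec = FixtureSpec(
        seed=11,
        genome_length=20_000,
        plants=[
            PlantSpec("M12", 5_000),
            PlantSpec("M12", 12_000, carriers=set()),
        ],
    )
    matrices = {"M12": motif12}
    reference = simulate_reference(spec, matrices)
    alignment = simulate_alignment(spec, reference, matrices)
    return spec, matrices, reference, alignment


@pytest.fixture(scope="session")
def calibrated12(motif12, planted_world):
    _, _, reference, _ = planted_world
    bg = Background.from_genome(reference)
    lom = LogOddsMatrix.build(motif12, bg)
    cal = calibrate_z(lom, reference, n_samples=100_000, seed=3)
    return lom, cal
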