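import numpy as np
import pytest

from pwmcleave import (
    PWM,
    BackgroundSet,
    MotifSpec,
    SubstrateRecord,
    deterministic_motif,
    generate_background,
    generate_substrates,
)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def toy_pwm() -> PWM:
    """A PWM with 100 distinct cell values, threshold 0, offset -5."""
    rng = np.random.default_rng(42)
    matrix = rng.normal(size=(20, 5)).round(3)
    return PWM(enzyme="TOY", matrix=matrix, offset=-5.0, threshold=0.0)


@pytest.fixture
def uniform_background() -> BackgroundSet:
    """Background covering all 20 residues exactly once: composition 0.05 each."""
    return BackgroundSet(peptides=(ALPHABET,), name="uniform")


@pytest.fixture
def planted_substrates() -> list[SubstrateRecord]:
    """Small synthetic set carrying the deterministic PSALD motif."""
    spec = MotifSpec(columns=deterministic_motif("PSALD"), n_substrates=100,
                     n_background=300, seed=7)
    return generate_substrates(spec)


@pytest.fixture
def planted_background() -> BackgroundSet:
    spec = MotifSpec(columns=deterministic_motif("PSALD"), n_substrates=100,
                     n_background=300, seed=7)
    return generate_background(spec)
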