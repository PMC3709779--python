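import numpy as np
import pytest

from hotspot_hremd import Bond, Particle, ToySystem, generate_fixture


@pytest.fixture
def tiny_system() -> ToySystem:
    """Three-bead linear chain with hand-picked parameters."""
    particles = [
        Particle(0, 1, 0.2, 0.05, 0.002),
        Particle(1, 2, -0.1, 0.04, 0.001),
        Particle(2, 3, 0.05, 0.06, 0.003),
    ]
    bonds = [Bond(0, 1, 0.4, 1000.0), Bond(1, 2, 0.4, 1000.0)]
    coords = np.array([[0.0, 0.0, 0.0], [0.4, 0.0, 0.0], [0.7, 0.3, 0.1]])
    return ToySystem(
        particles=particles,
        bonds=bonds,
        native_coords=coords,
        temperature=300.0,
        residue_count=3,
    )


@pytest.fixture(scope="session")
def small_fixture() -> ToySystem:
    return generate_fixture(10, (3, 7), 5.0, seed=1)
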