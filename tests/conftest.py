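import numpy as np
import pytest

from gvpt2 import (
    AnharmonicField,
    HarmonicModel,
    PropertySurface,
    VibData,
)


@pytest.fixture
def two_mode_rich() -> VibData:
    """2-mode system with every type of force constant, weak couplings."""
    harm = HarmonicModel(n_atoms=3, omega=np.array([950.0, 1700.0]))
    field = AnharmonicField(
        cubic={(1, 1, 1): 6.0, (2, 2, 2): -5.0, (1, 1, 2): 4.0, (1, 2, 2): -6.0},
        quartic={(1, 1, 1, 1): 3.0, (2, 2, 2, 2): 2.0, (1, 1, 2, 2): -1.5,
                 (1, 1, 1, 2): 1.0, (1, 2, 2, 2): -0.8},
    )
    rng = np.random.default_rng(7)
    p2 = rng.normal(0, 5e-3, (2, 2, 3))
    p2 = 0.5 * (p2 + p2.transpose(1, 0, 2))
    el = PropertySurface(
        name="electric_dipole", n_components=3, S=+1,
        P0=rng.normal(0, 0.2, 3), P1=rng.normal(0, 0.05, (2, 3)), P2=p2,
        P3_semidiag={(i, j): rng.normal(0, 5e-4, 3)
                     for i in (1, 2) for j in (1, 2)},
    )
    mag = PropertySurface(
        name="magnetic_dipole", n_components=3, S=-1,
        P1=rng.normal(0, 5e-3, (2, 3)), P2=rng.normal(0, 5e-4, (2, 2, 3)),
    )
    return VibData(harm, field, [el, mag])


def make_fermi_dyad(delta: float = 2.6, phi: float = 38.0,
                    with_dipole: bool = False) -> VibData:
    """Two modes in type-I Fermi resonance: omega_2 - 2 omega_1 = delta."""
    w1 = (1500.0 - delta) / 2.0
    harm = HarmonicModel(n_atoms=3, omega=np.array([w1, 1500.0]))
    field = AnharmonicField(cubic={(1, 1, 2): phi})
    props = []
    if with_dipole:
        props.append(PropertySurface(
            name="electric_dipole", n_components=3, S=+1,
            P1=np.array([[0.05, 0.01, 0.0], [0.02, 0.04, 0.01]]),
            P2=np.zeros((2, 2, 3)),
        ))
    return VibData(harm, field, props)


@pytest.fixture
def fermi_dyad() -> VibData:
    return make_fermi_dyad()
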