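import numpy as np
import pytest

import sabrespin as sb
from sabrespin.spin_core import CouplingNetwork, SpinSpec, SpinSystem, tensor_embed


@pytest.fixture(scope="session")
def preset3():
    """Reduced three-spin fixture: two hydrides + carbon."""
    return sb.preset_pyruvate_sabre(reduced=True)


@pytest.fixture(scope="session")
def preset6():
    """The full six-spin pyruvate parameterization."""
    return sb.preset_pyruvate_sabre()


@pytest.fixture(scope="session")
def drive_matching():
    """On-resonance drive at the spin-lock induced crossing (nu_A = -J_HH)."""
    return sb.DriveSpec("13C", 10.5, 0.0)


@pytest.fixture(scope="session")
def singlet_rho3(preset3):
    return sb.singlet_density(preset3.system).matrix


@pytest.fixture(scope="session")
def carbon_xplus():
    """Carbon polarized along +x (as after a 90-degree pulse)."""
    return np.array([[0.5, 0.5], [0.5, 0.5]], dtype=complex)


@pytest.fixture(scope="session")
def quartet_system():
    """Carbon coupled to three equivalent protons with J = 1.2 Hz."""
    spins = tuple(
        [SpinSpec(f"m{k}", "1H") for k in (1, 2, 3)] + [SpinSpec("c", "13C")]
    )
    system = SpinSystem(
        spins, {"m1": "methyl_1", "m2": "methyl_2", "m3": "methyl_3", "c": "carbon"}
    )
    couplings = CouplingNetwork.from_pairs(
        system, [("c", f"m{k}", 1.2) for k in (1, 2, 3)]
    )
    return system, couplings


@pytest.fixture(scope="session")
def exchange_pair_system():
    """Carbon coupled (J = 1.2 Hz) to a proton pair that can exchange."""
    system = SpinSystem(
        (SpinSpec("ha", "1H"), SpinSpec("hb", "1H"), SpinSpec("c", "13C")),
        {"ha": "hydride_a", "hb": "hydride_b", "c": "carbon"},
    )
    couplings = CouplingNetwork.from_pairs(
        system, [("c", "ha", 1.2), ("c", "hb", 1.2)]
    )
    return system, couplings
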