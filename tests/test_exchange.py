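"""The parahydrogen-exchange superoperator and the full generator."""

import numpy as np
import pytest

import sabrespin as sb
from sabrespin.exchange import ExchangeModel, build_generator, replacement_map
from sabrespin.spin_core import (
    SpinSpec,
    SpinSystem,
    partial_trace,
    singlet_state,
    tensor_embed,
    triplet_states,
)


@pytest.fixture(scope="module")
def pair_system():
    return SpinSystem(
        (SpinSpec("ha", "1H"), SpinSpec("hb", "1H")),
        {"ha": "hydride_a", "hb": "hydride_b"},
    )


def test_exchange_model_validation():
    with pytest.raises(ValueError):
        ExchangeModel(tau_ir=-1.0)
    with pytest.raises(ValueError):
        ExchangeModel(tau_ir=0.031, singlet_fraction=1.5)
    with pytest.raises(ValueError):
        ExchangeModel(tau_ir=0.031, fed_hydrogen=np.eye(4))  # trace 4


def test_fed_state_interpolates_singlet_and_triplets():
    s = singlet_state()
    fed = ExchangeModel(0.031, singlet_fraction=1.0).fed_state()
    assert np.allclose(fed, np.outer(s, s.conj()), atol=1e-12)
    fed_thermal = ExchangeModel(0.031, singlet_fraction=0.25).fed_state()
    assert np.allclose(fed_thermal, np.eye(4) / 4, atol=1e-12)


def test_replacement_map_properties(preset3):
    system = preset3.system
    model = preset3.exchange
    tp = triplet_states()["T+"]
    rho = tensor_embed(system, np.outer(tp, tp.conj()), system.hydride_pair)
    out = replacement_map(rho, system, model)
    red = partial_trace(out, system, system.hydride_pair)
    assert np.allclose(red, model.fed_state(), atol=1e-12)
    # idempotence and trace preservation
    again = replacement_map(out, system, model)
    assert np.allclose(again, out, atol=1e-12)
    assert np.trace(out).real == pytest.approx(1.0, abs=1e-12)


def test_replacement_map_unknown_labels(preset3):
    bad = ExchangeModel(0.031, hydride_pair=("nope", "hydride_b"))
    with pytest.raises(KeyError):
        replacement_map(np.eye(8) / 8, preset3.system, bad)


def test_generator_reduces_to_commutator_without_exchange(preset3):
    system = preset3.system
    drive = sb.DriveSpec("13C", 10.5, 0.0)
    H = sb.rotating_frame_hamiltonian(system, preset3.couplings, preset3.field, drive)
    G_none = build_generator(H, system, None)
    rho = sb.singlet_density(system).matrix
    expected = -2j * np.pi * (H @ rho - rho @ H)
    assert np.allclose(G_none.apply(rho), expected, atol=1e-12)


def test_generator_dimension_for_full_preset(preset6, drive_matching):
    H = sb.rotating_frame_hamiltonian(
        preset6.system, preset6.couplings, preset6.field, drive_matching
    )
    G = build_generator(H, preset6.system, preset6.exchange)
    assert G.matrix.shape == (4096, 4096)


def test_generator_is_trace_annihilating(preset3, drive_matching):
    H = sb.rotating_frame_hamiltonian(
        preset3.system, preset3.couplings, preset3.field, drive_matching
    )
    G = build_generator(H, preset3.system, preset3.exchange)
    d = preset3.system.dim
    trace_vec = np.eye(d).reshape(-1)  # <tr| in vec convention
    assert np.max(np.abs(trace_vec @ G.matrix.toarray())) < 1e-10


def test_exchange_closed_form_singlet_feeding(pair_system):
    """H = 0, hydrides start in |T+>: singlet population is 1 - e^(-t/tau)."""
    tau = 0.031
    model = ExchangeModel(tau, ("ha", "hb"), singlet_fraction=1.0)
    G = build_generator(np.zeros((4, 4)), pair_system, model)
    tp = triplet_states()["T+"]
    rho0 = np.outer(tp, tp.conj())
    s = singlet_state()
    for mult in (0.5, 1.0, 2.0):
        rho = sb.evolve(rho0, G, mult * tau)
        pop = np.real(s.conj() @ rho @ s)
        assert pop == pytest.approx(1.0 - np.exp(-mult), abs=1e-9)


def test_no_transfer_when_hydride_carbon_couplings_equal(preset3, drive_matching):
    """dJ_CH = 0 closes the transfer channel: no carbon order of any kind."""
    from sabrespin.spin_core import CouplingNetwork

    system = preset3.system
    coup_eq = CouplingNetwork.from_pairs(
        system,
        [("hydride_a", "hydride_b", -10.5), ("hydride_a", "carbon", 0.06),
         ("hydride_b", "carbon", 0.06)],
    )
    H = sb.rotating_frame_hamiltonian(system, coup_eq, preset3.field, drive_matching)
    G = build_generator(H, system, preset3.exchange)
    rho = sb.evolve(sb.singlet_density(system).matrix, G, 10.0)
    assert abs(sb.polarization(rho, system, "carbon", "x")) < 1e-10
    assert abs(sb.polarization(rho, system, "carbon", "z")) < 1e-10
    assert abs(sb.two_spin_order(rho, system, ("carbon", "hydride_a"))) < 1e-10


def test_polarization_linear_in_singlet_excess(preset3, drive_matching):
    """Generated polarization scales with f - 1/4 of the fed hydrogen."""
    system = preset3.system
    H = sb.rotating_frame_hamiltonian(
        system, preset3.couplings, preset3.field, drive_matching
    )
    values = {}
    for f in (1.0, 0.75, 0.25):
        model = ExchangeModel(0.031, system.hydride_pair, singlet_fraction=f)
        # start from the fed state so the response is strictly linear in f - 1/4
        rho0 = tensor_embed(system, model.fed_state(), system.hydride_pair)
        G = build_generator(H, system, model)
        rho = sb.evolve(rho0, G, 10.0)
        values[f] = sb.polarization(rho, system, "carbon", "x")
    assert values[0.25] == pytest.approx(0.0, abs=1e-10)
    # first-order linearity; second-order feedback of the generated carbon
    # order contributes ~3e-4 relative
    assert values[0.75] / values[1.0] == pytest.approx(
        (0.75 - 0.25) / (1.0 - 0.25), rel=0.01
    )


def test_trace_and_hermiticity_preserved_over_ten_seconds(preset3, drive_matching):
    system = preset3.system
    H = sb.rotating_frame_hamiltonian(
        system, preset3.couplings, preset3.field, drive_matching
    )
    G = build_generator(H, system, preset3.exchange)
    rho = sb.evolve(sb.singlet_density(system).matrix, G, 10.0)
    assert np.trace(rho).real == pytest.approx(1.0, abs=1e-8)
    assert np.max(np.abs(rho - rho.conj().T)) < 1e-8
    sb.DensityState(rho).validate(trace_tol=1e-8, herm_tol=1e-8, eig_tol=1e-7)


def test_optional_damping_drives_toward_identity(pair_system):
    model = None
    G = build_generator(
        np.zeros((4, 4)), pair_system, model, damping_rate=10.0
    )
    tp = triplet_states()["T+"]
    rho = sb.evolve(np.outer(tp, tp.conj()), G, 1.0)
    assert np.allclose(rho, np.eye(4) / 4, atol=1e-4)
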