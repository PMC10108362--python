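"""Polarization extraction, reporting conventions, and simulated spectra."""

import numpy as np
import pytest

import sabrespin as sb
from sabrespin.exchange import ExchangeModel, build_generator
from sabrespin.observables import PolarizationRecord, measure_fwhm
from sabrespin.spin_core import (
    CouplingNetwork,
    SpinSpec,
    SpinSystem,
    maximally_mixed,
    tensor_embed,
)


@pytest.fixture(scope="module")
def carbon_system():
    return (
        SpinSystem((SpinSpec("c", "13C"),), {"c": "carbon"}),
        CouplingNetwork(np.zeros((1, 1))),
    )


def test_polarization_basic_states(preset3):
    system = preset3.system
    alpha = np.diag([1.0, 0.0]).astype(complex)
    rho = tensor_embed(system, alpha, ["carbon"])
    assert sb.polarization(rho, system, "carbon", "z") == pytest.approx(1.0)
    mixed = tensor_embed(system, maximally_mixed(1), ["carbon"])
    for ax in "xyz":
        assert sb.polarization(mixed, system, "carbon", ax) == pytest.approx(0.0)
    singlet = sb.singlet_density(system).matrix
    for member in system.hydride_pair:
        assert sb.polarization(singlet, system, member, "z") == pytest.approx(0.0)


def test_two_spin_order_product_states(preset3):
    system = preset3.system
    aa = np.zeros((4, 4), dtype=complex)
    aa[0, 0] = 1.0  # |alpha alpha>
    rho = tensor_embed(system, aa, ["carbon", "hydride_a"])
    assert sb.two_spin_order(rho, system, ("carbon", "hydride_a")) == pytest.approx(1.0)
    ab = np.zeros((4, 4), dtype=complex)
    ab[1, 1] = 1.0  # |alpha beta>
    rho = tensor_embed(system, ab, ["carbon", "hydride_a"])
    assert sb.two_spin_order(rho, system, ("carbon", "hydride_a")) == pytest.approx(-1.0)
    mixed = tensor_embed(system, maximally_mixed(2), ["carbon", "hydride_a"])
    assert sb.two_spin_order(mixed, system, ("carbon", "hydride_a")) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        sb.two_spin_order(rho, system, ("carbon", "carbon"))


def test_apply_reporting_arithmetic(preset6):
    system = preset6.system
    rec = PolarizationRecord("z", ("carbon",), 0.11)
    ident = sb.apply_reporting(rec, system, scale="none", basis="bound")
    assert ident.scaled_value is None and ident.value == 0.11
    averaged = sb.apply_reporting(rec, system, scale="none", basis="averaged")
    assert averaged.scaled_value == pytest.approx(0.011)
    scaled = sb.apply_reporting(rec, system, scale="empirical", basis="bound")
    assert scaled.scaled_value == pytest.approx(0.38 * 0.11)
    h_rec = PolarizationRecord("z", ("hydride_a",), 0.01)
    h_scaled = sb.apply_reporting(h_rec, system, scale="empirical", basis="bound")
    assert h_scaled.scaled_value == pytest.approx(3.4 * 0.01)


def test_polarization_record_bound_check():
    with pytest.raises(ValueError):
        PolarizationRecord("z", ("c",), 1.5)


def test_spectrum_single_carbon_line(carbon_system, carbon_xplus):
    system, coup = carbon_system
    H = sb.lab_hamiltonian(system, coup, sb.StaticField(121.0))
    G = build_generator(H, system, None)
    rec = sb.spectrum(
        carbon_xplus, G, system, duration=4.0, dwell=1 / 3000,
        detection_weights={"13C": 1.0},
    )
    assert len(rec.lines) == 1
    center, _ = rec.lines[0]
    assert center == pytest.approx(sb.larmor_frequency("13C", 121.0), abs=0.3)


def test_spectrum_nyquist_violation_rejected(carbon_system, carbon_xplus):
    system, coup = carbon_system
    H = sb.lab_hamiltonian(system, coup, sb.StaticField(121.0))
    G = build_generator(H, system, None)
    with pytest.raises(ValueError):
        sb.spectrum(
            carbon_xplus, G, system, duration=4.0, dwell=1 / 1000,
            detection_weights={"13C": 1.0},
        )


def test_quartet_multiplet_and_parseval(quartet_system, carbon_xplus):
    """Carbon coupled to three equivalent protons: 1:3:3:1 quartet, 1.2 Hz."""
    system, coup = quartet_system
    H = sb.lab_hamiltonian(system, coup, sb.StaticField(121.0))
    G = build_generator(H, system, None)
    rho0 = tensor_embed(system, carbon_xplus, ["c"])
    rec = sb.spectrum(
        rho0, G, system, duration=16.0, dwell=1 / 3000,
        detection_weights={"13C": 1.0}, apodization_hz=0.2,
    )
    nu0 = sb.larmor_frequency("13C", 121.0)
    centers = sorted(c for c, _ in rec.lines)
    assert len(centers) == 4
    expected = [nu0 - 1.8, nu0 - 0.6, nu0 + 0.6, nu0 + 1.8]
    assert np.allclose(centers, expected, atol=0.2)
    # intensity pattern from absorption-mode areas around each line; the 15%
    # tolerance absorbs Lorentzian tail leakage between the windows
    absorption = np.real(rec.amplitude)
    areas = []
    for c in expected:
        window = np.abs(rec.frequency_hz - c) < 0.6
        areas.append(absorption[window].sum())
    areas = np.array(areas) / areas[0]
    assert np.allclose(areas, [1.0, 3.0, 3.0, 1.0], rtol=0.15)
    # and the pattern is symmetric
    assert areas[3] == pytest.approx(areas[0], rel=0.02)
    assert areas[2] == pytest.approx(areas[1], rel=0.02)
    # Parseval: windowed FID energy equals spectrum energy / N
    n = len(rec.fid)
    apo = np.exp(-np.pi * 0.2 * np.arange(n) * rec.dwell_s)
    fid_energy = np.sum(np.abs(rec.fid * apo) ** 2)
    spec_energy = np.sum(np.abs(rec.amplitude) ** 2) / n
    assert fid_energy == pytest.approx(spec_energy, rel=1e-9)


def test_exchange_collapses_multiplet(exchange_pair_system, carbon_xplus):
    """At tau_Ir = 31 ms the 1.2 Hz splitting to exchanging protons vanishes."""
    system, coup = exchange_pair_system
    H = sb.lab_hamiltonian(system, coup, sb.StaticField(121.0))
    rho0 = tensor_embed(system, carbon_xplus, ["c"])
    nu0 = sb.larmor_frequency("13C", 121.0)

    def run(tau):
        model = (
            None
            if tau is None
            else ExchangeModel(tau, ("ha", "hb"), singlet_fraction=0.25)
        )
        G = build_generator(H, system, model)
        return sb.spectrum(
            rho0, G, system, duration=8.0, dwell=1 / 3000,
            detection_weights={"13C": 1.0},
        )

    static = run(None)
    assert len(static.lines) == 3  # resolved 1:2:1 triplet
    collapsed = run(0.031)
    assert len(collapsed.lines) == 1
    assert collapsed.lines[0][0] == pytest.approx(nu0, abs=0.3)
    # exchange narrowing is monotone: the number of resolved maxima never
    # grows as tau_Ir shrinks
    counts = [len(run(tau).lines) for tau in (None, 1.0, 0.2, 0.031)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_scan_symmetry_in_offset(preset3, drive_matching):
    """x-polarization is even and z-polarization odd in the drive offset."""
    spec = sb.ProtocolSpec("light_sabre", drive=drive_matching, t_hyp=10.0)
    offsets = np.array([-7.5, -4.5, -1.5, 1.5, 4.5, 7.5])
    res = sb.scan_2d(spec, [10.5], offsets, preset3)
    x = res.maps["x"][0]
    z = res.maps["z"][0]
    assert np.allclose(x, x[::-1], atol=1e-6)
    assert np.allclose(z, -z[::-1], atol=1e-6)


def test_spectrum_record_csv_roundtrip(tmp_path, carbon_system, carbon_xplus):
    system, coup = carbon_system
    H = sb.lab_hamiltonian(system, coup, sb.StaticField(121.0))
    G = build_generator(H, system, None)
    rec = sb.spectrum(
        carbon_xplus, G, system, duration=1.0, dwell=1 / 3000,
        detection_weights={"13C": 1.0},
    )
    p = tmp_path / "spec.csv"
    rec.to_csv(p)
    import pandas as pd

    df = pd.read_csv(p)
    assert list(df.columns) == ["frequency_hz", "real", "imag"]
    assert len(df) == len(rec.frequency_hz)
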