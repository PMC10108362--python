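"""Protocol emulation and parameter scans on the fast three-spin fixture."""

import numpy as np
import pytest

import sabrespin as sb
from sabrespin.protocols import crusher, rotate


@pytest.fixture(scope="module")
def matched_spec(drive_matching):
    return sb.ProtocolSpec("light_sabre", drive=drive_matching, t_hyp=10.0)


def test_crusher_removes_all_transverse_observables(preset3, matched_spec):
    from sabrespin.exchange import build_generator

    system = preset3.system
    H = sb.rotating_frame_hamiltonian(
        system, preset3.couplings, preset3.field, matched_spec.drive
    )
    G = build_generator(H, system, preset3.exchange)
    rho = sb.evolve(sb.singlet_density(system).matrix, G, 10.0)
    crushed = crusher(rho)
    for label in system.labels:
        for ax in ("x", "y"):
            assert abs(sb.polarization(crushed, system, label, ax)) < 1e-12
    # longitudinal orders survive
    assert sb.polarization(crushed, system, "carbon", "z") == pytest.approx(
        sb.polarization(rho, system, "carbon", "z"), abs=1e-12
    )


def test_zero_time_protocol_gives_no_polarization(preset3, drive_matching):
    spec = sb.ProtocolSpec("light_sabre", drive=drive_matching, t_hyp=0.0)
    for readout in ("direct_transverse", "crusher_90", "sepp"):
        records = sb.run_protocol(
            sb.ProtocolSpec("light_sabre", drive=drive_matching, t_hyp=0.0, readout=readout),
            preset3,
        )
        carbon_records = [r for r in records if r.labels == ("carbon",) or r.kind == "zz"]
        for r in carbon_records:
            assert abs(r.value) < 1e-12


def test_x_readout_exceeds_z_readout_at_matching(preset3, matched_spec):
    x_rec = sb.run_protocol(matched_spec, preset3)[0]
    z_recs = sb.run_protocol(
        sb.ProtocolSpec("light_sabre", drive=matched_spec.drive, t_hyp=10.0, readout="crusher_90"),
        preset3,
    )
    z_carbon = [r for r in z_recs if r.labels == ("carbon",)][0]
    assert x_rec.kind == "x" and z_carbon.kind == "z"
    assert abs(x_rec.value) > abs(z_carbon.value)


def test_ideal_pulse_rotations(preset3):
    system = preset3.system
    alpha = np.diag([1.0, 0.0]).astype(complex)
    rho = sb.spin_core.tensor_embed(system, alpha, ["carbon"])
    rot = rotate(rho, system, ["carbon"], 90.0, "y")
    assert sb.polarization(rot, system, "carbon", "x") == pytest.approx(1.0, abs=1e-12)
    assert sb.polarization(rot, system, "carbon", "z") == pytest.approx(0.0, abs=1e-12)
    flip = rotate(rho, system, ["carbon"], 180.0, "x")
    assert sb.polarization(flip, system, "carbon", "z") == pytest.approx(-1.0, abs=1e-12)


def test_sepp_readout_returns_zz_and_inphase(preset3, drive_matching):
    spec = sb.ProtocolSpec(
        "light_sabre", drive=drive_matching, t_hyp=10.0, readout="sepp"
    )
    records = sb.run_protocol(spec, preset3)
    kinds = {r.kind for r in records}
    assert "zz" in kinds and "x" in kinds
    zz = [r for r in records if r.kind == "zz"][0]
    assert zz.labels[0] == "carbon"


def test_scan_argmax_near_slic_matching(preset3, matched_spec):
    amps = np.arange(2.0, 20.0 + 1e-9, 0.5)
    res = sb.scan_2d(matched_spec, amps, [0.0], preset3, kinds=("x",))
    assert abs(res.argmax["x"]["amplitude_hz"] - 10.5) <= 0.5


def test_scan_maps_are_deterministic(preset3, matched_spec):
    amps = [8.0, 10.5, 13.0]
    a = sb.scan_2d(matched_spec, amps, [0.0, 3.0], preset3)
    b = sb.scan_2d(matched_spec, amps, [0.0, 3.0], preset3)
    for kind in a.maps:
        assert np.array_equal(a.maps[kind], b.maps[kind])


def _amp_peak_fwhm(preset, tau):
    """FWHM along the amplitude axis of the |x| response at fixed offset."""
    p = preset.with_exchange(preset.exchange.with_tau(tau))
    spec = sb.ProtocolSpec("light_sabre", drive=sb.DriveSpec("13C", 10.5, 0.0), t_hyp=10.0)
    amps = np.arange(2.0, 24.0 + 1e-9, 0.5)
    res = sb.scan_2d(spec, amps, [0.0], p, kinds=("x",))
    v = np.abs(res.maps["x"][:, 0])
    half = v.max() / 2
    above = np.nonzero(v >= half)[0]
    return amps[above[-1]] - amps[above[0]]


def test_scan_peak_width_grows_as_lifetime_shrinks(preset3):
    """The amplitude-axis peak width is set by the complex lifetime tau_Ir."""
    widths = [_amp_peak_fwhm(preset3, tau) for tau in (0.062, 0.031, 0.015)]
    assert widths[0] < widths[1] < widths[2]


def test_buildup_scan_starts_at_zero_and_fits_monoexp(preset3, matched_spec):
    t_grid = np.linspace(1.0, 60.0, 20)
    curve = sb.buildup_scan(matched_spec, t_grid, preset3)
    fit = sb.fit_monoexp(curve)
    resid = np.abs(
        curve.values - fit.p_max * (1 - np.exp(-curve.times / fit.t_hyp))
    )
    assert resid.max() < 0.05 * abs(fit.p_max)
    # the curve extrapolates to zero at t = 0
    spec0 = sb.ProtocolSpec("light_sabre", drive=matched_spec.drive, t_hyp=0.0)
    assert sb.run_protocol(spec0, preset3)[0].value == pytest.approx(0.0, abs=1e-12)


def test_sheath_produces_longitudinal_carbon_polarization(preset3):
    spec = sb.ProtocolSpec("sheath", polarization_field_ut=0.36, t_hyp=10.0)
    records = sb.run_protocol(spec, preset3)
    z_carbon = [r for r in records if r.labels == ("carbon",)][0]
    assert abs(z_carbon.value) > 1e-3


def test_protocol_spec_validation(drive_matching):
    with pytest.raises(ValueError):
        sb.ProtocolSpec("light_sabre", drive=None)
    with pytest.raises(ValueError):
        sb.ProtocolSpec("sheath", t_hyp=-1.0)
    with pytest.raises(ValueError):
        sb.ProtocolSpec("light_sabre", drive=drive_matching, readout="bogus")


def test_scan_csv_long_format(tmp_path, preset3, matched_spec):
    import pandas as pd

    res = sb.scan_2d(matched_spec, [10.0, 10.5], [0.0, 1.0], preset3)
    p = tmp_path / "scan.csv"
    res.to_csv(p)
    df = pd.read_csv(p)
    assert list(df.columns) == ["amplitude_hz", "offset_hz", "kind", "value"]
    assert len(df) == 2 * 2 * len(res.maps)
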