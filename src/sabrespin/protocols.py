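"""Protocol emulation (LIGHT-SABRE and SABRE-SHEATH) and parameter scans.

A LIGHT-SABRE run evolves the freshly loaded complex (hydride singlet, all
other spins unpolarized) under the rotating-frame generator -- CW drive plus
hydrogen exchange -- for a hyperpolarization time t_hyp, then emulates one of
three readouts:

* ``direct_transverse``: the transverse carbon magnetization along the drive
  is observed directly (no pulses);
* ``crusher_90``: an ideal crusher gradient removes all coherences (projection
  onto the Zeeman product-basis diagonal), then 90-degree pulses on both
  channels convert the longitudinal orders to observables;
* ``sepp``: crusher, 90-degree pulse on protons only, then a 180 on both
  channels, converting carbon-proton zz order into in-phase proton signal.

A SABRE-SHEATH run evolves under the lab-frame generator at the sub-microtesla
polarization field, where the heteronuclear spins are strongly coupled and the
level anticrossing does the transfer without any drive.

Scans repeat the protocol over (amplitude, offset) grids and record the x, z
and zz polarization maps with their extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg

from .dynamics import BuildUpCurve, evolve, timeseries
from .exchange import build_generator
from .hamiltonians import DriveSpec, lab_hamiltonian, rotating_frame_hamiltonian
from .observables import PolarizationRecord, polarization, two_spin_order
from .spin_core import (
    DensityState,
    Preset,
    SpinSystem,
    StaticField,
    build_operator,
    singlet_density,
)

__all__ = [
    "ProtocolSpec",
    "ScanResult",
    "run_protocol",
    "scan_2d",
    "buildup_scan",
    "crusher",
    "rotate",
]

READOUTS = ("direct_transverse", "crusher_90", "sepp")


@dataclass(frozen=True)
class ProtocolSpec:
    """One experimental protocol configuration."""

    mode: str  # "light_sabre" or "sheath"
    static_field: StaticField = StaticField(121.0)
    drive: DriveSpec | None = None
    polarization_field_ut: float = 0.36
    t_hyp: float = 10.0
    readout: str = "direct_transverse"

    def __post_init__(self) -> None:
        if self.mode not in ("light_sabre", "sheath"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.t_hyp < 0:
            raise ValueError("t_hyp must be non-negative")
        if self.readout not in READOUTS:
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.mode == "light_sabre" and self.drive is None:
            raise ValueError("light_sabre requires a drive")
        if self.mode == "sheath" and self.polarization_field_ut < 0:
            raise ValueError("polarization field must be non-negative")


def crusher(rho: np.ndarray) -> np.ndarray:
    """Ideal crusher gradient: project onto the Zeeman product-basis diagonal."""
    return np.diag(np.diag(rho)).astype(complex)


def rotate(
    rho: np.ndarray,
    system: SpinSystem,
    labels: Sequence[str],
    angle_deg: float,
    axis: str = "y",
) -> np.ndarray:
    """Ideal instantaneous pulse: collective rotation of the listed spins."""
    gen = sum(build_operator(system, l, axis) for l in labels)
    U = scipy.linalg.expm(-1j * np.radians(angle_deg) * gen)
    return U @ rho @ U.conj().T


def _final_state(spec: ProtocolSpec, preset: Preset) -> np.ndarray:
    system, couplings, model = preset.system, preset.couplings, preset.exchange
    rho0 = singlet_density(system, model.hydride_pair).matrix
    if spec.t_hyp == 0:
        return rho0
    if spec.mode == "light_sabre":
        H = rotating_frame_hamiltonian(system, couplings, spec.static_field, spec.drive)
    else:
        H = lab_hamiltonian(
            system, couplings, StaticField(spec.polarization_field_ut), drive=None
        )
    G = build_generator(H, system, model)
    return evolve(rho0, G, spec.t_hyp)


def _zz_pair(system: SpinSystem) -> Tuple[str, str]:
    methyls = system.labels_with_role("methyl")
    partner = methyls[0] if methyls else system.hydride_pair[0]
    return (system.carbon, partner)


def run_protocol(spec: ProtocolSpec, preset: Preset) -> List[PolarizationRecord]:
    """Run one protocol and return the polarization records its readout exposes."""
    system = preset.system
    carbon = system.carbon
    rho = _final_state(spec, preset)

    if spec.mode == "sheath" or spec.readout == "crusher_90":
        rho_c = crusher(rho)
        # z values are what the 90-degree pulses make observable; the crusher
        # leaves them untouched, so read them off the crushed state
        protons = system.labels_with_isotope("1H")
        rho_pulsed = rotate(rho_c, system, list(protons) + [carbon], 90.0, "y")
        records = [
            PolarizationRecord(
                "z", (carbon,), polarization(rho_pulsed, system, carbon, "x")
            )
        ]
        for p in protons:
            records.append(
                PolarizationRecord("z", (p,), polarization(rho_pulsed, system, p, "x"))
            )
        return records

    if spec.readout == "direct_transverse":
        return [
            PolarizationRecord("x", (carbon,), polarization(rho, system, carbon, "x"))
        ]

    if spec.readout == "sepp":
        pair = _zz_pair(system)
        rho_c = crusher(rho)
        zz = two_spin_order(rho_c, system, pair)
        protons = system.labels_with_isotope("1H")
        rho_p = rotate(rho_c, system, protons, 90.0, "y")
        rho_p = rotate(rho_p, system, list(protons) + [system.carbon], 180.0, "x")
        inphase = sum(polarization(rho_p, system, p, "x") for p in protons)
        return [
            PolarizationRecord("zz", pair, zz),
            PolarizationRecord("x", tuple(protons), float(np.clip(inphase, -1, 1))),
        ]

    raise ValueError(f"unknown readout {spec.readout!r}")


@dataclass
class ScanResult:
    """Polarization maps over (amplitude, offset) grids."""

    axis_amplitude: np.ndarray
    axis_offset: np.ndarray
    maps: Dict[str, np.ndarray]  # kind -> (n_amp, n_off) array
    argmax: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis_amplitude = np.asarray(self.axis_amplitude, dtype=float)
        self.axis_offset = np.asarray(self.axis_offset, dtype=float)
        shape = (self.axis_amplitude.size, self.axis_offset.size)
        for kind, m in self.maps.items():
            m = np.asarray(m, dtype=float)
            if m.shape != shape:
                raise ValueError(f"map {kind!r} shape {m.shape} != grid {shape}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"map {kind!r} has non-finite values")
            self.maps[kind] = m

    def locate_extrema(self) -> None:
        """Record the |value|-argmax of each map."""
        for kind, m in self.maps.items():
            i, j = np.unravel_index(np.argmax(np.abs(m)), m.shape)
            self.argmax[kind] = {
                "amplitude_hz": float(self.axis_amplitude[i]),
                "offset_hz": float(self.axis_offset[j]),
                "value": float(m[i, j]),
            }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, m in self.maps.items():
            for i, a in enumerate(self.axis_amplitude):
                for j, o in enumerate(self.axis_offset):
                    rows.append((a, o, kind, m[i, j]))
        return pd.DataFrame(
            rows, columns=["amplitude_hz", "offset_hz", "kind", "value"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def scan_2d(
    spec_template: ProtocolSpec,
    amplitude_grid: Sequence[float],
    offset_grid: Sequence[float],
    preset: Preset,
    kinds: Sequence[str] = ("x", "z", "zz"),
) -> ScanResult:
    """Run the LIGHT-SABRE protocol over an (amplitude, offset) grid.

    One propagation is performed per grid point; the x, z and zz observables
    are all extracted from the same final state (the crusher is diagonal in
    the Zeeman basis, so it does not alter z or zz values).
    """
    amps = np.asarray(amplitude_grid, dtype=float)
    offs = np.asarray(offset_grid, dtype=float)
    if amps.size == 0 or offs.size == 0:
        raise ValueError("scan grids must be non-empty")
    if spec_template.mode != "light_sabre":
        raise ValueError("2D drive scans apply to light_sabre mode")
    system = preset.system
    carbon = system.carbon
    pair = _zz_pair(system)
    maps = {k: np.zeros((amps.size, offs.size)) for k in kinds}
    for i, a in enumerate(amps):
        for j, o in enumerate(offs):
            drive = replace(spec_template.drive, amplitude=float(a), offset=float(o))
            spec = replace(spec_template, drive=drive)
            rho = _final_state(spec, preset)
            if "x" in maps:
                maps["x"][i, j] = polarization(rho, system, carbon, "x")
            if "z" in maps:
                maps["z"][i, j] = polarization(rho, system, carbon, "z")
            if "zz" in maps:
                maps["zz"][i, j] = two_spin_order(rho, system, pair)
    result = ScanResult(amps, offs, maps)
    result.locate_extrema()
    return result


def buildup_scan(
    spec_template: ProtocolSpec,
    t_grid: Sequence[float],
    preset: Preset,
    kind: str | None = None,
) -> BuildUpCurve:
    """Polarization as a function of hyperpolarization time.

    ``kind`` defaults to "x" for LIGHT-SABRE (the drive-frame transverse
    carbon polarization) and "z" for SHEATH.  The state is propagated once
    across the grid, reusing each segment.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_hyp grid must be non-empty")
    system, couplings, model = preset.system, preset.couplings, preset.exchange
    carbon = system.carbon
    if kind is None:
        kind = "x" if spec_template.mode == "light_sabre" else "z"
    if spec_template.mode == "light_sabre":
        H = rotating_frame_hamiltonian(
            system, couplings, spec_template.static_field, spec_template.drive
        )
    else:
        H = lab_hamiltonian(
            system,
            couplings,
            StaticField(spec_template.polarization_field_ut),
            drive=None,
        )
    G = build_generator(H, system, model)
    rho0 = singlet_density(system, model.hydride_pair).matrix
    if kind == "zz":
        pair = _zz_pair(system)
        obs = lambda rho: two_spin_order(rho, system, pair)
    else:
        obs = lambda rho: polarization(rho, system, carbon, kind)
    return timeseries(rho0, G, t_grid, obs, kind=kind)
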