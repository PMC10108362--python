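"""Lab-frame and doubly-rotating-frame spin Hamiltonians (units of Hz).

The lab-frame Hamiltonian is the standard ultralow-field form

    H = - sum_i nu0_i I_z,i  +  sum_{i<j} J_ij I_i . I_j  +  H_drive(t),

with nu0_i = gamma_i * B0 * (1 + delta_i * 1e-6) and full (non-secular)
scalar couplings.  A continuous-wave drive is a linearly oscillating
transverse field; its circular component has nutation frequency
``amplitude`` on the target isotope, so the lab term carries a factor 2.

The doubly-rotating frame transforms each isotope at its own reference
frequency (the target isotope at the drive frequency).  Counter-rotating
drive terms are dropped (RWA) and heteronuclear flip-flop terms are
truncated to I_z S_z whenever the Larmor separation exceeds
``truncation_threshold`` times the coupling; the result is time-independent,
which lets the exchange dynamics be propagated with a single matrix
exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spin_core import (
    GAMMA_MHZ_PER_T,
    CouplingNetwork,
    SpinSystem,
    StaticField,
    build_operator,
)

__all__ = [
    "DriveSpec",
    "FrameMode",
    "FrameTruncationError",
    "larmor_frequency",
    "lab_hamiltonian",
    "rotating_frame_hamiltonian",
]


class FrameTruncationError(ValueError):
    """The secular truncation is invalid: the spins are strongly coupled.

    Raised when a heteronuclear pair's Larmor separation is not large compared
    to its J coupling, in which case lab-frame propagation must be used (the
    SABRE-SHEATH regime at sub-microtesla fields).
    """


@dataclass(frozen=True)
class DriveSpec:
    """A rectangular continuous-wave drive near one isotope's Larmor frequency.

    Parameters
    ----------
    target_isotope : str
        Isotope whose resonance the drive addresses ("13C" or "1H").
    amplitude : float
        Nutation frequency nu_CW^A on the target isotope, Hz.
    offset : float
        Drive frequency minus the target Larmor frequency, Hz (positive means
        the drive sits above resonance).
    phase : float
        RF phase in radians; 0 puts the rotating-frame field along +x.
    """

    target_isotope: str = "13C"
    amplitude: float = 0.0
    offset: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.target_isotope not in GAMMA_MHZ_PER_T:
            raise ValueError(f"unknown isotope {self.target_isotope!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def field_ut(self) -> float:
        """Equivalent rotating-field amplitude in uT (= amplitude / gamma)."""
        return self.amplitude / GAMMA_MHZ_PER_T[self.target_isotope]

    @classmethod
    def from_field(
        cls, target_isotope: str, field_ut: float, offset: float = 0.0, phase: float = 0.0
    ) -> "DriveSpec":
        amp = GAMMA_MHZ_PER_T[target_isotope] * field_ut
        return cls(target_isotope, amp, offset, phase)

    def frequency_hz(self, field: StaticField) -> float:
        """Absolute drive frequency at the given static field."""
        return larmor_frequency(self.target_isotope, field.b0_ut) + self.offset


@dataclass(frozen=True)
class FrameMode:
    """Frame selection and the secular-truncation safety factor."""

    mode: str = "doubly_rotating"  # or "lab"
    truncation_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("lab", "doubly_rotating"):
            raise ValueError(f"unknown frame mode {self.mode!r}")
        if self.truncation_threshold <= 1:
            raise ValueError("truncation_threshold must exceed 1")


def larmor_frequency(
    isotope: str, field_ut: float, chemical_shift_ppm: float = 0.0
) -> float:
    """Larmor frequency in Hz for an isotope at a field in microtesla."""
    if field_ut < 0:
        raise ValueError("field must be non-negative")
    try:
        gamma = GAMMA_MHZ_PER_T[isotope]
    except KeyError:
        raise ValueError(f"unknown isotope {isotope!r}") from None
    return gamma * field_ut * (1.0 + chemical_shift_ppm * 1e-6)


def _nu0(system: SpinSystem, field: StaticField) -> np.ndarray:
    """Per-spin Larmor frequencies (Hz), chemical shift included."""
    return np.array(
        [
            s.gyromagnetic_ratio * field.b0_ut * (1.0 + s.chemical_shift * 1e-6)
            for s in system.spins
        ]
    )


def _coupling_term(
    system: SpinSystem, couplings: CouplingNetwork, i: int, j: int, secular: bool
) -> np.ndarray:
    li, lj = system.labels[i], system.labels[j]
    term = build_operator(system, li, "z") @ build_operator(system, lj, "z")
    if not secular:
        term = (
            term
            + build_operator(system, li, "x") @ build_operator(system, lj, "x")
            + build_operator(system, li, "y") @ build_operator(system, lj, "y")
        )
    return couplings.J[i, j] * term


def lab_hamiltonian(
    system: SpinSystem,
    couplings: CouplingNetwork,
    field: StaticField,
    drive: DriveSpec | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Full lab-frame Hamiltonian in Hz (time-dependent if a drive is present)."""
    if couplings.J.shape[0] != system.n_spins:
        raise ValueError("coupling matrix dimension does not match the spin system")
    d = system.dim
    H = np.zeros((d, d), dtype=complex)
    nu0 = _nu0(system, field)
    for i, lbl in enumerate(system.labels):
        H -= nu0[i] * build_operator(system, lbl, "z")
    for i in range(system.n_spins):
        for j in range(i + 1, system.n_spins):
            if couplings.J[i, j] != 0.0:
                H += _coupling_term(system, couplings, i, j, secular=False)
    if drive is not None and drive.amplitude > 0:
        nu_rf = drive.frequency_hz(field)
        osc = np.cos(2.0 * np.pi * nu_rf * t + drive.phase)
        gamma_t = GAMMA_MHZ_PER_T[drive.target_isotope]
        for i, s in enumerate(system.spins):
            # linear field: 2*amplitude circular equivalent, scaled by gamma ratio
            H += (
                2.0
                * drive.amplitude
                * (s.gyromagnetic_ratio / gamma_t)
                * osc
                * build_operator(system, s.label, "x")
            )
    return H


def lab_drive_operator(
    system: SpinSystem, drive: DriveSpec
) -> np.ndarray:
    """Time-independent part of the lab drive: H_drive(t) = cos(w t + phi) * V."""
    d = system.dim
    V = np.zeros((d, d), dtype=complex)
    gamma_t = GAMMA_MHZ_PER_T[drive.target_isotope]
    for s in system.spins:
        V += (
            2.0
            * drive.amplitude
            * (s.gyromagnetic_ratio / gamma_t)
            * build_operator(system, s.label, "x")
        )
    return V


def rotating_frame_hamiltonian(
    system: SpinSystem,
    couplings: CouplingNetwork,
    field: StaticField,
    drive: DriveSpec,
    frame: FrameMode | None = None,
) -> np.ndarray:
    """Time-independent Hamiltonian in the doubly-rotating frame, in Hz.

    Each isotope rotates at its own reference frequency: the drive frequency
    for the target isotope, the bare (zero-shift) Larmor frequency otherwise.
    Residual Zeeman terms are ``(nu_ref - nu0_i) I_z``, so an on-shift target
    spin sees exactly ``offset * I_z``.  The drive survives as
    ``amplitude * (cos(phase) I_x + sin(phase) I_y)`` on target-isotope spins.

    Raises
    ------
    FrameTruncationError
        If a heteronuclear pair with nonzero J has Larmor separation below
        ``truncation_threshold * |J|`` (strong coupling: use the lab frame).
    """
    if drive is None:
        raise ValueError("rotating frame requires a drive specification")
    frame = frame or FrameMode()
    if frame.mode != "doubly_rotating":
        raise ValueError("rotating_frame_hamiltonian requires doubly_rotating mode")
    nu0 = _nu0(system, field)
    nu_rf = drive.frequency_hz(field)
    nu_ref = np.array(
        [
            nu_rf
            if s.isotope == drive.target_isotope
            else larmor_frequency(s.isotope, field.b0_ut)
            for s in system.spins
        ]
    )
    d = system.dim
    H = np.zeros((d, d), dtype=complex)
    for i, lbl in enumerate(system.labels):
        detuning = nu_ref[i] - nu0[i]
        if detuning != 0.0:
            H += detuning * build_operator(system, lbl, "z")
    for i in range(system.n_spins):
        for j in range(i + 1, system.n_spins):
            J = couplings.J[i, j]
            if J == 0.0:
                continue
            same_iso = system.spins[i].isotope == system.spins[j].isotope
            if same_iso:
                H += _coupling_term(system, couplings, i, j, secular=False)
            else:
                sep = abs(nu0[i] - nu0[j])
                # validity scale: the largest coupling touching either spin
                # (level anticrossings mix flip-flop states through the whole
                # network, e.g. via J_HH in the SHEATH regime)
                j_scale = max(
                    np.max(np.abs(couplings.J[i, :])),
                    np.max(np.abs(couplings.J[j, :])),
                )
                if sep <= frame.truncation_threshold * j_scale:
                    raise FrameTruncationError(
                        f"Larmor separation {sep:.3g} Hz of pair "
                        f"({system.labels[i]}, {system.labels[j]}) is below "
                        f"{frame.truncation_threshold:g} x the coupling scale "
                        f"{j_scale:.3g} Hz; use the lab frame"
                    )
                H += _coupling_term(system, couplings, i, j, secular=True)
    if drive.amplitude > 0:
        cx, cy = np.cos(drive.phase), np.sin(drive.phase)
        for s in system.spins:
            if s.isotope == drive.target_isotope:
                H += drive.amplitude * (
                    cx * build_operator(system, s.label, "x")
                    + cy * build_operator(system, s.label, "y")
                )
    return H
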