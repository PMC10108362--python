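"""Analytic matching-condition theory for the two LIGHT-SABRE transfer routes.

On resonance, the rotating-frame Hamiltonian restricted to the two states
|S0 X->, |T0 X+> (hydride singlet/central triplet times the carbon states
parallel/antiparallel to the CW field) reads, in Hz,

    [ -3/4 J_HH - nu_eff/2      dJ_CH/4          ]
    [      dJ_CH/4          1/4 J_HH + nu_eff/2 ],

with dJ_CH the difference of the two hydride-carbon couplings and
nu_eff = sqrt(offset^2 + amplitude^2).  The diagonal gap J_HH + nu_eff
vanishes at the spin-lock induced crossing nu_CW^A = -J_HH (for zero
offset), where the tiny off-diagonal dJ_CH/4 transfers singlet order into
carbon polarization along the drive.

Slightly off resonance the carbon quantization axis tilts by
theta = atan(amplitude/offset); generation of z-polarization is most
efficient when sin(2 theta) sin(theta) is maximal, at the magic angle
theta = atan(sqrt(2)) ~ 54.7 deg, with the crossing now at nu_eff = -J_HH.

The analogous SABRE-SHEATH level anticrossing occurs where the proton-carbon
Larmor separation matches |J_HH|: (gammaH - gammaC) B0 = |J_HH|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .hamiltonians import DriveSpec, rotating_frame_hamiltonian
from .spin_core import GAMMA_MHZ_PER_T, Preset, singlet_state, triplet_states

__all__ = [
    "TiltedFrame",
    "EffectiveBlock",
    "magic_angle",
    "tilted_frame",
    "x_transfer_block",
    "z_transfer_condition",
    "sheath_matching_field",
    "block_vs_full_check",
    "matching_report",
]


@dataclass(frozen=True)
class TiltedFrame:
    """Tilt of the target-spin quantization axis under an off-resonant drive."""

    theta_deg: float
    nu_eff: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ValueError("theta must lie in [0, 90] degrees")
        if self.nu_eff < 0:
            raise ValueError("nu_eff must be non-negative")


@dataclass(frozen=True)
class EffectiveBlock:
    """A labeled 2x2 Hermitian block of the rotating-frame Hamiltonian (Hz)."""

    matrix: np.ndarray
    basis: Tuple[str, str]

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=complex)
        if m.shape != (2, 2) or np.max(np.abs(m - m.conj().T)) > 1e-12:
            raise ValueError("block must be 2x2 Hermitian")
        object.__setattr__(self, "matrix", m)

    @property
    def diagonal_gap(self) -> float:
        return float(np.real(self.matrix[1, 1] - self.matrix[0, 0]))

    @property
    def off_diagonal(self) -> float:
        return float(np.real(self.matrix[0, 1]))


def magic_angle() -> float:
    """The drive tilt maximizing sin(2 theta) sin(theta): atan(sqrt(2)), deg."""
    return float(np.degrees(np.arctan(np.sqrt(2.0))))


def tilted_frame(amplitude: float, offset: float) -> TiltedFrame:
    """Effective field and tilt angle for a drive (amplitude, offset) in Hz."""
    nu_eff = float(np.hypot(amplitude, offset))
    theta = float(np.degrees(np.arctan2(abs(amplitude), abs(offset))))
    return TiltedFrame(theta, nu_eff)


def x_transfer_block(
    J_HH: float,
    J_HC_a: float,
    J_HC_b: float,
    nu_A: float,
    delta_nu: float = 0.0,
) -> EffectiveBlock:
    """The {|S0 X->, |T0 X+>} block governing on-resonance x-transfer.

    The off-diagonal element is dJ_CH/4 = (J_HC_a - J_HC_b)/4 (scaled by
    sin(theta) off resonance); the diagonal gap is J_HH + nu_eff and closes
    exactly at delta_nu = 0, nu_A = -J_HH.
    """
    tf = tilted_frame(nu_A, delta_nu)
    off = 0.25 * (J_HC_a - J_HC_b) * np.sin(np.radians(tf.theta_deg))
    m = np.array(
        [
            [-0.75 * J_HH - 0.5 * tf.nu_eff, off],
            [off, 0.25 * J_HH + 0.5 * tf.nu_eff],
        ]
    )
    return EffectiveBlock(m, ("S0 X-", "T0 X+"))


def z_transfer_condition(
    J_HH: float, theta_deg: float | None = None
) -> Tuple[float, float]:
    """Drive (offset, amplitude) pair realizing the z-transfer crossing.

    With nu_eff = -J_HH and tilt theta (default: the magic angle), the
    matching drive has offset = nu_eff cos(theta), amplitude =
    nu_eff sin(theta).  Returns (delta_nu, nu_A) in Hz.
    """
    if J_HH >= 0:
        raise ValueError("J_HH must be negative for the crossing to exist")
    theta = magic_angle() if theta_deg is None else float(theta_deg)
    if not (0.0 < theta < 90.0):
        raise ValueError("theta must lie strictly inside (0, 90) degrees")
    nu_eff = -J_HH
    th = np.radians(theta)
    return (float(nu_eff * np.cos(th)), float(nu_eff * np.sin(th)))


def sheath_matching_field(J_HH: float) -> float:
    """SABRE-SHEATH matching field in uT: (gammaH - gammaC) B0 = |J_HH|."""
    if J_HH == 0:
        raise ValueError("J_HH must be nonzero")
    dgamma = GAMMA_MHZ_PER_T["1H"] - GAMMA_MHZ_PER_T["13C"]  # Hz per uT
    return abs(J_HH) / dgamma


def _block_basis_vectors(preset: Preset) -> np.ndarray:
    """Kets |S0 X->, |T0 X+> on the reduced 3-spin system (hydrides + carbon)."""
    system = preset.system
    if system.n_spins != 3:
        raise ValueError("block comparison requires the 3-spin fixture")
    s0 = singlet_state()
    t0 = triplet_states()["T0"]
    xm = np.array([1.0, -1.0], dtype=complex) / np.sqrt(2.0)
    xp = np.array([1.0, 1.0], dtype=complex) / np.sqrt(2.0)
    v1 = np.kron(s0, xm)
    v2 = np.kron(t0, xp)
    return np.column_stack([v1, v2])


def block_vs_full_check(
    preset: Preset, drive: DriveSpec, atol: float = 1e-10
) -> Dict[str, float]:
    """Project the full rotating-frame Hamiltonian onto the analytic block.

    Works on the reduced 3-spin fixture; returns the projected matrix
    elements, the analytic ones, and their maximum absolute discrepancy.
    """
    if drive.offset != 0.0:
        raise ValueError(
            "block projection uses the on-resonance X+- basis; set offset = 0"
        )
    system, couplings = preset.system, preset.couplings
    H = rotating_frame_hamiltonian(system, couplings, preset.field, drive)
    P = _block_basis_vectors(preset)
    block_full = P.conj().T @ H @ P
    J_HH = couplings.coupling(system, "hydride_a", "hydride_b")
    J_a = couplings.coupling(system, "hydride_a", "carbon")
    J_b = couplings.coupling(system, "hydride_b", "carbon")
    analytic = x_transfer_block(J_HH, J_a, J_b, drive.amplitude, drive.offset)
    # the tiny hydride chemical-shift residuals are diagonal in the carbon
    # states and vanish within S0/T0, so the comparison is exact
    discrepancy = float(np.max(np.abs(block_full - analytic.matrix)))
    return {
        "off_diagonal_full": float(np.real(block_full[0, 1])),
        "off_diagonal_analytic": analytic.off_diagonal,
        "diagonal_gap_full": float(np.real(block_full[1, 1] - block_full[0, 0])),
        "diagonal_gap_analytic": analytic.diagonal_gap,
        "max_abs_discrepancy": discrepancy,
        "within_tolerance": float(discrepancy <= atol),
    }


def matching_report(J_HH: float, J_HC_a: float, J_HC_b: float) -> Dict[str, float]:
    """All matching conditions for a given coupling set, as a flat table."""
    dnu, nu_a = z_transfer_condition(J_HH)
    blk = x_transfer_block(J_HH, J_HC_a, J_HC_b, -J_HH, 0.0)
    return {
        "j_hh_hz": J_HH,
        "delta_j_ch_hz": J_HC_a - J_HC_b,
        "x_matching_amplitude_hz": -J_HH,
        "x_block_off_diagonal_hz": blk.off_diagonal,
        "magic_angle_deg": magic_angle(),
        "z_matching_offset_hz": dnu,
        "z_matching_amplitude_hz": nu_a,
        "sheath_matching_field_ut": sheath_matching_field(J_HH),
    }
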