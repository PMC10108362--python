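"""Propagation of density matrices under a generator.

Time-independent generators (the doubly-rotating frame, or the lab frame
without a drive) are propagated by Krylov exponential action on vec(rho).
Lab-frame propagation with a CW drive is periodic in time, so the propagator
over one drive period is assembled once from piecewise-constant steps and
then raised to the required power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .exchange import ExchangeModel, GeneratorOperator, build_generator
from .hamiltonians import DriveSpec, lab_hamiltonian, lab_drive_operator
from .spin_core import CouplingNetwork, DensityState, SpinSystem, StaticField

__all__ = ["BuildUpCurve", "evolve", "timeseries", "evolve_lab_driven"]


@dataclass
class BuildUpCurve:
    """A polarization observable sampled over hyperpolarization times."""

    times: np.ndarray
    values: np.ndarray
    kind: str = ""
    p_max: float | None = None
    t_hyp: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


def _as_matrix(state: DensityState | np.ndarray) -> np.ndarray:
    return np.asarray(state.matrix if isinstance(state, DensityState) else state)


def evolve(
    state: DensityState | np.ndarray,
    generator: GeneratorOperator,
    t: float,
    method: str = "auto",
) -> np.ndarray:
    """Propagate ``state`` for time ``t`` (seconds) under a fixed generator.

    ``method`` is ``"krylov"`` (sparse exponential action, the default for
    dimensions above 16), ``"dense"`` (dense expm of the full superoperator)
    or ``"auto"``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    rho = _as_matrix(state).astype(complex)
    if t == 0:
        return rho.copy()
    d = generator.dim
    if method == "auto":
        method = "dense" if d <= 16 else "krylov"
    if method == "dense":
        U = scipy.linalg.expm(generator.matrix.toarray() * t)
        return (U @ rho.reshape(-1)).reshape(d, d)
    if method == "krylov":
        v = expm_multiply(generator.matrix * t, rho.reshape(-1))
        return v.reshape(d, d)
    raise ValueError(f"unknown method {method!r}")


def timeseries(
    state: DensityState | np.ndarray,
    generator: GeneratorOperator,
    times: Sequence[float],
    observable: Callable[[np.ndarray], float],
    kind: str = "",
) -> BuildUpCurve:
    """Evaluate ``observable(rho(t))`` on an increasing time grid.

    Propagators are reused between grid points (each segment continues from
    the previous state), so the cost is one exponential action per interval.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("time grid must be non-empty")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must be non-negative")
    rho = _as_matrix(state).astype(complex)
    values = np.empty(times.size)
    t_prev = 0.0
    for k, t in enumerate(times):
        dt = t - t_prev
        if dt > 0:
            rho = evolve(rho, generator, dt)
        values[k] = observable(rho)
        t_prev = t
    return BuildUpCurve(times, values, kind=kind)


def evolve_lab_driven(
    state: DensityState | np.ndarray,
    system: SpinSystem,
    couplings: CouplingNetwork,
    static_field: StaticField,
    drive: DriveSpec,
    model: ExchangeModel | None,
    t: float,
    steps_per_fast_period: int = 50,
) -> np.ndarray:
    """Lab-frame propagation under an oscillating drive (brute-force oracle).

    The generator is periodic with the drive period T = 1/nu_rf.  The period
    propagator is built from piecewise-constant steps (the drive evaluated at
    step midpoints) with at least ``steps_per_fast_period`` steps per period
    of the fastest Larmor frequency present, then raised to the integer number
    of whole periods by binary exponentiation; the remainder is stepped
    explicitly.  Dense superoperator arithmetic: intended for small systems.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    rho = _as_matrix(state).astype(complex)
    if t == 0:
        return rho.copy()
    d = system.dim
    if d > 32:
        raise ValueError("lab-frame driven propagation is limited to small systems")

    H0 = lab_hamiltonian(system, couplings, static_field, drive=None)
    V = lab_drive_operator(system, drive)
    nu_rf = drive.frequency_hz(static_field)
    if nu_rf <= 0:
        raise ValueError("drive frequency must be positive")
    nu_fast = max(
        abs(s.gyromagnetic_ratio * static_field.b0_ut) for s in system.spins
    )
    nu_fast = max(nu_fast, nu_rf)
    period = 1.0 / nu_rf
    n_steps = max(1, int(np.ceil(steps_per_fast_period * nu_fast * period)))
    dt = period / n_steps

    L0 = build_generator(H0, system, model).matrix.toarray()
    LV = build_generator(V, system, None).matrix.toarray()  # -i 2pi [V, .]

    def step_propagator(t0: float) -> np.ndarray:
        tm = t0 + 0.5 * dt
        osc = np.cos(2.0 * np.pi * nu_rf * tm + drive.phase)
        return scipy.linalg.expm((L0 + osc * LV) * dt)

    # propagator over one full period
    U_period = np.eye(d * d, dtype=complex)
    for k in range(n_steps):
        U_period = step_propagator(k * dt) @ U_period

    n_whole = int(np.floor(t / period))
    remainder = t - n_whole * period

    # binary exponentiation of the period propagator
    U_total = np.eye(d * d, dtype=complex)
    base = U_period
    e = n_whole
    while e > 0:
        if e & 1:
            U_total = base @ U_total
        base = base @ base
        e >>= 1

    # remainder: step from phase t0 = n_whole * period (same as phase 0)
    n_rem = int(np.floor(remainder / dt))
    for k in range(n_rem):
        U_total = step_propagator(k * dt) @ U_total
    last = remainder - n_rem * dt
    if last > 1e-15 * max(t, 1.0):
        tm = n_rem * dt + 0.5 * last
        osc = np.cos(2.0 * np.pi * nu_rf * tm + drive.phase)
        U_total = scipy.linalg.expm((L0 + osc * LV) * last) @ U_total

    return (U_total @ rho.reshape(-1)).reshape(d, d)
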