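"""The evolution generator: coherent Liouvillian plus parahydrogen exchange.

The active complex loses its dihydride pair at rate 1/tau_Ir and immediately
binds fresh hydrogen in a prescribed spin state (pure singlet for 100%
parahydrogen).  Writing R for the replacement map

    R(rho) = fed_hydrogen (x) Tr_pair(rho),

the density matrix of the active complex obeys the linear master equation

    d rho/dt = -i 2*pi [H, rho] + (1/tau_Ir) (R(rho) - rho).

R is completely positive, trace preserving and idempotent, so the flow
preserves trace, Hermiticity and positivity.  The generator is represented
as a sparse matrix acting on row-major vec(rho); for the six-spin pyruvate
system that is a 4096 x 4096 operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import scipy.sparse as sp

from .spin_core import (
    DensityState,
    SpinSystem,
    singlet_state,
    tensor_embed,
    partial_trace,
    triplet_states,
)

__all__ = ["ExchangeModel", "GeneratorOperator", "replacement_map", "build_generator"]


def _fed_from_fraction(f: float) -> np.ndarray:
    """f |S><S| + (1-f)/3 * sum_i |T_i><T_i| on the hydrogen pair."""
    s = singlet_state()
    rho = f * np.outer(s, s.conj())
    for t in triplet_states().values():
        rho = rho + (1.0 - f) / 3.0 * np.outer(t, t.conj())
    return rho


@dataclass(frozen=True)
class ExchangeModel:
    """Hydrogen-exchange parameters of the active Ir complex.

    Parameters
    ----------
    tau_ir : float
        Lifetime of the complex between hydrogen exchange events, seconds.
    hydride_pair : (str, str)
        Labels of the two hydride spins that are replaced.
    singlet_fraction : float
        Singlet fraction f of the incoming hydrogen;
        fed state = f|S><S| + (1-f)/3 * sum of triplet projectors.
        f = 1 is pure parahydrogen, f = 1/4 is thermal hydrogen.
    fed_hydrogen : ndarray, optional
        Explicit 4x4 density operator of the incoming pair; overrides
        ``singlet_fraction`` when given.
    """

    tau_ir: float
    hydride_pair: Tuple[str, str] = ("hydride_a", "hydride_b")
    singlet_fraction: float = 1.0
    fed_hydrogen: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.tau_ir > 0):
            raise ValueError("tau_ir must be positive")
        if not (0.0 <= self.singlet_fraction <= 1.0):
            raise ValueError("singlet_fraction must lie in [0, 1]")
        if self.fed_hydrogen is not None:
            fed = np.array(self.fed_hydrogen, dtype=complex)
            if fed.shape != (4, 4):
                raise ValueError("fed_hydrogen must be 4x4")
            if abs(np.trace(fed) - 1.0) > 1e-9:
                raise ValueError("fed_hydrogen must have unit trace")
            if np.max(np.abs(fed - fed.conj().T)) > 1e-9:
                raise ValueError("fed_hydrogen must be Hermitian")
            object.__setattr__(self, "fed_hydrogen", fed)

    def fed_state(self) -> np.ndarray:
        if self.fed_hydrogen is not None:
            return self.fed_hydrogen
        return _fed_from_fraction(self.singlet_fraction)

    def with_tau(self, tau_ir: float) -> "ExchangeModel":
        return ExchangeModel(
            tau_ir, self.hydride_pair, self.singlet_fraction, self.fed_hydrogen
        )


def replacement_map(
    state: DensityState | np.ndarray, system: SpinSystem, model: ExchangeModel
) -> np.ndarray:
    """Replace the hydride pair of ``state`` with the fed hydrogen state.

    Implements the composition of the removal map (partial trace over the
    pair) and the addition map (tensor with the fed pair state), re-embedded
    in the original spin ordering.  Idempotent and trace preserving.
    """
    a, b = model.hydride_pair
    system.index(a), system.index(b)  # raises KeyError on unknown labels
    keep = [l for l in system.labels if l not in (a, b)]
    rho = np.asarray(state.matrix if isinstance(state, DensityState) else state)
    reduced = partial_trace(rho, system, keep)
    block = model.fed_state()
    return tensor_embed(system, block, (a, b), reduced)


def _trace_pair_matrix(system: SpinSystem, pair: Tuple[str, str]) -> sp.csr_matrix:
    """Sparse map vec(rho) -> vec(Tr_pair rho), row-major vec convention."""
    n = system.n_spins
    pa, pb = (system.index(pair[0]), system.index(pair[1]))
    keep = [i for i in range(n) if i not in (pa, pb)]
    d = 2 ** n
    dr = 2 ** len(keep)
    rows, cols, vals = [], [], []

    def bits_to_index(bits, positions, total):
        idx = 0
        for b, p in zip(bits, positions):
            idx |= b << (total - 1 - p)
        return idx

    for ir in range(dr):
        ir_bits = [(ir >> (len(keep) - 1 - k)) & 1 for k in range(len(keep))]
        for jr in range(dr):
            jr_bits = [(jr >> (len(keep) - 1 - k)) & 1 for k in range(len(keep))]
            for ka in range(2):
                for kb in range(2):
                    i_full = bits_to_index(
                        ir_bits + [ka, kb], keep + [pa, pb], n
                    )
                    j_full = bits_to_index(
                        jr_bits + [ka, kb], keep + [pa, pb], n
                    )
                    rows.append(ir * dr + jr)
                    cols.append(i_full * d + j_full)
                    vals.append(1.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(dr * dr, d * d))


def _embed_pair_matrix(
    system: SpinSystem, pair: Tuple[str, str], fed: np.ndarray
) -> sp.csr_matrix:
    """Sparse map vec(rho_reduced) -> vec(fed (x) rho_reduced) in declared order."""
    n = system.n_spins
    pa, pb = (system.index(pair[0]), system.index(pair[1]))
    keep = [i for i in range(n) if i not in (pa, pb)]
    d = 2 ** n
    dr = 2 ** len(keep)
    rows, cols, vals = [], [], []

    def bits_to_index(bits, positions, total):
        idx = 0
        for b, p in zip(bits, positions):
            idx |= b << (total - 1 - p)
        return idx

    fa, fb = np.nonzero(fed)
    for ir in range(dr):
        ir_bits = [(ir >> (len(keep) - 1 - k)) & 1 for k in range(len(keep))]
        for jr in range(dr):
            jr_bits = [(jr >> (len(keep) - 1 - k)) & 1 for k in range(len(keep))]
            for a_idx, b_idx in zip(fa, fb):
                a_bits = [(a_idx >> 1) & 1, a_idx & 1]
                b_bits = [(b_idx >> 1) & 1, b_idx & 1]
                i_full = bits_to_index(ir_bits + a_bits, keep + [pa, pb], n)
                j_full = bits_to_index(jr_bits + b_bits, keep + [pa, pb], n)
                rows.append(i_full * d + j_full)
                cols.append(ir * dr + jr)
                vals.append(fed[a_idx, b_idx])
    return sp.csr_matrix((vals, (rows, cols)), shape=(d * d, dr * dr))


@dataclass
class GeneratorOperator:
    """The full evolution generator as a sparse matrix on vec(rho)."""

    matrix: sp.csr_matrix
    dim: int  # Hilbert-space dimension d; the matrix is d^2 x d^2
    tau_ir: float | None = None

    def apply(self, rho: np.ndarray) -> np.ndarray:
        """Action d(rho)/dt on a density matrix (dense convenience path)."""
        v = np.asarray(rho, dtype=complex).reshape(-1)
        return (self.matrix @ v).reshape(self.dim, self.dim)


def build_generator(
    H: np.ndarray,
    system: SpinSystem,
    model: ExchangeModel | None,
    damping_rate: float = 0.0,
) -> GeneratorOperator:
    """Assemble the generator -i*2*pi*[H, .] + (1/tau_Ir)(R - Id) (+ damping).

    Parameters
    ----------
    H : ndarray
        Hermitian Hamiltonian in Hz (the 2*pi is applied here).
    model : ExchangeModel or None
        None (or infinite tau_ir) disables exchange.
    damping_rate : float
        Optional uniform relaxation rate (1/s) toward the maximally mixed
        state; off by default.
    """
    H = np.asarray(H)
    if np.max(np.abs(H - H.conj().T)) > 1e-9 * max(1.0, np.max(np.abs(H))):
        raise ValueError("H must be Hermitian")
    d = H.shape[0]
    if d != system.dim:
        raise ValueError("H dimension does not match the spin system")
    Hs = sp.csr_matrix(H)
    ident = sp.identity(d, format="csr", dtype=complex)
    L = -2j * np.pi * (sp.kron(Hs, ident) - sp.kron(ident, Hs.T))
    tau = None
    if model is not None and np.isfinite(model.tau_ir):
        tau = model.tau_ir
        fed = model.fed_state()
        R = _embed_pair_matrix(system, model.hydride_pair, fed) @ _trace_pair_matrix(
            system, model.hydride_pair
        )
        L = L + (1.0 / tau) * (R - sp.identity(d * d, format="csr", dtype=complex))
    if damping_rate > 0.0:
        # rho -> (Id/d) tr(rho): rank-one sparse term
        diag_positions = np.arange(d) * d + np.arange(d)
        rows = np.repeat(diag_positions, d)
        cols = np.tile(diag_positions, d)
        vals = np.full(d * d, 1.0 / d, dtype=complex)
        T = sp.csr_matrix((vals, (rows, cols)), shape=(d * d, d * d))
        L = L + damping_rate * (T - sp.identity(d * d, format="csr", dtype=complex))
    return GeneratorOperator(sp.csr_matrix(L), d, tau)
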