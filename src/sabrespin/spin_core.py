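"""Spin-1/2 product-operator algebra and the pyruvate-SABRE spin system.

The objects here describe the *active* SABRE complex: two parahydrogen-derived
hydride protons, the three methyl protons of 1-(13C)-pyruvate, and the carboxyl
carbon-13.  Everything downstream (Hamiltonians, exchange superoperators,
protocol emulation) is built on the product basis fixed in this module.

Conventions
-----------
* Each spin is spin-1/2; |alpha> is the +z eigenstate, |beta> the -z eigenstate.
* Spins are ordered as declared in the :class:`SpinSystem`; the tensor index is
  big-endian over the spin list (spin 0 is the most significant qubit).
* Gyromagnetic ratios are stored in MHz/T, which is numerically identical to
  Hz/uT -- Larmor frequencies in Hz follow directly from fields in microtesla.
* J couplings are in Hz throughout; factors of 2*pi enter only when a
  Hamiltonian is turned into a propagator (see :mod:`sabrespin.exchange`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "GAMMA_MHZ_PER_T",
    "SpinSpec",
    "SpinSystem",
    "CouplingNetwork",
    "DensityState",
    "StaticField",
    "Preset",
    "build_operator",
    "pauli_half",
    "singlet_state",
    "singlet_density",
    "triplet_states",
    "partial_trace",
    "tensor_embed",
    "maximally_mixed",
    "preset_pyruvate_sabre",
]

#: Default gyromagnetic ratios, MHz/T (== Hz/uT).
GAMMA_MHZ_PER_T: Dict[str, float] = {"1H": 42.577, "13C": 10.7084}

_SX = np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex)
_SY = np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex)
_SZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_ID2 = np.eye(2, dtype=complex)
_AXES = {"x": _SX, "y": _SY, "z": _SZ}


def pauli_half(axis: str) -> np.ndarray:
    """Single spin-1/2 operator I_axis (2x2), axis in {x, y, z}."""
    try:
        return _AXES[axis].copy()
    except KeyError:
        raise ValueError(f"unknown axis {axis!r}; expected one of x, y, z") from None


@dataclass(frozen=True)
class SpinSpec:
    """One spin-1/2 nucleus.

    Parameters
    ----------
    label : str
        Unique name within the system (e.g. ``"hydride_a"``).
    isotope : str
        ``"1H"`` or ``"13C"``.
    gyromagnetic_ratio : float, optional
        MHz/T; defaults to the tabulated value for the isotope.
    chemical_shift : float
        Chemical shift in ppm relative to the isotope reference frequency.
    """

    label: str
    isotope: str
    gyromagnetic_ratio: float | None = None
    chemical_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.isotope not in GAMMA_MHZ_PER_T:
            raise ValueError(f"unsupported isotope {self.isotope!r}")
        if self.gyromagnetic_ratio is None:
            object.__setattr__(
                self, "gyromagnetic_ratio", GAMMA_MHZ_PER_T[self.isotope]
            )
        if self.gyromagnetic_ratio <= 0:
            raise ValueError("gyromagnetic_ratio must be positive")
        if not np.isfinite(self.chemical_shift):
            raise ValueError("chemical_shift must be finite")


@dataclass(frozen=True)
class SpinSystem:
    """An ordered collection of spins plus their chemical roles."""

    spins: Tuple[SpinSpec, ...]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spins", tuple(self.spins))
        labels = [s.label for s in self.spins]
        if len(set(labels)) != len(labels):
            raise ValueError("spin labels must be unique")
        object.__setattr__(self, "roles", dict(self.roles))

    @property
    def n_spins(self) -> int:
        return len(self.spins)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(s.label for s in self.spins)

    def index(self, label: str) -> int:
        for i, s in enumerate(self.spins):
            if s.label == label:
                return i
        raise KeyError(f"unknown spin label {label!r}")

    def spec(self, label: str) -> SpinSpec:
        return self.spins[self.index(label)]

    def labels_with_role(self, role_prefix: str) -> Tuple[str, ...]:
        return tuple(
            lbl for lbl, r in self.roles.items() if r.startswith(role_prefix)
        )

    def labels_with_isotope(self, isotope: str) -> Tuple[str, ...]:
        return tuple(s.label for s in self.spins if s.isotope == isotope)

    @property
    def hydride_pair(self) -> Tuple[str, str]:
        pair = sorted(
            (lbl for lbl, r in self.roles.items() if r.startswith("hydride")),
            key=lambda l: self.roles[l],
        )
        if len(pair) != 2:
            raise ValueError("system must declare exactly two hydride roles")
        return tuple(pair)  # type: ignore[return-value]

    @property
    def carbon(self) -> str:
        carbons = [lbl for lbl, r in self.roles.items() if r == "carbon"]
        if len(carbons) != 1:
            raise ValueError("system must declare exactly one carbon role")
        return carbons[0]


@dataclass(frozen=True)
class CouplingNetwork:
    """Scalar (J) couplings in Hz, stored as a symmetric matrix over spins."""

    J: np.ndarray

    def __post_init__(self) -> None:
        J = np.array(self.J, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("J must be a square matrix")
        if not np.allclose(J, J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(J), 0.0, atol=1e-12):
            raise ValueError("J must have zero diagonal")
        object.__setattr__(self, "J", J)

    @classmethod
    def from_pairs(
        cls, system: SpinSystem, pairs: Iterable[Tuple[str, str, float]]
    ) -> "CouplingNetwork":
        J = np.zeros((system.n_spins, system.n_spins))
        for a, b, value in pairs:
            ia, ib = system.index(a), system.index(b)
            if ia == ib:
                raise ValueError("self-coupling is not allowed")
            J[ia, ib] = J[ib, ia] = float(value)
        return cls(J)

    def coupling(self, system: SpinSystem, a: str, b: str) -> float:
        return float(self.J[system.index(a), system.index(b)])


@dataclass
class DensityState:
    """A density matrix on the full product basis."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.array(self.matrix, dtype=complex)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def validate(
        self,
        trace_tol: float = 1e-9,
        herm_tol: float = 1e-9,
        eig_tol: float = 1e-8,
    ) -> "DensityState":
        """Assert unit trace, Hermiticity and positivity (within tolerances)."""
        tr = np.trace(self.matrix)
        if abs(tr - 1.0) > trace_tol:
            raise ValueError(f"trace {tr} differs from 1 by more than {trace_tol}")
        if np.max(np.abs(self.matrix - self.matrix.conj().T)) > herm_tol:
            raise ValueError("density matrix is not Hermitian")
        w = np.linalg.eigvalsh(0.5 * (self.matrix + self.matrix.conj().T))
        if w.min() < -eig_tol:
            raise ValueError(f"negative eigenvalue {w.min()}")
        return self


@dataclass(frozen=True)
class StaticField:
    """The static magnetic field B0, in microtesla."""

    b0_ut: float

    def __post_init__(self) -> None:
        if self.b0_ut < 0:
            raise ValueError("B0 must be non-negative")


def _embed_single(system: SpinSystem, index: int, op2: np.ndarray) -> np.ndarray:
    mats = [_ID2] * system.n_spins
    mats[index] = op2
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def build_operator(system: SpinSystem, spin_label: str, axis: str) -> np.ndarray:
    """Spin operator for one spin, embedded in the full product space.

    Returns the 2^N x 2^N matrix acting as I_axis on ``spin_label`` and as the
    identity on every other spin.
    """
    return _embed_single(system, system.index(spin_label), pauli_half(axis))


def singlet_state() -> np.ndarray:
    """|S> = (|alpha beta> - |beta alpha>)/sqrt(2) on two spins (length-4 ket)."""
    v = np.zeros(4, dtype=complex)
    v[1] = 1.0 / np.sqrt(2.0)
    v[2] = -1.0 / np.sqrt(2.0)
    return v


def triplet_states() -> Dict[str, np.ndarray]:
    """The three triplet kets |T+>, |T0>, |T-> on two spins."""
    tp = np.zeros(4, dtype=complex)
    tp[0] = 1.0
    t0 = np.zeros(4, dtype=complex)
    t0[1] = t0[2] = 1.0 / np.sqrt(2.0)
    tm = np.zeros(4, dtype=complex)
    tm[3] = 1.0
    return {"T+": tp, "T0": t0, "T-": tm}


def maximally_mixed(n_spins: int) -> np.ndarray:
    d = 2 ** n_spins
    return np.eye(d, dtype=complex) / d


def tensor_embed(
    system: SpinSystem,
    block: np.ndarray,
    block_labels: Sequence[str],
    rest: np.ndarray | None = None,
) -> np.ndarray:
    """Embed ``block`` (density operator on ``block_labels``) into the full space.

    The remaining spins carry ``rest`` (default: maximally mixed).  The result
    respects the declared spin ordering of ``system`` regardless of the order
    or position of ``block_labels``.
    """
    idx = [system.index(l) for l in block_labels]
    if len(set(idx)) != len(idx):
        raise ValueError("block labels must be distinct")
    other = [i for i in range(system.n_spins) if i not in idx]
    if rest is None:
        rest = maximally_mixed(len(other))
    rest = np.asarray(rest, dtype=complex)
    if rest.shape != (2 ** len(other), 2 ** len(other)):
        raise ValueError("rest has wrong dimension")
    full = np.kron(np.asarray(block, dtype=complex), rest)
    # current axis order: block spins (as given) then the others; permute back
    order = idx + other
    n = system.n_spins
    tens = full.reshape([2] * (2 * n))
    perm = np.argsort(order)
    tens = tens.transpose(list(perm) + [n + p for p in perm])
    return np.ascontiguousarray(tens.reshape(2 ** n, 2 ** n))


def singlet_density(
    system: SpinSystem,
    pair: Tuple[str, str] | None = None,
    rest: np.ndarray | None = None,
) -> DensityState:
    """Density matrix with ``pair`` in the pure singlet state.

    The remaining spins are maximally mixed unless ``rest`` is supplied.  This
    is the canonical initial state of the active complex right after a fresh
    parahydrogen molecule binds.
    """
    if pair is None:
        pair = system.hydride_pair
    a, b = pair
    if a == b:
        raise ValueError("pair labels must be distinct")
    s = singlet_state()
    block = np.outer(s, s.conj())
    return DensityState(tensor_embed(system, block, (a, b), rest))


def partial_trace(
    state: DensityState | np.ndarray, system: SpinSystem, keep: Sequence[str]
) -> np.ndarray:
    """Reduced density matrix over the spins in ``keep`` (declared order)."""
    keep = list(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    rho = np.asarray(state.matrix if isinstance(state, DensityState) else state)
    keep_idx = sorted(system.index(l) for l in keep)
    if len(set(keep_idx)) != len(keep_idx):
        raise ValueError("keep labels must be distinct")
    n = system.n_spins
    drop = [i for i in range(n) if i not in keep_idx]
    tens = rho.reshape([2] * (2 * n))
    for k, i in enumerate(sorted(drop, reverse=True)):
        # trace axis i (bra) against axis i+current_n (ket)
        cur_n = n - k
        tens = np.trace(tens, axis1=i, axis2=i + cur_n)
    d = 2 ** len(keep_idx)
    return np.ascontiguousarray(tens.reshape(d, d))


@dataclass(frozen=True)
class Preset:
    """A complete model parameterization: spins, couplings, exchange, field."""

    system: SpinSystem
    couplings: CouplingNetwork
    exchange: "object"  # ExchangeModel; typed loosely to avoid a cycle
    field: StaticField

    def with_exchange(self, exchange) -> "Preset":
        return replace(self, exchange=exchange)


def preset_pyruvate_sabre(reduced: bool = False):
    """The 1-(13C)-pyruvate SABRE parameterization.

    Six spins (two hydrides, three methyl protons, one carbon-13) with
    J_HH = -10.5 Hz between the hydrides, 0.06 Hz from one hydride to the
    carbon (0 from the other), 1.2 Hz from the carbon to each methyl proton;
    complex lifetime tau_Ir = 31 ms; static field B0 = 121 uT; hydride
    chemical-shift difference 2 ppm.

    Parameters
    ----------
    reduced : bool
        If True, return the fast three-spin fixture (two hydrides + carbon)
        with the same couplings among the retained spins.  Useful for tests
        and brute-force oracles.
    """
    from .exchange import ExchangeModel  # local import to avoid a cycle

    hydrides = [
        SpinSpec("hydride_a", "1H", chemical_shift=0.0),
        SpinSpec("hydride_b", "1H", chemical_shift=2.0),
    ]
    methyls = [SpinSpec(f"methyl_{k}", "1H") for k in (1, 2, 3)]
    carbon = SpinSpec("carbon", "13C")

    if reduced:
        spins = hydrides + [carbon]
        roles = {"hydride_a": "hydride_a", "hydride_b": "hydride_b", "carbon": "carbon"}
    else:
        spins = hydrides + methyls + [carbon]
        roles = {
            "hydride_a": "hydride_a",
            "hydride_b": "hydride_b",
            "methyl_1": "methyl_1",
            "methyl_2": "methyl_2",
            "methyl_3": "methyl_3",
            "carbon": "carbon",
        }
    system = SpinSystem(tuple(spins), roles)
    pairs = [("hydride_a", "hydride_b", -10.5), ("hydride_a", "carbon", 0.06)]
    if not reduced:
        pairs += [("carbon", f"methyl_{k}", 1.2) for k in (1, 2, 3)]
    couplings = CouplingNetwork.from_pairs(system, pairs)
    exchange = ExchangeModel(
        tau_ir=0.031, hydride_pair=("hydride_a", "hydride_b"), singlet_fraction=1.0
    )
    return Preset(system, couplings, exchange, StaticField(121.0))
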