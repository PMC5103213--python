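"""Spin operators, projectors and the orientation-dependent Hamiltonian.

The magnetosensitive radical pair is modelled as two electron spins, each
hyperfine-coupled to a single spin-1/2 nucleus, giving a 16-dimensional
Hilbert space with the fixed tensor-product ordering

    electron 1  (x)  electron 2  (x)  nucleus 1  (x)  nucleus 2.

The Hamiltonian contains the electronic Zeeman interaction with the
geomagnetic field and the two hyperfine couplings,

    H = (mu_B/hbar) * [ g1 B.S1 + g2 B.S2 + g1 S1.A1.I1 + g2 S2.A2.I2 ],

with the hyperfine tensors A diagonal in the molecular frame and given in
tesla, so H is in angular-frequency units (rad/s).  Exchange and
dipole-dipole couplings between the radicals are neglected, as is the
nuclear Zeeman interaction (three to four orders of magnitude smaller than
the electronic one at geomagnetic field strength).

The external field direction is parameterised by the single polar angle
Theta in the molecular x-z plane: B = B0 * (sin Theta, 0, cos Theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import G_ELECTRON_DEFAULT, MT_TO_TESLA, MU_B, HBAR

__all__ = [
    "HyperfineTensor",
    "MagneticField",
    "SpinSystem",
    "SpinOperators",
    "build_spin_operators",
    "singlet_projector",
    "triplet_projector",
    "build_hamiltonian",
    "SPIN_SYSTEM_PRESETS",
    "get_spin_system",
]

DIM = 16

# Single spin-1/2 operator set in hbar units.
_SX = 0.5 * np.array([[0, 1], [1, 0]], dtype=complex)
_SY = 0.5 * np.array([[0, -1j], [1j, 0]], dtype=complex)
_SZ = 0.5 * np.array([[1, 0], [0, -1]], dtype=complex)
_ID2 = np.eye(2, dtype=complex)


@dataclass(frozen=True)
class HyperfineTensor:
    """Diagonal hyperfine coupling tensor in the molecular frame.

    Principal values are given in millitesla; the tensor is diagonal by
    construction, so no symmetrisation is required.
    """

    principal_values_mT: tuple[float, float, float]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.principal_values_mT)
        if len(vals) != 3 or not all(math.isfinite(v) for v in vals):
            raise ValueError("hyperfine tensor needs three finite principal values")
        object.__setattr__(self, "principal_values_mT", vals)

    @property
    def tesla(self) -> np.ndarray:
        """Principal values converted to tesla."""
        return np.asarray(self.principal_values_mT) * MT_TO_TESLA

    @property
    def is_isotropic(self) -> bool:
        v = self.principal_values_mT
        return v[0] == v[1] == v[2]


@dataclass(frozen=True)
class MagneticField:
    """Static external field of magnitude ``b0_tesla`` at polar angle theta.

    The field vector lies in the molecular x-z plane:
    B = B0 (sin Theta, 0, cos Theta) with Theta in degrees.
    """

    b0_tesla: float
    theta_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.b0_tesla) and math.isfinite(self.theta_deg)):
            raise ValueError("field magnitude and angle must be finite")
        if self.b0_tesla < 0:
            raise ValueError("field magnitude must be non-negative")

    @property
    def vector_tesla(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        return self.b0_tesla * np.array([math.sin(th), 0.0, math.cos(th)])


@dataclass(frozen=True)
class SpinSystem:
    """Two radicals, each with one unpaired electron and one spin-1/2 nucleus."""

    a1: HyperfineTensor
    a2: HyperfineTensor
    g1: float = G_ELECTRON_DEFAULT
    g2: float = G_ELECTRON_DEFAULT

    dim: int = field(default=DIM, init=False)


@dataclass(frozen=True)
class SpinOperators:
    """Cartesian spin operator triples embedded in the 16-dim product space."""

    s1: tuple[np.ndarray, np.ndarray, np.ndarray]
    s2: tuple[np.ndarray, np.ndarray, np.ndarray]
    i1: tuple[np.ndarray, np.ndarray, np.ndarray]
    i2: tuple[np.ndarray, np.ndarray, np.ndarray]


def _embed(op: np.ndarray, position: int) -> np.ndarray:
    """Place a single-spin operator at `position` in e1 (x) e2 (x) n1 (x) n2."""
    factors = [_ID2, _ID2, _ID2, _ID2]
    factors[position] = op
    out = factors[0]
    for f in factors[1:]:
        out = np.kron(out, f)
    return out


@lru_cache(maxsize=None)
def build_spin_operators(system: SpinSystem | None = None) -> SpinOperators:
    """Build the four spin operator triples as 16x16 complex matrices.

    The operators depend only on the fixed 2-electron/2-nucleus topology,
    not on the coupling tensors, so the result is cached.
    """
    triples = []
    for pos in range(4):
        triples.append(tuple(_embed(op, pos) for op in (_SX, _SY, _SZ)))
    return SpinOperators(s1=triples[0], s2=triples[1], i1=triples[2], i2=triples[3])


def singlet_projector(system: SpinSystem | None = None) -> np.ndarray:
    """Projector onto the electronic singlet, Q_S = 1/4 - S1.S2.

    Acts as the identity on both nuclear spins, hence trace(Q_S) = 4.
    """
    ops = build_spin_operators(system)
    s1s2 = sum(a @ b for a, b in zip(ops.s1, ops.s2))
    return 0.25 * np.eye(DIM, dtype=complex) - s1s2


def triplet_projector(system: SpinSystem | None = None) -> np.ndarray:
    """Projector onto the electronic triplet manifold, Q_T = 1 - Q_S."""
    return np.eye(DIM, dtype=complex) - singlet_projector(system)


def build_hamiltonian(system: SpinSystem, field: MagneticField) -> np.ndarray:
    """Zeeman + hyperfine Hamiltonian of the primary pair, in rad/s.

    Hermitian to machine precision and periodic in Theta with period 360
    degrees.
    """
    ops = build_spin_operators(system)
    b_vec = field.vector_tesla

    h = np.zeros((DIM, DIM), dtype=complex)
    for g, s_ops, i_ops, hf in (
        (system.g1, ops.s1, ops.i1, system.a1),
        (system.g2, ops.s2, ops.i2, system.a2),
    ):
        gamma = g * MU_B / HBAR
        a_tesla = hf.tesla
        for k in range(3):
            h += gamma * b_vec[k] * s_ops[k]
            h += gamma * a_tesla[k] * (s_ops[k] @ i_ops[k])
    return h


#: Spin-system presets addressable by name in run configurations.
#: "reference": axial tensor (1, 1, 0) mT on radical 1, isotropic 0.5 mT on
#: radical 2 — the standard model compass system.
#: "avoided_crossing": tensors tuned so the spin levels exhibit an avoided
#: crossing versus orientation, producing a narrow spike in the singlet yield.
SPIN_SYSTEM_PRESETS: dict[str, SpinSystem] = {
    "reference": SpinSystem(
        a1=HyperfineTensor((1.0, 1.0, 0.0)),
        a2=HyperfineTensor((0.5, 0.5, 0.5)),
    ),
    "avoided_crossing": SpinSystem(
        a1=HyperfineTensor((-0.0989, -0.0989, 1.7569)),
        a2=HyperfineTensor((0.0, 0.0, 1.0812)),
    ),
}


def get_spin_system(name: str) -> SpinSystem:
    """Look up a named spin-system preset."""
    try:
        return SPIN_SYSTEM_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown spin system preset {name!r}; "
            f"available: {sorted(SPIN_SYSTEM_PRESETS)}"
        ) from None
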