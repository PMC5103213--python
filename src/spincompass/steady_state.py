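"""Steady state of the cyclic radical-pair reaction scheme.

The primary radical pair RP1 is generated photochemically in the electronic
singlet state at a rate R0, evolves coherently under the spin Hamiltonian,
recombines spin-selectively (singlet only) through a fast regeneration
channel with rate constant k_r, and is converted spin-independently into the
secondary pair RP2 with the forward rate constant k_f.  The density matrix
obeys the stochastic Liouville equation

    drho/dt = R0 Q_S / Tr(Q_S)  -  i [H, rho]
              -  (k_r / 2) {Q_S, rho}  -  k_f rho,

with the singlet-selective reaction in Haberkorn (anticommutator) form.
Under continuous illumination rho reaches a steady state, obtained here by a
direct dense solve of the 256-dimensional vectorised linear system.

Dimensionless product-formation rates are normalised by the classical rate
R_cl = R0 k_f / (k_f + k_r), the product rate in the absence of coherent
singlet-triplet mixing, so that R(Theta) counts the effective number of spin
conversion channels opened by the magnetic interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lapack, lu_factor, lu_solve

from .spin_hamiltonian import DIM, singlet_projector, triplet_projector

__all__ = [
    "RateConstants",
    "SteadyState",
    "RateTriple",
    "build_liouvillian",
    "solve_steady_state",
    "compute_rates",
]

CONDITION_WARN_THRESHOLD = 1e12
RESIDUAL_RTOL = 1e-8


@dataclass(frozen=True)
class RateConstants:
    """Reaction rate constants of the cyclic scheme (all in s^-1).

    k_f  -- spin-independent forward conversion RP1 -> RP2
    k_r  -- spin-selective (singlet-only) regeneration of the photoreceptor;
            the "back" rate of the cycle
    r0   -- generation rate of singlet RP1 under continuous illumination
    """

    k_f: float
    k_r: float
    r0: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_f) and self.k_f > 0):
            raise ValueError("k_f must be positive (steady state requires decay)")
        if not (math.isfinite(self.k_r) and self.k_r >= 0):
            raise ValueError("k_r must be non-negative")
        if not (math.isfinite(self.r0) and self.r0 > 0):
            raise ValueError("r0 must be positive")

    @property
    def k_b(self) -> float:
        """Alias: the backward rate of the cycle is the regeneration rate."""
        return self.k_r

    @property
    def classical_rate(self) -> float:
        """Product-formation rate with no singlet-triplet mixing,
        R_cl = R0 k_f / (k_f + k_r)."""
        return self.r0 * self.k_f / (self.k_f + self.k_r)


@dataclass(frozen=True)
class SteadyState:
    """Steady-state density matrix with solver diagnostics.

    rho has dimension of seconds (a population per unit generation rate);
    its trace times k_f is the absolute RP2 formation rate.
    """

    rho: np.ndarray
    residual_norm: float
    condition_estimate: float
    method: str = "dense-lu"


def build_liouvillian(
    h: np.ndarray, rates: RateConstants
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised generator of the spin density-matrix equation of motion.

    Returns ``(L, source)`` with column-stacking convention
    vec(A X B) = (B^T kron A) vec(X), such that

        d vec(rho)/dt = L vec(rho) + source,

    where L encodes -i[H, .] - (k_r/2){Q_S, .} - k_f and
    source = vec(R0 Q_S / Tr(Q_S)).  Dividing the source by Tr(Q_S) makes
    the total population inflow exactly R0.
    """
    h = np.asarray(h, dtype=complex)
    if h.shape != (DIM, DIM):
        raise ValueError(f"Hamiltonian must be {DIM}x{DIM}")
    qs = singlet_projector()
    eye = np.eye(DIM, dtype=complex)

    commutator = -1j * (np.kron(eye, h) - np.kron(h.T, eye))
    # Q_S is real-symmetric, so Q_S^T = Q_S.
    haberkorn = -(rates.k_r / 2.0) * (np.kron(eye, qs) + np.kron(qs.T, eye))
    decay = -rates.k_f * np.eye(DIM * DIM, dtype=complex)

    liouv = commutator + haberkorn + decay
    source = (rates.r0 / np.trace(qs).real) * qs.flatten(order="F")
    return liouv, source


def solve_steady_state(h: np.ndarray, rates: RateConstants) -> SteadyState:
    """Solve L vec(rho) = -source for the steady-state density matrix.

    Raises ``np.linalg.LinAlgError`` if the system is singular or the
    condition estimate exceeds the warning threshold (the steady state would
    not be numerically trustworthy).
    """
    liouv, source = build_liouvillian(h, rates)

    anorm = np.linalg.norm(liouv, 1)
    lu, piv = lu_factor(liouv)
    rcond, _ = lapack.zgecon(lu, anorm)
    cond = 1.0 / rcond if rcond > 0 else np.inf
    if not np.isfinite(cond) or cond > CONDITION_WARN_THRESHOLD:
        raise np.linalg.LinAlgError(
            f"ill-conditioned steady-state solve (cond estimate {cond:.3e} "
            f"> {CONDITION_WARN_THRESHOLD:.0e}) for k_f={rates.k_f}, "
            f"k_r={rates.k_r}"
        )

    x = lu_solve((lu, piv), -source)
    residual = float(np.linalg.norm(liouv @ x + source))
    src_norm = float(np.linalg.norm(source))
    if residual > RESIDUAL_RTOL * src_norm:
        raise np.linalg.LinAlgError(
            f"steady-state residual {residual:.3e} exceeds "
            f"{RESIDUAL_RTOL:.0e} * ||source|| = {RESIDUAL_RTOL * src_norm:.3e}"
        )

    rho = x.reshape((DIM, DIM), order="F")
    # The exact steady state is Hermitian; discard the anti-Hermitian
    # round-off component.
    rho = 0.5 * (rho + rho.conj().T)
    return SteadyState(
        rho=rho, residual_norm=residual, condition_estimate=cond
    )


@dataclass(frozen=True)
class RateTriple:
    """Dimensionless steady-state product-formation rates.

    total = singlet + triplet holds exactly by projector completeness; all
    three are independent of the generation rate R0.
    """

    total: float
    singlet: float
    triplet: float


def compute_rates(ss: SteadyState, rates: RateConstants) -> RateTriple:
    """Dimensionless RP2 formation rates from a steady state.

    R   = k_f Tr(rho)     / R_cl   (total)
    R_S = k_f Tr(Q_S rho) / R_cl   (via the singlet channel)
    R_T = k_f Tr(Q_T rho) / R_cl   (via the triplet channel)
    """
    qs = singlet_projector()
    qt = triplet_projector()
    r_cl = rates.classical_rate
    singlet = rates.k_f * np.trace(qs @ ss.rho).real / r_cl
    triplet = rates.k_f * np.trace(qt @ ss.rho).real / r_cl
    return RateTriple(total=singlet + triplet, singlet=singlet, triplet=triplet)
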