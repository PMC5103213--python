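"""Orientation sweeps, compass-precision metrics and cycle amplification.

The orientation dependence of the steady-state product-formation rate,
R(Theta), is the compass signal.  Because absolute rates are confounded by
light intensity, the biologically readable quantity is the relative change

    R_relative(Theta) = 100 * (R_max - R(Theta)) / R_max   [%],

which is zero at the best orientation and largest where the rate drops most.
Three scalar summaries characterise a compass:

* efficiency      -- the maximum value R_relative can attain,
                     100 * (R_max - R_min) / R_max;
* directionality  -- where the orientation-average sits between the
                     extremes, 100 * (<R> - R_min) / (R_max - R_min):
                     50% for the broadest possible signal, approaching 100%
                     when the response is flat near R_max except for a
                     narrow spike down to R_min;
* optimality      -- efficiency * (2*directionality - 100) / 100, clipped at
                     zero: vanishes for the broadest distribution and grows
                     with both amplitude and sharpness.

The cyclic reaction scheme amplifies small orientation-dependent changes in
the per-cycle signalling probability p_f: over lam photoexcitation cycles
the probability of reaching the signalling state is 1 - (1 - p_f)^lam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spin_hamiltonian import MagneticField, SpinSystem, build_hamiltonian
from .steady_state import RateConstants, compute_rates, solve_steady_state

__all__ = [
    "AngularResponse",
    "CompassMetrics",
    "AmplificationParams",
    "angular_sweep",
    "relative_rate",
    "compass_metrics",
    "metric_grid",
    "amplification_probability",
    "DEFAULT_THETA_GRID",
    "DEFAULT_B0_TESLA",
]

logger = logging.getLogger(__name__)

DEFAULT_B0_TESLA = 50e-6
DEFAULT_THETA_GRID = np.arange(0.0, 180.0 + 0.5, 1.0)

#: Components of the product-formation rate addressable by name.
_COMPONENTS = ("total", "singlet", "triplet")


@dataclass(frozen=True)
class AngularResponse:
    """Product-formation rates on an orientation grid.

    All rate arrays are dimensionless (normalised by the classical rate) and
    parallel to ``theta_deg``; total = singlet + triplet elementwise.
    """

    theta_deg: np.ndarray
    total: np.ndarray
    singlet: np.ndarray
    triplet: np.ndarray
    rates: RateConstants
    preset: str | None = None

    def component(self, name: str) -> np.ndarray:
        if name not in _COMPONENTS:
            raise ValueError(f"component must be one of {_COMPONENTS}, got {name!r}")
        return getattr(self, name)

    @property
    def r_max(self) -> float:
        return float(np.max(self.total))

    @property
    def r_min(self) -> float:
        return float(np.min(self.total))

    @property
    def r_mean(self) -> float:
        """Unweighted orientation average over the grid."""
        return float(np.mean(self.total))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per orientation."""
        return pd.DataFrame(
            {
                "theta_deg": self.theta_deg,
                "R": self.total,
                "R_S": self.singlet,
                "R_T": self.triplet,
                "R_relative": relative_rate(self, "total"),
            }
        )


@dataclass(frozen=True)
class CompassMetrics:
    """Scalar compass-precision summaries, each in percent on [0, 100]."""

    efficiency: float
    directionality: float
    optimality: float


@dataclass(frozen=True)
class AmplificationParams:
    """Per-cycle signalling probability and number of excitation cycles."""

    p_f: float
    lam: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_f <= 1.0:
            raise ValueError("p_f must lie in [0, 1]")
        if self.lam < 1:
            raise ValueError("number of excitation cycles must be >= 1")

    @property
    def p_r(self) -> float:
        """Probability of the regeneration pathway in one cycle."""
        return 1.0 - self.p_f


def angular_sweep(
    system: SpinSystem,
    rates: RateConstants,
    theta_grid: np.ndarray | None = None,
    b0_tesla: float = DEFAULT_B0_TESLA,
    preset: str | None = None,
) -> AngularResponse:
    """Solve the steady state at every orientation on the grid.

    The grid must be strictly increasing; the default covers [0, 180]
    degrees in 1-degree steps.
    """
    grid = DEFAULT_THETA_GRID if theta_grid is None else np.asarray(theta_grid, float)
    if grid.size == 0:
        raise ValueError("theta grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("theta grid must be strictly increasing")

    total = np.empty(grid.size)
    singlet = np.empty(grid.size)
    triplet = np.empty(grid.size)
    for i, theta in enumerate(grid):
        h = build_hamiltonian(system, MagneticField(b0_tesla, theta))
        try:
            ss = solve_steady_state(h, rates)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"steady-state solve failed at theta = {theta} deg: {err}"
            ) from err
        triple = compute_rates(ss, rates)
        total[i], singlet[i], triplet[i] = (
            triple.total,
            triple.singlet,
            triple.triplet,
        )
    logger.info(
        "angular sweep: %d orientations, k_f=%.3g s^-1, k_r=%.3g s^-1",
        grid.size,
        rates.k_f,
        rates.k_r,
    )
    return AngularResponse(
        theta_deg=grid,
        total=total,
        singlet=singlet,
        triplet=triplet,
        rates=rates,
        preset=preset,
    )


def relative_rate(resp: AngularResponse, component: str = "total") -> np.ndarray:
    """Relative change of a rate component across orientations, in percent.

    R_relative(Theta) = 100 * (C_max - C(Theta)) / C_max for component curve
    C; zero at the argmax, bounded by [0, 100].
    """
    curve = resp.component(component)
    c_max = float(np.max(curve))
    if c_max <= 0.0:
        raise ValueError(f"component {component!r} has no positive maximum")
    return 100.0 * (c_max - curve) / c_max


def compass_metrics(resp: AngularResponse) -> CompassMetrics:
    """Efficiency, directionality and optimality of a response curve.

    A constant response carries no directional information: efficiency 0,
    directionality 50 (by convention) and optimality 0.
    """
    r_max, r_min, r_mean = resp.r_max, resp.r_min, resp.r_mean
    spread = r_max - r_min
    if spread <= 0.0 or r_max <= 0.0:
        return CompassMetrics(efficiency=0.0, directionality=50.0, optimality=0.0)
    efficiency = 100.0 * spread / r_max
    directionality = 100.0 * (r_mean - r_min) / spread
    optimality = max(0.0, efficiency * (2.0 * directionality - 100.0) / 100.0)
    return CompassMetrics(
        efficiency=efficiency, directionality=directionality, optimality=optimality
    )


def metric_grid(
    system: SpinSystem,
    k_f_grid: np.ndarray,
    k_r_grid: np.ndarray,
    theta_grid: np.ndarray | None = None,
    b0_tesla: float = DEFAULT_B0_TESLA,
    r0: float = 1.0,
) -> pd.DataFrame:
    """Compass metrics over a (k_f, k_r) rate-constant grid.

    Returns a long-format table sorted by (k_f, k_r) with one row per cell;
    cells whose steady-state solve fails are recorded with NaN metrics and
    an ``error`` message rather than aborting the grid.
    """
    rows = []
    for k_f in np.sort(np.asarray(k_f_grid, float)):
        for k_r in np.sort(np.asarray(k_r_grid, float)):
            row: dict = {"k_f": k_f, "k_r": k_r}
            try:
                resp = angular_sweep(
                    system,
                    RateConstants(k_f=k_f, k_r=k_r, r0=r0),
                    theta_grid,
                    b0_tesla,
                )
                m = compass_metrics(resp)
                row.update(
                    efficiency_pct=m.efficiency,
                    directionality_pct=m.directionality,
                    optimality_pct=m.optimality,
                    error="",
                )
            except (np.linalg.LinAlgError, ValueError) as err:
                logger.warning("grid cell k_f=%g k_r=%g failed: %s", k_f, k_r, err)
                row.update(
                    efficiency_pct=np.nan,
                    directionality_pct=np.nan,
                    optimality_pct=np.nan,
                    error=str(err),
                )
            logger.info("grid cell k_f=%g k_r=%g done", k_f, k_r)
            rows.append(row)
    return pd.DataFrame(rows)


def amplification_probability(params: AmplificationParams) -> float:
    """Probability of reaching the signalling state within lam cycles.

    P = 1 - p_r^lam = 1 - (1 - p_f)^lam; monotone increasing in both p_f
    and lam, so the photocycle acts as a signal amplifier.
    """
    return 1.0 - params.p_r**params.lam
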