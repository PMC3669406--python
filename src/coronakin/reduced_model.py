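"""Quasi-steady-state reduction of the corona model (the slow dynamics).

During the fast phase the total coverage ``s = sum_i f_i`` relaxes to 1 on
the scale ``tau_fast = 1 / sum_j k_a,j c_j0``; afterwards it stays pinned
while species slowly exchange on the dissociation time scale.  Singular
perturbation eliminates the fast variable: setting the total-coverage
derivative to zero yields the quasi-steady free surface fraction

    theta* = [sum_j k_d,j x_j / (n_j N0)] / [sum_j k_a,j (c_j0 - x_j)]

and the slow model

    dx_i/dt = k_a,i (c_i0 - x_i) n_i N0 theta* - k_d,i x_i,

whose fraction derivatives sum to zero exactly — total coverage is conserved
on the slow manifold.  All terms are of the order of the dissociation rates,
so the reduced system is non-stiff and integrates with explicit methods at
steps of order 1/min k_d.  The separation parameter
``epsilon = max_i k_d,i / sum_j k_a,j c_j0`` controls the reduction error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .composition_analytics import metastable_composition, time_scales
from .model_core import CoronaSystem, Trajectory, check_valid, surface_fractions

__all__ = ["ReducedSettings", "theta_quasi_steady", "reduced_rhs",
           "simulate_reduced", "epsilon", "EPSILON_DUBIOUS"]

#: Above this separation parameter the QSS reduction is flagged as dubious.
EPSILON_DUBIOUS = 0.01


@dataclass(frozen=True)
class ReducedSettings:
    """Tolerances for the (non-stiff) slow-model integration."""

    rel_tol: float = 1e-10
    abs_tol: float = 1e-18
    epsilon_report: bool = True

    def __post_init__(self):
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("solver tolerances must be positive")


def theta_quasi_steady(x: np.ndarray, system: CoronaSystem) -> float:
    """Free surface fraction on the slow manifold.

    The value of theta at which the aggregate coverage balance holds:
    total dissociation flux (in fraction units) equals total association
    flux per unit free surface.

    Raises
    ------
    ValueError
        When all free protein is exhausted (denominator <= 0): the slow
        manifold is undefined there.
    """
    x = np.asarray(x, dtype=float)
    denom = float((system.k_a * (system.c0 - x)).sum())
    if denom <= 0:
        raise ValueError("slow manifold undefined: all free protein exhausted")
    numer = float((system.k_d * x / system.cap).sum())
    return numer / denom


def reduced_rhs(x: np.ndarray, system: CoronaSystem) -> np.ndarray:
    """Slow-model time derivatives (M/s); fraction derivatives sum to zero."""
    x = np.asarray(x, dtype=float)
    th = theta_quasi_steady(x, system)
    return system.k_a * (system.c0 - x) * system.cap * th - system.k_d * x


def simulate_reduced(
    system: CoronaSystem,
    t_grid: np.ndarray | None = None,
    settings: ReducedSettings | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the slow model from the metastable composition.

    The default initial condition is the metastable closed form (the state
    the fast phase hands over); pass ``x0`` to start from any admissible
    state instead, e.g. a full-model state when measuring the reduction
    error in isolation.  The trajectory conserves total coverage and
    converges to the equilibrium on its coverage slice (the exact
    equilibrium, up to its free surface fraction).  Requires every species
    to dissociate — otherwise the slow phase is trivial.
    """
    check_valid(system)
    if np.any(system.k_d <= 0):
        raise ValueError("reduced model requires k_d > 0 for every species")
    settings = settings or ReducedSettings()
    if t_grid is None:
        ts = time_scales(system)
        t_grid = np.geomspace(10.0 * ts.tau_fast, 100.0 * ts.tau_slow_lower_bound, 200)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be strictly increasing and non-negative")

    if x0 is None:
        x0 = metastable_composition(system).x
    else:
        x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(
        lambda t, x: reduced_rhs(x, system),
        (float(t_grid[0]), float(t_grid[-1])),
        x0,
        method="RK45",
        t_eval=t_grid,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
    )
    if not sol.success:
        raise RuntimeError(
            f"reduced-model solver failed at t = {sol.t[-1] if len(sol.t) else t_grid[0]:.3e} s: "
            f"{sol.message}"
        )
    x = np.clip(sol.y.T, 0.0, None)
    f, theta = surface_fractions(x, system)
    meta = {"model": "reduced", "panel_hash": system.panel_hash(),
            "rel_tol": settings.rel_tol, "abs_tol": settings.abs_tol}
    if settings.epsilon_report:
        meta["epsilon"] = epsilon(system)
    return Trajectory(times=t_grid, x=x, f=f, theta=np.asarray(theta), metadata=meta)


def epsilon(system: CoronaSystem) -> float:
    """Time-scale separation parameter max_i k_d,i / sum_j k_a,j c_j0.

    Values above :data:`EPSILON_DUBIOUS` mean fast and slow phases are not
    well separated and the reduction is dubious.
    """
    flux = float((system.k_a * system.c0).sum())
    if flux <= 0:
        raise ValueError("epsilon undefined: all association fluxes are zero")
    return float(system.k_d.max()) / flux
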