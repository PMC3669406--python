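"""Full mass-action ODE model of corona formation and its integration.

The bound concentration of species ``i`` evolves as

    dx_i/dt = k_a,i (c_i0 - x_i) n_i N0 theta - k_d,i x_i,
    theta   = 1 - sum_j x_j / (n_j N0),

i.e. free protein reacting with the free binding sites ``n_i N0 theta``
available to it, minus first-order dissociation.  Free protein is eliminated
through the conservation law ``free_i = c_i0 - x_i``, so conservation holds
exactly by construction.

The system is stiff: surface filling happens on the scale
``tau_fast = 1 / sum_j k_a,j c_j0`` while protein exchange relaxes on the
scale of dissociation-rate inverses, up to ~9 decades slower.  The default
integrator is therefore implicit (BDF) with an analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    FRACTION_TOL,
    CompositionResult,
    CoronaSystem,
    Trajectory,
    check_valid,
    surface_fractions,
)

__all__ = ["SolverSettings", "ode_rhs", "ode_jacobian", "simulate",
           "two_phase_summary", "TwoPhaseSummary", "default_time_grid"]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the stiff initial-value solve.

    ``abs_tol`` is in M and must sit far below the smallest site capacity so
    that the free surface fraction is resolved near zero.
    """

    rel_tol: float = 1e-10
    abs_tol: float = 1e-18
    max_step: float = np.inf
    stiff: bool = True

    def __post_init__(self):
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("solver tolerances must be positive")


def ode_rhs(x: np.ndarray, system: CoronaSystem) -> np.ndarray:
    """Time derivative of bound concentrations (M/s).

    Small negative entries in ``x`` (solver round-off) are clipped to zero
    before evaluation; likewise a slightly negative free surface fraction.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != system.m:
        raise ValueError(f"state has {x.shape[-1]} species, system has {system.m}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to ode_rhs")
    xc = np.clip(x, 0.0, None)
    theta = max(1.0 - float(np.sum(xc / system.cap)), 0.0)
    return system.k_a * (system.c0 - xc) * system.cap * theta - system.k_d * xc


def ode_jacobian(x: np.ndarray, system: CoronaSystem) -> np.ndarray:
    """Analytic Jacobian d(dx_i/dt)/dx_j of :func:`ode_rhs`."""
    xc = np.clip(np.asarray(x, dtype=float), 0.0, None)
    cap = system.cap
    theta = max(1.0 - float(np.sum(xc / cap)), 0.0)
    assoc = system.k_a * (system.c0 - xc) * cap  # d(rhs_i)/d(theta)
    J = -np.outer(assoc, 1.0 / cap)
    J[np.diag_indices_from(J)] += -system.k_a * cap * theta - system.k_d
    return J


def default_time_grid(system: CoronaSystem, n_points: int = 200) -> np.ndarray:
    """Geometric grid spanning both phases: [tau_fast/100, 100/min k_d].

    Without any dissociating species the upper end falls back to
    ``1000 * tau_fast`` (the slow phase is then absent).
    """
    from .composition_analytics import time_scales

    ts = time_scales(system)
    t_lo = ts.tau_fast / 100.0
    t_hi = 1000.0 * ts.tau_fast if np.isinf(ts.tau_slow_lower_bound) \
        else 100.0 * ts.tau_slow_lower_bound
    return np.geomspace(t_lo, t_hi, n_points)


def simulate(
    system: CoronaSystem,
    t_grid: np.ndarray | None = None,
    settings: SolverSettings | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the full model on an output grid.

    Parameters
    ----------
    t_grid : array, optional
        Strictly increasing output times (s), first entry >= 0.  Defaults to
        :func:`default_time_grid`.
    x0 : array, optional
        Initial bound concentrations; defaults to a bare surface (zeros).

    Returns
    -------
    Trajectory
        Output states satisfying conservation and coverage bounds; a breach
        beyond ten times the fraction tolerance aborts with a diagnostic.
    """
    check_valid(system)
    settings = settings or SolverSettings()
    t_grid = default_time_grid(system) if t_grid is None else np.asarray(t_grid, float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be one-dimensional and strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at a non-negative time")
    x0 = np.zeros(system.m) if x0 is None else np.asarray(x0, dtype=float)

    method = "BDF" if settings.stiff else "RK45"
    extra = {"jac": lambda t, x: ode_jacobian(x, system)} if settings.stiff else {}
    sol = solve_ivp(
        lambda t, x: ode_rhs(x, system),
        (0.0, float(t_grid[-1])),
        x0,
        method=method,
        t_eval=t_grid,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        max_step=settings.max_step,
        **extra,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed at t = {sol.t[-1] if len(sol.t) else 0.0:.3e} s: {sol.message}"
        )

    x = np.clip(sol.y.T, 0.0, None)  # round-off guard, consistent with RHS clipping
    f, theta = surface_fractions(x, system)
    _check_trajectory_invariants(x, f, theta, system)
    return Trajectory(
        times=t_grid,
        x=x,
        f=f,
        theta=np.asarray(theta),
        metadata={
            "model": "full",
            "panel_hash": system.panel_hash(),
            "rel_tol": settings.rel_tol,
            "abs_tol": settings.abs_tol,
            "method": method,
        },
    )


def _check_trajectory_invariants(x, f, theta, system) -> None:
    hard = 10.0 * FRACTION_TOL
    worst_theta = float(np.min(theta))
    if worst_theta < -hard:
        raise RuntimeError(
            f"coverage invariant breached: theta = {worst_theta:.3e} < -{hard:.1e}"
        )
    excess = np.max(x - system.c0[None, :])
    # conservation: bound may not exceed the total supply
    if excess > hard * float(np.max(system.c0)):
        raise RuntimeError(
            f"conservation breached: bound exceeds supply by {excess:.3e} M"
        )


@dataclass(frozen=True)
class TwoPhaseSummary:
    """Empirical two-phase report read off one trajectory.

    ``t_fast_end`` is the first time the free surface fraction drops below
    0.01 (99 % coverage); ``metastable`` the composition there; ``stable``
    the composition at the final output time.  When coverage never reaches
    99 % within the trajectory, ``fast_phase_complete`` is False and the
    compositions are taken at the final time.
    """

    fast_phase_complete: bool
    t_fast_end: float
    metastable: CompositionResult
    stable: CompositionResult


def two_phase_summary(traj: Trajectory, system: CoronaSystem) -> TwoPhaseSummary:
    """Locate the end of the fast phase and report both empirical compositions."""
    theta = np.asarray(traj.theta)
    below = np.nonzero(theta < 0.01)[0]

    def _comp(x_row: np.ndarray, label: str) -> CompositionResult:
        f, th = surface_fractions(x_row, system)
        return CompositionResult(system.names, f, x_row, th, label)

    final = _comp(traj.x[-1], "empirical")
    if len(below) == 0:
        return TwoPhaseSummary(False, float("nan"), final, final)

    k = below[0]
    if k == 0:
        t_cross, x_cross = traj.times[0], traj.x[0]
    else:
        # linear interpolation of the 0.01 crossing between grid points
        t0, t1 = traj.times[k - 1], traj.times[k]
        w = (0.01 - theta[k - 1]) / (theta[k] - theta[k - 1])
        t_cross = t0 + w * (t1 - t0)
        x_cross = traj.x[k - 1] + w * (traj.x[k] - traj.x[k - 1])
    return TwoPhaseSummary(True, float(t_cross), _comp(x_cross, "empirical"), final)
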