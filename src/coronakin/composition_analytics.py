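"""Closed-form corona compositions and characteristic time scales.

Two closed forms fall out of the two-phase structure of competitive
adsorption:

* **Metastable** (end of the fast, association-dominated phase): fractions
  proportional to the association fluxes ``k_a,i c_i0``.  Valid when enough
  protein is around that the surface, not the supply, is limiting.
* **Stable** (long-run equilibrium): the competitive Langmuir isotherm,
  fractions proportional to ``K_i c_i0`` with ``K_i = k_a,i / k_d,i``,
  assuming negligible depletion of free protein.

Both are independent of the coverage numbers ``n_i`` and of ``N0``.  The
exact equilibrium — with protein depletion retained — has no closed form;
:func:`stable_composition_exact` solves it by a damped fixed-point iteration
on the single scalar unknown, the free surface fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import CompositionResult, CoronaSystem, check_valid

__all__ = ["TimeScales", "metastable_composition", "stable_composition",
           "stable_composition_exact", "time_scales"]


@dataclass(frozen=True)
class TimeScales:
    """Characteristic times of the two phases.

    ``tau_fast = 1 / sum_j k_a,j c_j0`` is the surface-filling time constant;
    ``tau_slow_lower_bound = 1 / min k_d`` bounds the exchange-phase
    relaxation from below (infinite when no species dissociates).
    """

    tau_fast: float
    tau_slow_lower_bound: float


def metastable_composition(system: CoronaSystem) -> CompositionResult:
    """Composition at the end of the fast phase.

    ``f_bar_i = k_a,i c_i0 / sum_j k_a,j c_j0``; the surface is fully covered
    (theta = 0) and the fractions sum to one exactly.

    Raises
    ------
    ValueError
        If every association flux ``k_a,i c_i0`` vanishes (no species can
        bind, the composition is undefined), or on an invalid panel.
    """
    check_valid(system)
    w = system.k_a * system.c0
    total = w.sum()
    if total <= 0:
        raise ValueError("metastable composition undefined: all k_a * c0 are zero")
    f = w / total
    # compensate round-off on the dominant species so the sum is exactly 1
    f[np.argmax(f)] += 1.0 - f.sum()
    return CompositionResult(system.names, f, system.cap * f, 0.0, "metastable")


def stable_composition(system: CoronaSystem) -> CompositionResult:
    """Equilibrium composition under the protein-excess approximation.

    The competitive Langmuir isotherm:
    ``f_i = K_i c_i0 / (1 + sum_j K_j c_j0)`` and
    ``theta = 1 / (1 + sum_j K_j c_j0)``.

    Raises
    ------
    ValueError
        If any species has ``k_d = 0`` (its equilibrium constant is
        undefined), naming the species.
    """
    check_valid(system)
    _require_all_dissociating(system)
    load = system.K * system.c0
    denom = 1.0 + load.sum()
    f = load / denom
    theta = 1.0 - f.sum()  # exact complement, so sum(f) + theta == 1 identically
    return CompositionResult(system.names, f, system.cap * f, theta, "stable_approx")


def stable_composition_exact(
    system: CoronaSystem,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> CompositionResult:
    """Equilibrium with protein depletion retained.

    Solves, simultaneously for all species,

        k_a,i (c_i0 - x_i) n_i N0 theta = k_d,i x_i,
        theta = 1 - sum_j x_j / (n_j N0).

    For a given theta each balance has the scalar solution
    ``x_i(theta) = n_i N0 K_i c_i0 theta / (1 + n_i N0 K_i theta)``, which is
    increasing in theta, so the problem collapses to one scalar equation —
    the coverage identity

        h(theta) = 1 - theta - sum_i K_i c_i0 theta / (1 + n_i N0 K_i theta) = 0.

    ``h`` is strictly decreasing with ``h(0) = 1 > 0 > h(1)``, so the root is
    unique and bracketed on [0, 1]; it is found with Brent's method to
    machine precision (``tol`` is the relative residual accepted on each
    species balance, checked after the solve).

    Raises
    ------
    ValueError
        If any ``k_d = 0``.
    RuntimeError
        If the bracketed solve fails to meet the residual tolerance within
        ``max_iter`` iterations.
    """
    check_valid(system)
    _require_all_dissociating(system)
    cap, K, c0 = system.cap, system.K, system.c0
    capK = cap * K

    def x_of_theta(theta: float) -> np.ndarray:
        return capK * c0 * theta / (1.0 + capK * theta)

    def coverage_residual(theta: float) -> float:
        return 1.0 - theta - float((x_of_theta(theta) / cap).sum())

    theta = float(brentq(coverage_residual, 0.0, 1.0,
                         xtol=1e-300, rtol=8.9e-16, maxiter=max_iter))
    x = x_of_theta(theta)
    balance = np.abs(system.k_a * (c0 - x) * cap * theta - system.k_d * x)
    scale = np.maximum(system.k_d * x, 1e-300)
    worst = float(np.max(balance / scale))
    if worst > tol * 1e3:  # guard against a degenerate bracket, never triggered in practice
        raise RuntimeError(f"equilibrium solve left relative residual {worst:.3e}")
    f = x / cap
    theta = 1.0 - float(f.sum())
    return CompositionResult(system.names, f, x, theta, "stable_exact")


def time_scales(system: CoronaSystem) -> TimeScales:
    """Fast-phase time constant and the slow-phase lower bound."""
    flux = float((system.k_a * system.c0).sum())
    if flux <= 0:
        raise ValueError("tau_fast undefined: all association fluxes k_a * c0 are zero")
    kd_pos = system.k_d[system.k_d > 0]
    tau_slow = float(np.inf) if kd_pos.size == 0 else 1.0 / float(kd_pos.min())
    return TimeScales(tau_fast=1.0 / flux, tau_slow_lower_bound=tau_slow)


def _require_all_dissociating(system: CoronaSystem) -> None:
    dead = [sp.name for sp in system.species if sp.k_d == 0]
    if dead:
        raise ValueError(
            "equilibrium constant undefined (k_d = 0) for species: " + ", ".join(dead)
        )
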