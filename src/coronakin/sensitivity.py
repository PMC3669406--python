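"""Local sensitivity of corona compositions to kinetic parameters.

Both closed-form compositions share the structure ``f_i = w_i / D`` with
``w_i = k_a,i c_i0`` (metastable, ``D = sum w``) or ``w_i = K_i c_i0``
(stable, ``D = 1 + sum w``), so their relative (logarithmic) sensitivities
take the same own/cross form:

    d ln f_i / d ln p_i = 1 - f_i          (own parameter)
    d ln f_j / d ln p_i = -f_i   (j != i)  (cross)

with ``p`` the per-species ``k_a`` (metastable) or ``K`` (stable).  The
free surface fraction of the stable composition responds with ``-f_i``.
A relative error in a measured rate therefore propagates into the predicted
composition with a gain that depends only on the fraction itself: dominant
species are self-insensitive, rare species are hit hardest by competitors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition_analytics import metastable_composition, stable_composition
from .model_core import CoronaSystem, ProteinSpecies

__all__ = ["SensitivityMatrix", "metastable_sensitivity", "stable_sensitivity", "sweep"]

_SWEEP_PARAMS = ("k_a", "k_d", "K", "c0")


@dataclass(frozen=True)
class SensitivityMatrix:
    """Relative sensitivities S[i, p]: fraction i per parameter-of-species p.

    ``S[i, p] = d ln f_i / d ln param_p``, dimensionless.  ``parameter`` is
    ``"k_a"`` for the metastable target and ``"K"`` for the stable one.
    """

    names: tuple[str, ...]
    S: np.ndarray
    parameter: str
    target_label: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.parameter}[{n}]" for n in self.names]
        return pd.DataFrame(self.S, index=list(self.names), columns=cols)


def _own_cross(f: np.ndarray) -> np.ndarray:
    # S[j, i] = delta_ji - f_i
    m = len(f)
    return np.eye(m) - np.tile(f, (m, 1))


def metastable_sensitivity(system: CoronaSystem) -> SensitivityMatrix:
    """Sensitivity of the metastable fractions to the association rates."""
    comp = metastable_composition(system)
    return SensitivityMatrix(tuple(system.names), _own_cross(comp.f), "k_a", "metastable")


def stable_sensitivity(system: CoronaSystem) -> SensitivityMatrix:
    """Sensitivity of the stable fractions to the equilibrium constants."""
    comp = stable_composition(system)
    return SensitivityMatrix(tuple(system.names), _own_cross(comp.f), "K", "stable")


def _perturbed(system: CoronaSystem, idx: int, parameter: str, mult: float) -> CoronaSystem:
    species = list(system.species)
    sp = species[idx]
    if parameter == "k_a" or parameter == "K":
        # K is swept through k_a at fixed k_d, so K-sweeps and k_a-sweeps
        # coincide; they differ only for the metastable target, which does
        # not involve k_d at all.
        sp = ProteinSpecies(sp.name, sp.k_a * mult, sp.k_d, sp.n, sp.c0)
    elif parameter == "k_d":
        sp = ProteinSpecies(sp.name, sp.k_a, sp.k_d * mult, sp.n, sp.c0)
    elif parameter == "c0":
        sp = ProteinSpecies(sp.name, sp.k_a, sp.k_d, sp.n, sp.c0 * mult)
    else:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {_SWEEP_PARAMS}")
    species[idx] = sp
    return CoronaSystem(species, system.N0)


def _log_sensitivity_column(system: CoronaSystem, idx: int, parameter: str,
                            target: str) -> np.ndarray:
    """Closed-form d ln f_j / d ln param_idx for the chosen target."""
    if target == "metastable":
        f = metastable_composition(system).f
        if parameter in ("k_a", "c0", "K"):  # K is swept through k_a
            return (np.arange(len(f)) == idx).astype(float) - f[idx]
        if parameter == "k_d":
            return np.zeros(len(f))
    elif target == "stable":
        f = stable_composition(system).f
        if parameter in ("k_a", "K", "c0"):
            return (np.arange(len(f)) == idx).astype(float) - f[idx]
        if parameter == "k_d":
            return -((np.arange(len(f)) == idx).astype(float) - f[idx])
    raise ValueError(f"unknown target {target!r}")


def sweep(
    system: CoronaSystem,
    species_name: str,
    parameter: str,
    relative_range: float = 0.5,
    n_points: int = 11,
    target: str = "metastable",
) -> pd.DataFrame:
    """Recompute a closed-form composition over a one-parameter sweep.

    The chosen parameter of one species is scaled by multipliers spanning
    ``[1 - relative_range, 1 + relative_range]``; the table reports the
    recomputed fractions alongside the first-order prediction from the
    analytic sensitivity, ``f_j (1 + S[j] (mult - 1))``.

    Returns
    -------
    DataFrame
        Columns ``multiplier, species, f_recomputed, f_first_order``.
    """
    if not (0 < relative_range <= 1):
        raise ValueError("relative_range must lie in (0, 1]")
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    if parameter not in _SWEEP_PARAMS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {_SWEEP_PARAMS}")
    try:
        idx = system.names.index(species_name)
    except ValueError:
        raise ValueError(f"unknown species {species_name!r}") from None
    compose = metastable_composition if target == "metastable" else stable_composition
    if target not in ("metastable", "stable"):
        raise ValueError(f"unknown target {target!r}")

    f0 = compose(system).f
    S_col = _log_sensitivity_column(system, idx, parameter, target)
    rows = []
    for mult in np.linspace(1.0 - relative_range, 1.0 + relative_range, n_points):
        f_new = compose(_perturbed(system, idx, parameter, mult)).f
        f_lin = f0 * (1.0 + S_col * (mult - 1.0))
        for j, name in enumerate(system.names):
            rows.append((float(mult), name, float(f_new[j]), float(f_lin[j])))
    return pd.DataFrame(rows, columns=["multiplier", "species", "f_recomputed", "f_first_order"])
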