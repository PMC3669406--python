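"""Core domain types for nanoparticle-protein corona kinetics.

The model describes competitive adsorption of ``m`` protein species onto a
population of nanoparticles.  Each species is characterised by an association
rate ``k_a`` (M^-1 s^-1), a dissociation rate ``k_d`` (s^-1), a coverage
number ``n`` (average count of molecules of that species needed to fully
cover one particle), and an initial total concentration ``c0`` (M).  The
nanoparticles are present at concentration ``N0`` (M), so species ``i`` has a
site capacity of ``n_i * N0`` in concentration units.

Units are fixed package-wide: concentrations in molar, time in seconds.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Absolute tolerance on dimensionless surface fractions for state invariants.
FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class ProteinSpecies:
    """Kinetic and coverage parameters of one protein type.

    Parameters
    ----------
    name : str
        Short unique identifier, e.g. ``"HSA"``.
    k_a : float
        Association rate constant, M^-1 s^-1.
    k_d : float
        Dissociation rate constant, s^-1.  ``k_d = 0`` marks irreversibly
        slow unbinding on the time scales of interest; the equilibrium
        constant is then undefined.
    n : float
        Average number of molecules of this species fully covering one
        nanoparticle (dimensionless).
    c0 : float
        Initial total (free + bound) concentration, M.
    """

    name: str
    k_a: float
    k_d: float
    n: float
    c0: float

    @property
    def K(self) -> float:
        """Equilibrium constant k_a / k_d in M^-1; NaN when k_d == 0."""
        if self.k_d > 0:
            return self.k_a / self.k_d
        return math.nan


@dataclass(frozen=True)
class CoronaSystem:
    """A panel of protein species competing for one nanoparticle population.

    Attributes
    ----------
    species : tuple of ProteinSpecies
        Ordered panel, length ``m >= 1``.
    N0 : float
        Nanoparticle concentration, M.
    """

    species: tuple[ProteinSpecies, ...]
    N0: float

    def __init__(self, species: Sequence[ProteinSpecies], N0: float):
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "N0", float(N0))

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[ProteinSpecies]:
        return iter(self.species)

    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def names(self) -> list[str]:
        return [sp.name for sp in self.species]

    @property
    def k_a(self) -> np.ndarray:
        return np.array([sp.k_a for sp in self.species], dtype=float)

    @property
    def k_d(self) -> np.ndarray:
        return np.array([sp.k_d for sp in self.species], dtype=float)

    @property
    def n(self) -> np.ndarray:
        return np.array([sp.n for sp in self.species], dtype=float)

    @property
    def c0(self) -> np.ndarray:
        return np.array([sp.c0 for sp in self.species], dtype=float)

    @property
    def cap(self) -> np.ndarray:
        """Per-species site capacity n_i * N0, M."""
        return self.n * self.N0

    @property
    def K(self) -> np.ndarray:
        """Equilibrium constants k_a/k_d, M^-1 (NaN where k_d == 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(self.k_d > 0, self.k_a / self.k_d, np.nan)
        return K

    def panel_hash(self) -> str:
        """Stable short hash of the full parameterization (for metadata)."""
        payload = repr(
            [(sp.name, sp.k_a, sp.k_d, sp.n, sp.c0) for sp in self.species]
            + [self.N0]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class SystemState:
    """Bound-protein concentrations at one instant.

    ``x[i]`` is the concentration of species ``i`` bound to nanoparticles
    (M).  Surface fractions and the free surface fraction are derived via
    :func:`surface_fractions`.
    """

    x: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))


@dataclass
class Trajectory:
    """Time course of bound concentrations on a fixed output grid.

    Attributes
    ----------
    times : (T,) array
        Strictly increasing output times, s.
    x : (T, m) array
        Bound concentrations, M.
    f : (T, m) array
        Occupied surface fractions x / (n * N0).
    theta : (T,) array
        Free surface fraction 1 - sum_i f_i.
    metadata : dict
        Solver settings, seed (stochastic runs), panel hash, model label.
    """

    times: np.ndarray
    x: np.ndarray
    f: np.ndarray
    theta: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def states(self) -> list[SystemState]:
        return [SystemState(row) for row in self.x]

    def to_frame(self, names: Sequence[str]) -> "pd.DataFrame":  # noqa: F821
        """Tidy long-format table: time_s, species, x_molar, f, theta."""
        import pandas as pd

        T, m = self.x.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, m),
                "species": np.tile(np.asarray(names, dtype=object), T),
                "x_molar": self.x.ravel(),
                "f": self.f.ravel(),
                "theta": np.repeat(self.theta, m),
            }
        )


@dataclass(frozen=True)
class CompositionResult:
    """A static corona composition (per-species surface fractions).

    ``label`` is one of ``metastable`` (end of the fast association phase),
    ``stable_approx`` (competitive-Langmuir closed form, protein excess
    assumed), ``stable_exact`` (equilibrium with depletion retained), or
    ``empirical`` (read off a simulated trajectory).
    """

    names: tuple[str, ...]
    f: np.ndarray
    x: np.ndarray
    theta: float
    label: str

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "theta": float(self.theta),
            "species": list(self.names),
            "f": [float(v) for v in self.f],
            "x_molar": [float(v) for v in self.x],
        }


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding. ``level`` is 'error' or 'warning'."""

    level: str
    message: str

    @property
    def is_error(self) -> bool:
        return self.level == "error"


def validate_system(system: CoronaSystem) -> list[Diagnostic]:
    """Check panel invariants and the protein-excess standing assumption.

    Hard errors: non-positive ``k_a``, ``n`` or ``N0``; negative ``k_d`` or
    ``c0``; duplicate species names; empty panel.  A warning is issued when
    the metastable closed form would demand more bound protein than is
    available for some species (``x_bar_i > c_i0``) — the protein-excess
    assumption behind the fast-phase formula is then violated and the
    empirical fast-phase composition from a full simulation should be
    preferred.
    """
    diags: list[Diagnostic] = []
    if system.m < 1:
        return [Diagnostic("error", "panel is empty (m = 0)")]
    if not system.N0 > 0:
        diags.append(Diagnostic("error", f"N0 must be > 0, got {system.N0!r}"))
    seen: set[str] = set()
    for sp in system.species:
        if sp.name in seen:
            diags.append(Diagnostic("error", f"duplicate species name {sp.name!r}"))
        seen.add(sp.name)
        if not sp.k_a > 0:
            diags.append(
                Diagnostic("error", f"species {sp.name!r}: k_a must be > 0, got {sp.k_a!r}")
            )
        if sp.k_d < 0:
            diags.append(
                Diagnostic("error", f"species {sp.name!r}: k_d must be >= 0, got {sp.k_d!r}")
            )
        if not sp.n > 0:
            diags.append(
                Diagnostic("error", f"species {sp.name!r}: n must be > 0, got {sp.n!r}")
            )
        if sp.c0 < 0:
            diags.append(
                Diagnostic("error", f"species {sp.name!r}: c0 must be >= 0, got {sp.c0!r}")
            )
    if any(d.is_error for d in diags):
        return diags

    # Protein-excess assumption: the metastable formula allocates the whole
    # surface in proportion to k_a*c0; flag species that cannot supply their
    # allocated share.
    w = system.k_a * system.c0
    total = w.sum()
    if total > 0:
        x_bar = system.cap * w / total
        for i, sp in enumerate(system.species):
            if x_bar[i] > sp.c0:
                diags.append(
                    Diagnostic(
                        "warning",
                        f"protein-excess assumption violated for {sp.name!r}: "
                        f"metastable demand {x_bar[i]:.3e} M exceeds c0 = {sp.c0:.3e} M",
                    )
                )
    return diags


def check_valid(system: CoronaSystem) -> None:
    """Raise ``ValueError`` if the panel has any error-level diagnostic."""
    errors = [d for d in validate_system(system) if d.is_error]
    if errors:
        raise ValueError("; ".join(d.message for d in errors))


def surface_fractions(
    state: SystemState | np.ndarray, system: CoronaSystem
) -> tuple[np.ndarray, float]:
    """Occupied surface fractions and the free surface fraction.

    ``f_i = x_i / (n_i N0)`` and ``theta = 1 - sum_i f_i``.

    Raises
    ------
    ValueError
        If the state dimension does not match the panel.
    """
    x = state.x if isinstance(state, SystemState) else np.asarray(state, dtype=float)
    if x.shape[-1] != system.m:
        raise ValueError(f"state has {x.shape[-1]} species, system has {system.m}")
    f = x / system.cap
    theta = 1.0 - f.sum(axis=-1)
    return f, float(theta) if np.ndim(theta) == 0 else theta
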