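"""Seeded synthetic protein panels for tests, demos and sweeps.

Real corona studies draw their kinetic constants from surface-plasmon-
resonance experiments on serum proteins; here panels are sampled
log-uniformly over serum-plausible magnitudes instead, so that everything
in the package runs with zero external data.  The default ranges are
engineering choices tuned to the two-phase regime the model targets
(association flux far faster than dissociation): k_a in [1e3, 1e7] M^-1
s^-1, k_d in [1e-6, 1e-3] s^-1, coverage numbers in [10, 1000], c0 in
[1e-7, 1e-3] M, nanoparticles at 1 nM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition_analytics import metastable_composition
from .model_core import CoronaSystem, ProteinSpecies, validate_system
from .reduced_model import epsilon

__all__ = ["PanelRanges", "generate_panel", "demo_panel", "panel_regime_report"]


@dataclass(frozen=True)
class PanelRanges:
    """Log-uniform sampling bounds for one synthetic panel.

    All bounds are positive with low <= high.  ``max_epsilon`` rejects draws
    whose time-scale separation parameter exceeds the bound, guaranteeing
    generated panels sit in the two-phase regime the model describes; set it
    to ``None`` to disable rejection.
    """

    m: int = 3
    k_a: tuple[float, float] = (1e3, 1e7)
    k_d: tuple[float, float] = (1e-6, 1e-3)
    n: tuple[float, float] = (10.0, 1000.0)
    c0: tuple[float, float] = (1e-7, 1e-3)
    N0: float = 1e-9
    seed: int = 0
    max_epsilon: float | None = 0.01

    def __post_init__(self):
        for name in ("k_a", "k_d", "n", "c0"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} bounds must satisfy 0 < low <= high")
        if self.N0 <= 0 or self.m < 1:
            raise ValueError("N0 must be > 0 and m >= 1")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_panel(ranges: PanelRanges | None = None, **kwargs) -> CoronaSystem:
    """Draw one reproducible panel (same seed, same panel).

    Keyword arguments override :class:`PanelRanges` fields for convenience,
    e.g. ``generate_panel(seed=7, m=5)``.  When ``max_epsilon`` is set,
    draws are rejected (deterministically, from the same stream) until the
    separation parameter is below the bound.
    """
    if ranges is None:
        ranges = PanelRanges(**kwargs)
    elif kwargs:
        raise TypeError("pass either a PanelRanges or keyword overrides, not both")
    rng = np.random.default_rng(ranges.seed)
    for _ in range(10_000):
        k_a = _log_uniform(rng, *ranges.k_a, ranges.m)
        k_d = _log_uniform(rng, *ranges.k_d, ranges.m)
        n = _log_uniform(rng, *ranges.n, ranges.m)
        c0 = _log_uniform(rng, *ranges.c0, ranges.m)
        system = CoronaSystem(
            [ProteinSpecies(f"P{i+1}", k_a[i], k_d[i], n[i], c0[i])
             for i in range(ranges.m)],
            ranges.N0,
        )
        if ranges.max_epsilon is None or epsilon(system) <= ranges.max_epsilon:
            return system
    raise RuntimeError("could not draw a panel satisfying max_epsilon")


def panel_regime_report(system: CoronaSystem) -> dict:
    """Regime flags for one panel: separation parameter and protein excess.

    ``excess_factor`` is the smallest ratio of available protein to the
    metastable demand across species (>= 1 means the protein-excess
    assumption holds with margin).
    """
    comp = metastable_composition(system)
    with np.errstate(divide="ignore"):
        excess = np.where(comp.x > 0, system.c0 / comp.x, np.inf)
    return {
        "epsilon": epsilon(system),
        "excess_factor": float(np.min(excess)),
        "warnings": [d.message for d in validate_system(system) if not d.is_error],
    }


def demo_panel() -> CoronaSystem:
    """Canonical three-species demonstration panel.

    Species A is an albumin-like binder: very abundant (0.6 mM) with a
    moderate association rate, so it dominates the early association flux
    k_a*c0.  Species B is a lipoprotein-like species of intermediate
    abundance and affinity.  Species C is a fibrinogen-like species: scarce
    but with a very slow off-rate, hence the largest equilibrium load K*c0.
    The panel is built so the fast-phase ranking (A > B > C, set by k_a*c0)
    and the equilibrium ranking (C > A > B, set by K*c0) differ — the
    hallmark exchange behaviour in which an abundant fast binder is slowly
    displaced by a rarer, higher-affinity competitor.
    """
    return CoronaSystem(
        [
            ProteinSpecies("A", k_a=1.0e4, k_d=5.0e-4, n=50.0, c0=6.0e-4),
            ProteinSpecies("B", k_a=2.0e5, k_d=4.0e-4, n=30.0, c0=5.0e-6),
            ProteinSpecies("C", k_a=5.0e4, k_d=2.0e-6, n=20.0, c0=3.0e-6),
        ],
        N0=1.0e-9,
    )
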