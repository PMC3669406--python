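import numpy as np
import pytest

from coronakin import CoronaSystem, ProteinSpecies, demo_panel


@pytest.fixture
def demo():
    return demo_panel()


@pytest.fixture
def symmetric_pair():
    """Two species with identical parameters: everything must come out equal."""
    sp = dict(k_a=1e5, k_d=1e-4, n=100.0, c0=1e-5)
    return CoronaSystem(
        [ProteinSpecies("S1", **sp), ProteinSpecies("S2", **sp)], N0=1e-9
    )


@pytest.fixture
def single_species():
    return CoronaSystem(
        [ProteinSpecies("only", k_a=1e5, k_d=1e-4, n=100.0, c0=1e-5)], N0=1e-9
    )


def rescale(system: CoronaSystem, lam: float) -> CoronaSystem:
    """Scale all concentrations by lam and k_a by 1/lam (dimensionless outputs invariant)."""
    return CoronaSystem(
        [
            ProteinSpecies(sp.name, sp.k_a / lam, sp.k_d, sp.n, sp.c0 * lam)
            for sp in system.species
        ],
        system.N0 * lam,
    )


def scale_kd(system: CoronaSystem, fac: float) -> CoronaSystem:
    return CoronaSystem(
        [ProteinSpecies(sp.name, sp.k_a, sp.k_d * fac, sp.n, sp.c0)
         for sp in system.species],
        system.N0,
    )


def scale_ka(system: CoronaSystem, fac: float) -> CoronaSystem:
    return CoronaSystem(
        [ProteinSpecies(sp.name, sp.k_a * fac, sp.k_d, sp.n, sp.c0)
         for sp in system.species],
        system.N0,
    )


def strip_dissociation(system: CoronaSystem) -> CoronaSystem:
    return CoronaSystem(
        [ProteinSpecies(sp.name, sp.k_a, 0.0, sp.n, sp.c0) for sp in system.species],
        system.N0,
    )


def with_protein_excess(system: CoronaSystem, factor: float) -> CoronaSystem:
    """Shrink N0 until every species' supply exceeds its metastable demand
    by at least ``factor`` (fractions are unaffected by N0)."""
    from coronakin import panel_regime_report

    rep = panel_regime_report(system)
    scale = min(1.0, rep["excess_factor"] / factor)
    return CoronaSystem(system.species, system.N0 * scale * 0.999)
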