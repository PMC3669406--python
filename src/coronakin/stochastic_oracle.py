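"""Particle-resolved stochastic simulation of corona formation.

A direct (Gillespie) simulation of the underlying reversible adsorption
events, tracking every nanoparticle individually.  Each particle ``p``
carries a free surface fraction ``theta_p`` in [0, 1]; a binding event of
species ``i`` consumes one free molecule, pushes one bound molecule onto
particle ``p`` and decrements ``theta_p`` by a surface increment with mean
``1/n_i`` (the footprint of one molecule); an unbinding event restores the
increment that molecule originally claimed, so ``theta_p`` stays in [0, 1]
exactly and per-species molecule counts are conserved at every event.

Propensities follow mass action through an explicit volume scale ``V``
(counts = molar concentration x V):

    binding of i onto p :  k_a,i * n_i * free_i / V * theta_p
    unbinding of i from p: k_d,i * bound_{i,p}

so replicate means converge to the mean-field ODE of
:mod:`coronakin.full_dynamics` as the particle number grows.  The footprint
increments are drawn either deterministically (exactly ``1/n_i``) or
uniformly on ``[0, 2/n_i]``; only the mean is physically constrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import CoronaSystem, Trajectory, check_valid

__all__ = ["ParticleEnsemble", "SSAResult", "ssa_simulate", "occupancy_histogram"]


@dataclass
class ParticleEnsemble:
    """State of a finite nanoparticle population.

    Attributes
    ----------
    theta_p : (P,) array
        Free surface fraction of each particle.
    bound : (m, P) int array
        Bound molecule counts per species per particle.
    free : (m,) int array
        Free molecule counts per species.
    volume_scale : float
        V linking counts to concentrations (counts = M * V).
    increments : list of list of list of float
        ``increments[i][p]`` holds the surface increment claimed by each
        bound molecule of species i on particle p (popped on unbinding).
    """

    theta_p: np.ndarray
    bound: np.ndarray
    free: np.ndarray
    volume_scale: float
    increments: list = field(repr=False, default_factory=list)
    seed: int | None = None

    @property
    def n_particles(self) -> int:
        return len(self.theta_p)

    def theta_mean(self) -> float:
        return float(self.theta_p.mean())

    def bound_concentrations(self) -> np.ndarray:
        """Per-species bound concentration, M."""
        return self.bound.sum(axis=1) / self.volume_scale


@dataclass
class SSAResult:
    trajectory: Trajectory
    ensemble: ParticleEnsemble
    n_events: int
    ended_early: bool  # total propensity hit zero before t_max


def ssa_simulate(
    system: CoronaSystem,
    n_particles: int = 500,
    t_max: float = 1.0,
    seed: int = 0,
    sample_times: np.ndarray | None = None,
    volume_scale: float | None = None,
    increment_model: str = "deterministic",
    max_events: int = 50_000_000,
) -> SSAResult:
    """Run one exact-stochastic replicate.

    Parameters
    ----------
    n_particles : int
        Nanoparticles tracked individually (>= 1).
    volume_scale : float, optional
        Counts-per-molar factor V; defaults to ``n_particles / N0`` so the
        simulated particle number represents exactly the nominal
        nanoparticle concentration.  Free molecule counts are
        ``round(c_i0 * V)`` and must be >= 1 per species.
    increment_model : {"deterministic", "uniform"}
        Footprint of one bound molecule: exactly ``1/n_i``, or uniform on
        ``[0, 2/n_i]`` (same mean).
    sample_times : array, optional
        Times at which ensemble means are recorded; defaults to 50 points
        linearly spaced on ``(0, t_max]``.

    Returns
    -------
    SSAResult
        Sampled mean trajectory, final ensemble, event count, and whether
        the run exhausted its event space before ``t_max``.
    """
    check_valid(system)
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if increment_model not in ("deterministic", "uniform"):
        raise ValueError("increment_model must be 'deterministic' or 'uniform'")
    m = system.m
    V = n_particles / system.N0 if volume_scale is None else float(volume_scale)
    free = np.rint(system.c0 * V).astype(np.int64)
    if np.any(free < 1):
        raise ValueError("volume_scale too small: a species has < 1 free molecule")
    total = free.copy()  # per-species conserved totals

    if sample_times is None:
        sample_times = np.linspace(t_max / 50.0, t_max, 50)
    sample_times = np.asarray(sample_times, dtype=float)

    rng = np.random.default_rng(seed)
    theta_p = np.ones(n_particles)
    bound = np.zeros((m, n_particles), dtype=np.int64)
    incs: list[list[list[float]]] = [[[] for _ in range(n_particles)] for _ in range(m)]

    k_a, k_d, n_cov = system.k_a, system.k_d, system.n
    mean_inc = 1.0 / n_cov

    t = 0.0
    n_events = 0
    ended_early = False
    samples = np.zeros((len(sample_times), m))
    next_sample = 0

    while True:
        # exact sum each event: incremental tracking would leave round-off
        # that keeps a fully absorbed ensemble from reaching propensity zero
        sum_theta = float(theta_p.sum())
        w_bind = k_a * n_cov * free / V          # per-species, per unit theta_p
        a_bind = float(w_bind.sum()) * sum_theta
        u_unbind = k_d * bound.sum(axis=1)
        a_unbind = float(u_unbind.sum())
        a0 = a_bind + a_unbind
        if a0 <= 0.0:
            ended_early = True
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / a0)

        # record any sample times passed before the next event fires
        while next_sample < len(sample_times) and sample_times[next_sample] <= t_next:
            samples[next_sample] = bound.sum(axis=1) / V
            next_sample += 1
        if t_next > t_max or ended_early:
            break
        t = t_next

        if rng.random() * a0 < a_bind:
            # binding: pick species by flux weight, particle by free surface
            i = int(np.searchsorted(np.cumsum(w_bind), rng.random() * w_bind.sum()))
            i = min(i, m - 1)
            cum = np.cumsum(theta_p)
            p = int(np.searchsorted(cum, rng.random() * sum_theta))
            p = min(p, n_particles - 1)
            if increment_model == "deterministic":
                inc = mean_inc[i]
            else:
                inc = rng.uniform(0.0, 2.0 * mean_inc[i])
            inc = min(inc, theta_p[p])  # clip so theta_p >= 0
            theta_p[p] -= inc
            free[i] -= 1
            bound[i, p] += 1
            incs[i][p].append(inc)
        else:
            # unbinding: species by dissociation flux, particle by bound count
            i = int(np.searchsorted(np.cumsum(u_unbind), rng.random() * a_unbind))
            i = min(i, m - 1)
            row = bound[i].astype(float)
            cum = np.cumsum(row)
            p = int(np.searchsorted(cum, rng.random() * cum[-1]))
            p = min(p, n_particles - 1)
            # the leaving molecule is a uniform pick among those bound
            j = int(rng.integers(len(incs[i][p])))
            inc = incs[i][p].pop(j)
            theta_p[p] += inc
            free[i] += 1
            bound[i, p] -= 1

        n_events += 1
        if n_events >= max_events:
            raise RuntimeError(f"event count guard tripped at {max_events} events")
        assert free[i] + bound[i].sum() == total[i]

    x = samples
    cap = system.cap
    f = x / cap
    theta = 1.0 - f.sum(axis=1)
    traj = Trajectory(
        times=sample_times,
        x=x,
        f=f,
        theta=theta,
        metadata={
            "model": "ssa",
            "panel_hash": system.panel_hash(),
            "seed": seed,
            "n_particles": n_particles,
            "volume_scale": V,
            "increment_model": increment_model,
        },
    )
    ensemble = ParticleEnsemble(
        theta_p=theta_p, bound=bound, free=free, volume_scale=V,
        increments=incs, seed=seed,
    )
    return SSAResult(trajectory=traj, ensemble=ensemble, n_events=n_events,
                     ended_early=ended_early)


def occupancy_histogram(
    ensemble: ParticleEnsemble, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized distribution of per-particle free surface fractions.

    Returns ``(density, bin_edges)`` as from ``numpy.histogram`` with
    ``density=True``; the distribution's mean is the ensemble free-surface
    expectation used in the mean-field comparison.
    """
    if ensemble.n_particles == 0:
        raise ValueError("empty ensemble")
    return np.histogram(ensemble.theta_p, bins=bins, range=(0.0, 1.0), density=True)
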