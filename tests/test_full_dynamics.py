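import numpy as np
import pytest

from conftest import scale_ka, strip_dissociation, with_protein_excess
from coronakin import (
    CoronaSystem,
    ProteinSpecies,
    SolverSettings,
    metastable_composition,
    ode_rhs,
    simulate,
    stable_composition_exact,
    time_scales,
    two_phase_summary,
)
from coronakin.full_dynamics import default_time_grid, ode_jacobian


class TestRhs:
    def test_empty_surface_pure_association(self, demo):
        np.testing.assert_allclose(
            ode_rhs(np.zeros(demo.m), demo), demo.k_a * demo.c0 * demo.cap
        )

    def test_zero_at_exact_equilibrium(self, demo):
        comp = stable_composition_exact(demo)
        scale = (demo.k_d * comp.x).max()
        assert np.abs(ode_rhs(comp.x, demo)).max() < 1e-10 * scale

    def test_full_coverage_without_dissociation_is_stationary(self):
        s = strip_dissociation(
            CoronaSystem([ProteinSpecies("P", 1e5, 1e-4, 50.0, 1e-5)], 1e-9)
        )
        np.testing.assert_array_equal(ode_rhs(np.array([s.cap[0]]), s), [0.0])

    def test_rejects_non_finite_and_mismatched_input(self, demo):
        with pytest.raises(ValueError):
            ode_rhs(np.array([np.nan] * demo.m), demo)
        with pytest.raises(ValueError):
            ode_rhs(np.zeros(demo.m + 1), demo)

    def test_jacobian_matches_finite_differences(self, demo):
        x = 0.3 * demo.cap
        J = ode_jacobian(x, demo)
        for j in range(demo.m):
            h = demo.cap[j] * 1e-7
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            col = (ode_rhs(xp, demo) - ode_rhs(xm, demo)) / (2 * h)
            np.testing.assert_allclose(J[:, j], col, rtol=1e-6)


class TestSimulate:
    def test_trajectory_respects_conservation_and_coverage(self, demo):
        traj = simulate(demo)
        assert np.all(traj.x <= demo.c0[None, :] + 1e-9 * demo.c0.max())
        assert np.all(traj.f.sum(axis=1) <= 1 + 1e-9)
        assert np.all(traj.theta >= -1e-9)

    def test_single_species_exponential_coverage_limit(self):
        """With k_d = 0 and 1000x protein excess the fraction follows the
        closed form 1 - exp(-k_a c0 t) to better than 1e-3."""
        k_a, n, N0 = 1e5, 100.0, 1e-9
        c0 = 1000.0 * n * N0
        s = CoronaSystem([ProteinSpecies("P", k_a, 0.0, n, c0)], N0)
        t = np.linspace(1e-3, 10.0, 200) / (k_a * c0)
        traj = simulate(s, t_grid=t)
        ref = 1.0 - np.exp(-k_a * c0 * t)
        assert np.abs(traj.f[:, 0] - ref).max() < 1e-3

    def test_monotone_growth_during_association_phase(self, demo):
        tau = time_scales(demo).tau_fast
        traj = simulate(demo, t_grid=np.geomspace(tau / 100, tau / 100 * 2, 50))
        assert np.all(traj.theta >= 0.97)  # still in the fast phase
        assert np.all(np.diff(traj.x, axis=0) >= -1e-18)

    def test_long_time_limit_is_exact_equilibrium(self, demo):
        traj = simulate(demo)  # default grid ends at 100 / min k_d
        assert np.abs(traj.f[-1] - stable_composition_exact(demo).f).max() < 1e-6

    def test_bad_grid_rejected(self, demo):
        with pytest.raises(ValueError):
            simulate(demo, t_grid=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            simulate(demo, t_grid=np.array([-1.0, 0.5]))


class TestTwoPhaseSummary:
    def test_no_slow_phase_without_dissociation(self, demo):
        """With k_d = 0 the composition moves only while the remaining free
        surface fills, so the 99%-coverage and final compositions differ by
        at most the free fraction at the crossing (1%)."""
        s = with_protein_excess(strip_dissociation(demo), 10.0)
        tau = time_scales(s).tau_fast
        traj = simulate(s, t_grid=np.geomspace(tau / 100, 50 * tau, 300))
        summ = two_phase_summary(traj, s)
        assert summ.fast_phase_complete
        np.testing.assert_allclose(summ.stable.f, summ.metastable.f, atol=0.0105)
        # and bound amounts never decrease: nothing unbinds
        assert np.all(np.diff(traj.x, axis=0) >= -1e-18)

    def test_symmetric_panel_gives_equal_fractions(self, symmetric_pair):
        traj = simulate(symmetric_pair)
        summ = two_phase_summary(traj, symmetric_pair)
        assert summ.metastable.f[0] == pytest.approx(summ.metastable.f[1], abs=1e-9)
        assert summ.stable.f[0] == pytest.approx(summ.stable.f[1], abs=1e-9)

    def test_fast_phase_time_matches_exponential_estimate(self, demo):
        summ = two_phase_summary(simulate(demo), demo)
        t_ref = np.log(100.0) * time_scales(demo).tau_fast
        assert summ.fast_phase_complete
        assert t_ref / 10 < summ.t_fast_end < t_ref * 10

    def test_incomplete_fast_phase_reported_not_raised(self, demo):
        tau = time_scales(demo).tau_fast
        traj = simulate(demo, t_grid=np.geomspace(tau / 1000, tau / 100, 20))
        summ = two_phase_summary(traj, demo)
        assert not summ.fast_phase_complete and np.isnan(summ.t_fast_end)


class TestTimeScaleSeparation:
    def test_faster_association_shrinks_only_the_fast_phase(self, demo):
        """Scaling every k_a by 10 divides the time to 99% coverage by ~10
        but leaves the slow-phase relaxation half-life unchanged (<5%)."""
        fast = scale_ka(demo, 10.0)

        t99 = {}
        half_life = {}
        for key, s in (("base", demo), ("fast", fast)):
            t99[key] = two_phase_summary(simulate(s), s).t_fast_end
            # slow-phase half-life of the approach to equilibrium, measured
            # from a start time safely past both fast phases
            eq = stable_composition_exact(s).f
            t_grid = np.geomspace(10.0, 100.0 / s.k_d.min(), 400)
            traj = simulate(s, t_grid=t_grid)
            gap = np.abs(traj.f - eq[None, :]).max(axis=1)
            target = gap[0] / 2
            k = np.nonzero(gap < target)[0][0]
            w = (target - gap[k - 1]) / (gap[k] - gap[k - 1])
            half_life[key] = t_grid[k - 1] + w * (t_grid[k] - t_grid[k - 1])

        assert t99["fast"] == pytest.approx(t99["base"] / 10, rel=0.1)
        assert half_life["fast"] == pytest.approx(half_life["base"], rel=0.05)


def test_default_grid_spans_both_phases(demo):
    ts = time_scales(demo)
    grid = default_time_grid(demo)
    assert grid[0] == pytest.approx(ts.tau_fast / 100)
    assert grid[-1] == pytest.approx(100 * ts.tau_slow_lower_bound)


def test_stiff_flag_controls_integrator(demo):
    tau = time_scales(demo).tau_fast
    grid = np.geomspace(tau / 100, 5 * tau, 50)
    a = simulate(demo, t_grid=grid, settings=SolverSettings(stiff=True))
    b = simulate(demo, t_grid=grid, settings=SolverSettings(stiff=False))
    assert a.metadata["method"] == "BDF" and b.metadata["method"] == "RK45"
    np.testing.assert_allclose(a.f, b.f, atol=1e-7)
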