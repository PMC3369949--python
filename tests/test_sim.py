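"""Unit and property tests for the individual-based simulator."""

import numpy as np
import pytest

from sweepint.params import ParameterError, SimParams
from sweepint.sim import (
    Genome,
    crossover_pattern,
    init_population,
    recombine,
    run_simulation,
    step_generation,
)

from conftest import make_single_locus_state


class TestInit:
    def test_wild_type_start(self):
        params = SimParams(N=100, U=0.01, R=1.0, s=0.05)
        state = init_population(params)
        assert state.N == 100
        assert state.n_segregating == 0
        assert state.registry == {}
        assert state.generation == 0

    def test_seeded_determinism(self):
        params = SimParams(N=50, U=0.1, R=1.0, s=0.05, generations=40, seed=7)
        a, b = run_simulation(params), run_simulation(params)
        assert np.array_equal(a.mean_log_fitness, b.mean_log_fitness)
        assert [m.id for m in a.fixations] == [m.id for m in b.fixations]

    def test_sexual_reproduction_needs_two(self):
        with pytest.raises(ParameterError, match="N"):
            SimParams(N=1, U=0.01, R=1.0, s=0.05)

    @pytest.mark.parametrize(
        "kw,field",
        [
            (dict(U=-1e-3), "U"),
            (dict(R=0.0), "R"),
            (dict(s=-0.1), "s"),
            (dict(s=0.05, s_mean=0.05), "s"),
            (dict(generations=0), "generations"),
        ],
    )
    def test_invalid_params_name_the_field(self, kw, field):
        base = dict(N=10, U=0.01, R=1.0, s=0.05)
        base.update(kw)
        with pytest.raises(ParameterError) as err:
            SimParams(**base)
        assert err.value.field_name == field


class TestRecombine:
    def test_identical_parents_invisible(self, rng):
        g = Genome(np.array([0.1, 0.7, 2.3]), np.array([1, 2, 3]))
        for _ in range(20):
            off = recombine(g, g, R=3.0, rng=rng)
            assert np.array_equal(off.ids, g.ids)

    def test_no_crossover_gives_one_parent(self):
        # R tiny: Poisson(R) is almost surely 0, offspring equals a parent
        rng = np.random.default_rng(1)
        a = Genome(np.array([0.25]), np.array([1]))
        b = Genome(np.array([0.75]), np.array([2]))
        picks = set()
        for _ in range(200):
            off = recombine(a, b, R=1e-12, rng=rng)
            assert off.ids.tolist() in ([1], [2])
            picks.add(off.ids[0])
        assert picks == {1, 2}  # fair coin chooses either parent

    @pytest.mark.parametrize("d", [0.1, 0.5, 5.0])
    def test_haldane_map_function(self, d, rng):
        """Recombinant fraction between loci at distance d -> (1-e^{-2d})/2."""
        n = 40000
        R = max(2 * d, 4.0)
        pos = np.array([1.0, 1.0 + d])
        rec = 0
        for _ in range(n):
            k = rng.poisson(R)
            xo = rng.uniform(0.0, R, size=k)
            pat = crossover_pattern(pos, xo, start=int(rng.integers(0, 2)))
            rec += pat[0] != pat[1]
        expected = (1 - np.exp(-2 * d)) / 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 4 * se


class TestStepGeneration:
    def test_neutral_sampling_variance(self, rng):
        """With equal fitnesses the per-locus change is binomial drift."""
        N, p0, reps = 200, 0.5, 8000
        dps = np.empty(reps)
        for i in range(reps):
            state = make_single_locus_state(N, 1e-12, p0, rng)
            step_generation(state)
            dps[i] = state.registry[0].count / N - p0
        assert abs(dps.mean()) < 4 * dps.std() / np.sqrt(reps)
        var_expected = p0 * (1 - p0) / N
        se_var = var_expected * np.sqrt(2.0 / reps)
        assert abs(dps.var() - var_expected) < 4 * se_var

    def test_selection_response(self, rng):
        """E[dp] = s p(1-p)/(1+s p) for a single multiplicative locus."""
        N, s, p0, reps = 400, 0.1, 0.3, 8000
        tot = 0.0
        for _ in range(reps):
            state = make_single_locus_state(N, s, p0, rng)
            step_generation(state)
            tot += state.registry[0].count / N - p0
        expected = s * p0 * (1 - p0) / (1 + s * p0)
        se = np.sqrt(p0 * (1 - p0) / N / reps)
        assert abs(tot / reps - expected) < 4 * se

    def test_mutation_influx_poisson_mean(self):
        params = SimParams(N=500, U=0.02, R=1.0, s=0.05, generations=400, seed=3)
        out = run_simulation(params, keep_state=True)
        n_arisen = out.final_state.next_id
        lam = params.N * params.U * params.generations
        assert abs(n_arisen - lam) < 4 * np.sqrt(lam)

    def test_registry_consistency_and_no_reappearance(self):
        params = SimParams(N=150, U=0.05, R=2.0, s=0.05, generations=1, seed=11)
        state = init_population(params)
        resolved = []
        for _ in range(250):
            step_generation(state, resolved)
            state.check_consistency()
        assert state.N == 150
        resolved_ids = {m.id for m in resolved}
        live_ids = set(int(i) for i in state.col_ids)
        assert resolved_ids.isdisjoint(live_ids)
        for rec in resolved:
            assert rec.fate in ("fixed", "lost")
            assert (rec.count == state.N) == (rec.fate == "fixed")


class TestRunSimulation:
    def test_no_mutation_no_fixation(self):
        out = run_simulation(SimParams(N=100, U=0.0, R=1.0, s=0.05, generations=200, seed=5))
        assert out.fixations == []

    def test_mean_log_fitness_nondecreasing_in_expectation(self):
        out = run_simulation(SimParams(N=500, U=0.01, R=1.0, s=0.1, generations=800, seed=9))
        # cumulative substitution gains dominate: end above start
        assert out.mean_log_fitness[-1] > out.mean_log_fitness[0]

    def test_moderate_interference_matches_additive_prediction(self):
        """Measured sweep density vs the additive approximation (Z=1.05)."""
        from scipy.optimize import brentq

        from sweepint.observables import rate_summary

        params = SimParams(
            N=2000, U=2e-3, R=1.0, s=0.05, generations=5000, seed=12, burn_in=600
        )
        summ = rate_summary(run_simulation(params))
        Z, sR = 1.05, params.R * params.s
        pred = brentq(
            lambda L: summ.Lambda0 * (1 - 2 * Z * L) * np.exp(-4 * L * sR) - L, 0, 1 / (2 * Z)
        )
        assert summ.n_fixed > 300
        assert abs(summ.Lambda - pred) / pred < 0.15

    def test_trajectories_recorded_and_bounded(self):
        params = SimParams(
            N=100, U=0.02, R=1.0, s=0.1, generations=300, seed=2, record_trajectories=True
        )
        out = run_simulation(params)
        assert out.trajectories
        for counts in out.trajectories.values():
            assert counts.min() >= 0 and counts.max() <= params.N


class TestExponentialEffects:
    def test_interference_biases_fixed_effects_upward(self):
        """With exponential effects, interference filters out weak mutations,
        shifting the distribution of successful effects above its baseline."""
        means = {}
        for label, U in [("weak", 3e-4), ("strong", 8e-3)]:
            params = SimParams(
                N=1000, U=U, R=0.5, s_mean=0.05, generations=4000, seed=61, burn_in=500
            )
            out = run_simulation(params)
            svals = [m.s for m in out.fixations if m.t_fate >= 500]
            assert len(svals) > 30
            means[label] = np.mean(svals)
        # baseline mean of successful effects is 2 s_mean; interference raises it
        assert means["weak"] == pytest.approx(0.1, rel=0.2)
        assert means["strong"] > means["weak"]


class TestScalingCollapse:
    def test_equal_baseline_density_gives_equal_scaled_rate(self):
        """(N, U) and (2N, U/2) at equal Lambda0 yield the same Lambda/Lambda0."""
        from sweepint.observables import rate_summary

        summaries = []
        for N, U, seed in [(1000, 2e-3, 21), (2000, 1e-3, 22)]:
            params = SimParams(N=N, U=U, R=1.0, s=0.05, generations=4000, seed=seed, burn_in=500)
            summaries.append(rate_summary(run_simulation(params)))
        r1, r2 = (s.Lambda / s.Lambda0 for s in summaries)
        # Poisson counting error on each run's substitution count
        se_log = np.sqrt(sum(1.0 / max(s.n_fixed, 1) for s in summaries))
        assert abs(np.log(r1 / r2)) < 3 * se_log
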