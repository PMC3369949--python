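"""Tests for the analytic rate calculators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepint.params import TheoryInputs
from sweepint.theory import (
    ALPHA_POLYGAMY,
    additive_density,
    baseline,
    coalescence_time,
    diffusion_sojourn_stats,
    exp_effects,
    facultative_rescale,
    lambertw_rate,
    pfix_diffusion,
    self_consistent_density,
    weak_selection_pfix,
)


def _inputs(**kw):
    base = dict(N=10000, U=1e-4, R=1.0, s=0.02)
    base.update(kw)
    return TheoryInputs(**base)


class TestPfixDiffusion:
    def test_neutral_limit(self):
        assert pfix_diffusion(1000, 1e-12) == pytest.approx(1e-3, rel=1e-6)

    def test_weak_selection_limit(self):
        assert pfix_diffusion(10**7, 0.001) == pytest.approx(0.002, rel=1e-3)

    def test_direct_evaluation(self):
        expected = (1 - math.exp(-0.1)) / (1 - math.exp(-10))
        assert pfix_diffusion(100, 0.05) == pytest.approx(expected)

    def test_absorbing_markov_chain_oracle(self):
        """Exact WF fixation probabilities from the transition matrix."""
        N, s = 100, 0.05
        # haploid WF with multiplicative selection: i -> Binomial(N, p_sel)
        from scipy.stats import binom

        P = np.zeros((N + 1, N + 1))
        for i in range(N + 1):
            psel = i * (1 + s) / (i * (1 + s) + (N - i))
            P[i] = binom.pmf(np.arange(N + 1), N, psel)
        Q, R_ = P[1:N, 1:N], P[1:N, [0, N]]
        absorb = np.linalg.solve(np.eye(N - 1) - Q, R_)
        exact = absorb[0, 1]  # from one copy, into fixation
        assert pfix_diffusion(N, s) == pytest.approx(exact, rel=0.02)


class TestBaseline:
    def test_no_mutation_no_substitution(self):
        _, Lambda0, v0 = baseline(_inputs(U=0.0))
        assert Lambda0 == 0.0 and v0 == 0.0

    def test_hand_arithmetic(self):
        # 2NUs per genome with p0 = 2s, over R = 1 Morgan
        inp = _inputs(N=10**4, U=1e-4, s=0.02, R=1.0, p0_convention="2s")
        _, Lambda0, _ = baseline(inp)
        assert Lambda0 == pytest.approx(0.04)

    def test_linear_in_N(self):
        inp = _inputs(p0_convention="2s")
        a = baseline(inp)[1]
        b = baseline(inp.replace(N=2 * inp.N))[1]
        assert b == pytest.approx(2 * a)


class TestLambertW:
    def test_no_interference_limit(self):
        assert lambertw_rate(1e-9, 4.0) == pytest.approx(1e-9, rel=1e-6)

    def test_product_log_identity(self):
        # W(e) = 1, so alpha v0 = e gives v = 1/alpha
        alpha = 4.0
        assert lambertw_rate(math.e / alpha, alpha) == pytest.approx(1 / alpha)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(v0=st.floats(1e-6, 50.0), alpha=st.floats(0.1, 10.0))
    def test_matches_damped_fixed_point_iteration(self, v0, alpha):
        v = lambertw_rate(v0, alpha)
        x = min(v0, 1.0 / alpha)
        for _ in range(6000):
            x = 0.9 * x + 0.1 * v0 * math.exp(-alpha * x)
        assert v == pytest.approx(x, abs=1e-12, rel=1e-10)

    def test_logarithmic_growth(self):
        vals = [lambertw_rate(10.0**k, 1.0) for k in (2, 4, 6)]
        # roughly equal increments per decade pair: ln growth
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0], rel=0.25)
        assert vals[2] < 20  # vastly below v0 = 1e6


class TestAdditiveDensity:
    def test_low_density_limit(self):
        assert additive_density(1e-6) == pytest.approx(1e-6, rel=1e-5)

    def test_ceiling_at_half(self):
        assert additive_density(1e15, Z=1.0) == pytest.approx(0.5, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        assert additive_density(lo) <= additive_density(hi) < 0.5

    def test_explicit_solution_solves_implicit_relation(self):
        """Lambda = Lambda0 (1 - 2 Z Lambda), solved numerically, matches the
        closed form at Lambda0 = 0.5."""
        from scipy.optimize import brentq

        for Z in (1.0, 1.05):
            lam = additive_density(0.5, Z=Z)
            lam_num = brentq(lambda L: 0.5 * (1 - 2 * Z * L) - L, 0.0, 0.5)
            assert lam == pytest.approx(lam_num, rel=1e-10)


class TestSelfConsistentDensity:
    def test_reduces_to_additive_when_map_term_negligible(self):
        inp = _inputs(N=10**6, U=1e-6, s=1e-4, R=1.0, Z=1.0)
        res = self_consistent_density(inp)
        assert res.Lambda == pytest.approx(additive_density(res.Lambda0), rel=1e-3)

    @pytest.mark.parametrize("field", ["N", "U", "R", "s"])
    def test_monotone_in_parameters(self, field):
        inp = _inputs()
        lo = self_consistent_density(inp).Lambda
        hi = self_consistent_density(inp.replace(**{field: getattr(inp, field) * 2})).Lambda
        if field == "R":
            # Lambda is per Morgan; the genomic rate Lambda * R must not fall
            assert 2 * hi >= lo * 0.999
        else:
            assert hi >= lo * 0.999

    def test_interference_never_helps(self):
        res = self_consistent_density(_inputs(U=0.05))
        assert res.Lambda <= res.Lambda0
        assert res.p_fix <= res.p0


class TestCoalescenceTime:
    def test_pure_drift(self):
        assert coalescence_time(_inputs(N=200, U=0.0, s=0.05), 0.0) == 200.0

    def test_decreasing_in_sweep_rate(self):
        inp = _inputs(N=10**4, s=0.02)
        ts = [coalescence_time(inp, L) for L in (0.0, 0.01, 0.1, 0.3)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_effective_size_decreases_with_actual_size(self):
        """Holding U, s, R fixed, larger N (more sweeps) means lower T2 over
        the mid range where the sweep term dominates drift but Lambda has not
        yet hit the interference ceiling."""
        t2s = []
        for N in (3 * 10**3, 10**4, 3 * 10**4):
            inp = _inputs(N=N, U=1e-3, s=0.02, R=1.0)
            res = self_consistent_density(inp)
            t2s.append(coalescence_time(inp, res.Lambda, res.sigma2))
        assert t2s[1] < t2s[0] and t2s[2] < t2s[1]


class TestExpEffects:
    def test_interference_term_exactly_twice_fixed_effects(self):
        res = exp_effects(TheoryInputs(N=10**4, U=1e-3, R=1.0, s_mean=0.02))
        ratio = res.diagnostics["interference_term"] / res.diagnostics["fixed_effects_interference_term"]
        assert ratio == 2.0

    def test_no_interference_limit_recovers_baseline_profile(self):
        res = exp_effects(TheoryInputs(N=10**6, U=1e-9, R=1.0, s_mean=0.02))
        profile = res.diagnostics["profile"]
        assert res.s_cutoff_strong < 1e-3 * 0.02  # vanishes relative to s_mean
        assert profile(0.03) == pytest.approx(0.06, rel=1e-3)

    def test_cutoff_scales_with_rate(self):
        lo = exp_effects(TheoryInputs(N=10**4, U=1e-4, R=1.0, s_mean=0.02))
        hi = exp_effects(TheoryInputs(N=10**4, U=1e-2, R=1.0, s_mean=0.02))
        assert hi.s_cutoff_strong > lo.s_cutoff_strong


class TestWeakSelection:
    def test_no_interference_recovers_baseline(self):
        p, flagged = weak_selection_pfix(0.001, _inputs(), Lambda=0.0, s_mean_successful=0.02)
        assert p == pytest.approx(0.002)
        assert not flagged

    def test_monotone_in_s(self):
        ps = [
            weak_selection_pfix(s, _inputs(), Lambda=0.2, s_mean_successful=0.02)[0]
            for s in (0.002, 0.005, 0.01, 0.02)
        ]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_neutral_floor_flagged(self):
        p, flagged = weak_selection_pfix(1e-5, _inputs(), Lambda=0.3, s_mean_successful=0.05)
        assert p == 1.0 / _inputs().N
        assert flagged


class TestFacultativeRescale:
    def test_obligate_sex_identity(self):
        inp = _inputs(U=1e-3)
        assert facultative_rescale(inp, 1.0).Lambda == pytest.approx(
            self_consistent_density(inp).Lambda, rel=1e-12
        )

    def test_rate_falls_as_outcrossing_becomes_rare(self):
        inp = _inputs(U=1e-3)
        lams = [facultative_rescale(inp, psi).Lambda for psi in (1.0, 0.3, 0.1, 0.03)]
        assert all(a >= b for a, b in zip(lams, lams[1:]))

    def test_linked_dominance_condition_shifts(self):
        inp = _inputs()
        d1 = facultative_rescale(inp, 1.0).diagnostics["linked_dominance_condition"]
        d2 = facultative_rescale(inp, 0.1).diagnostics["linked_dominance_condition"]
        assert d2 == pytest.approx(10 * d1)


class TestSojournStats:
    def test_maruyama_symmetry(self):
        stats = diffusion_sojourn_stats(500, 0.02)
        below, above = stats[(0.0, 0.5)], stats[(0.5, 1.0)]
        assert below[0] == pytest.approx(above[0], rel=0.01)
        assert below[1] == pytest.approx(above[1], rel=0.05)

    def test_total_time_decreases_with_selection(self):
        tot = [
            sum(v[0] for v in diffusion_sojourn_stats(200, s).values()) for s in (0.01, 0.05, 0.2)
        ]
        assert tot[0] > tot[1] > tot[2]

    def test_conditioned_wright_fisher_oracle(self):
        """Mean and sd of the sojourn below/above 1/2 vs direct simulation."""
        N, s = 100, 0.05
        rng = np.random.default_rng(3)
        lo, hi = [], []
        while len(lo) < 700:
            i, tl, th = 1, 0, 0
            while 0 < i < N:
                psel = i * (1 + s) / (i * (1 + s) + (N - i))
                if i < N / 2:
                    tl += 1
                else:
                    th += 1
                i = rng.binomial(N, psel)
            if i == N:
                lo.append(tl)
                hi.append(th)
        lo, hi = np.array(lo), np.array(hi)
        stats = diffusion_sojourn_stats(N, s)
        for arr, key in ((lo, (0.0, 0.5)), (hi, (0.5, 1.0))):
            mean, sd = stats[key]
            assert mean == pytest.approx(arr.mean(), abs=4 * arr.std() / math.sqrt(len(arr)))
            assert sd == pytest.approx(arr.std(), rel=0.15)
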