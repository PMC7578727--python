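"""Unit behaviour of the six optimizers and their shared contracts."""

import math

import numpy as np
import pytest

from bigsel.metaheuristics import (
    ALGORITHMS,
    Agent,
    BasConfig,
    CsoConfig,
    FfoConfig,
    IwoConfig,
    LcoConfig,
    NonFiniteFitnessError,
    TlboConfig,
    bas_decay,
    bas_step,
    cso_step,
    ffo_step,
    iwo_seed_count,
    iwo_sigma,
    iwo_step,
    lco_play_match,
    lco_schedule,
    lco_step,
    lco_win_probability,
    minimize,
    smell_concentration,
    tlbo_step,
    tlbo_teaching_factor,
)

sphere = lambda x: float(np.sum(x * x))  # noqa: E731


class TestIwoPrimitives:
    def test_seed_count_boundaries_and_midpoint(self):
        assert iwo_seed_count(0.0, 0.0, 1.0, 1, 5) == 5  # best -> A_max
        assert iwo_seed_count(1.0, 0.0, 1.0, 1, 5) == 1  # worst -> A_min
        assert iwo_seed_count(0.5, 0.0, 1.0, 1, 5) == 3  # midway
        assert iwo_seed_count(0.7, 0.7, 0.7, 1, 5) == 5  # degenerate: all equal

    def test_seed_count_invalid_bounds(self):
        with pytest.raises(ValueError, match="a_min"):
            iwo_seed_count(0.5, 0.0, 1.0, 5, 1)

    def test_sigma_schedule_endpoints_and_midpoint(self):
        assert iwo_sigma(0, 10, 2, 1.0, 0.0) == pytest.approx(1.0)
        assert iwo_sigma(10, 10, 2, 1.0, 0.0) == pytest.approx(0.0)
        assert iwo_sigma(5, 10, 2, 1.0, 0.0) == pytest.approx(0.25)

    def test_step_truncates_to_best_c_max_against_sort_oracle(self):
        """With a_min = a_max = 2 a 3-weed colony spawns 6 offspring; the
        survivors must equal the full-sort top c_max of parents+offspring."""
        rng = np.random.default_rng(0)
        cfg = IwoConfig(pop_init=3, c_max=5, a_min=2, a_max=2, t_max=10)
        positions = [rng.uniform(0, 1, 4) for _ in range(3)]
        pop = [Agent(p, sphere(p)) for p in positions]
        evaluated = []

        def spy(x):
            f = sphere(x)
            evaluated.append(f)
            return f

        out = iwo_step(pop, cfg, t=1, rng=rng, fitness=spy)
        assert len(evaluated) == 6  # 2 seeds per weed
        merged = sorted([a.fitness for a in pop] + evaluated)
        assert [a.fitness for a in out] == merged[: cfg.c_max]

    def test_population_never_exceeds_c_max(self):
        rng = np.random.default_rng(1)
        cfg = IwoConfig(pop_init=4, c_max=6, a_min=1, a_max=4, t_max=5)
        pop = [Agent(x := rng.uniform(0, 1, 3), sphere(x)) for _ in range(4)]
        for t in range(1, 6):
            pop = iwo_step(pop, cfg, t, rng, sphere)
            assert len(pop) <= cfg.c_max


class _StubRng:
    """Minimal deterministic stand-in for Generator in hand-worked examples."""

    def __init__(self, uniform_value=1.0, integers_value=0, normal=None):
        self.uniform_value = uniform_value
        self.integers_value = integers_value
        self.normal_value = normal

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.uniform_value
        return np.full(size, self.uniform_value)

    def integers(self, n):
        return self.integers_value

    def standard_normal(self, d):
        return np.asarray(self.normal_value)

    def normal(self, loc, scale, size=None):
        return np.zeros(size)


class TestTlbo:
    def test_teaching_factor_fixed_mode_is_two(self):
        assert tlbo_teaching_factor(np.random.default_rng(0), "fixed-2") == 2

    def test_teaching_factor_random_boundaries(self):
        assert tlbo_teaching_factor(_StubRng(uniform_value=0.0), "random") == 1
        assert tlbo_teaching_factor(_StubRng(uniform_value=1.0), "random") == 2

    def test_teaching_factor_random_frequencies(self):
        rng = np.random.default_rng(0)
        draws = [tlbo_teaching_factor(rng, "random") for _ in range(10_000)]
        frac_two = np.mean([d == 2 for d in draws])
        assert 0.45 <= frac_two <= 0.55

    def test_hand_worked_teacher_phase(self):
        """1-dim f(x) = x^2, learners {1,2,3}, n_j = 1, T_F = 2: the class
        mean is 2, the teacher sits at 1, Diff_Mean = 1 - 4 = -3; the
        learner at 1 would move to -2 (worse) and must stay."""
        f = lambda x: float(x[0] ** 2)  # noqa: E731
        pop = [Agent(np.array([v]), f(np.array([v]))) for v in (1.0, 2.0, 3.0)]
        cfg = TlboConfig(pop_size=3, generations=1, tf_mode="fixed-2")
        out = tlbo_step(pop, cfg, _StubRng(uniform_value=1.0), f, lo=-10, hi=10)
        # teacher phase: 1 -> -2 rejected; 2 -> -1 accepted; 3 -> 0 accepted
        # learner phase with n = 1 rejects every move (worked by hand)
        assert [a.position[0] for a in out] == [1.0, -1.0, 0.0]

    def test_population_best_never_worsens(self):
        rng = np.random.default_rng(5)
        cfg = TlboConfig(pop_size=6, generations=1)
        pop = [Agent(x := rng.uniform(0, 1, 4), sphere(x)) for _ in range(6)]
        for _ in range(10):
            before = min(a.fitness for a in pop)
            pop = tlbo_step(pop, cfg, rng, sphere)
            assert min(a.fitness for a in pop) <= before

    def test_all_at_optimum_is_stationary(self):
        pop = [Agent(np.zeros(3), 0.0) for _ in range(4)]
        out = tlbo_step(pop, TlboConfig(pop_size=4, generations=1), np.random.default_rng(0), sphere, lo=-1, hi=1)
        assert all(a.fitness == 0.0 for a in out)


class TestLco:
    @pytest.mark.parametrize("a", [2, 4, 6, 8, 10, 12])
    def test_round_robin_schedule_properties(self, a):
        weeks = lco_schedule(a)
        assert len(weeks) == a - 1
        pairs = set()
        for week in weeks:
            seen = set()
            for j, k in week:
                assert j != k
                seen.update((j, k))
                pairs.add(frozenset((j, k)))
            assert seen == set(range(a))  # every team plays once per week
        assert len(pairs) == a * (a - 1) // 2  # every pair meets exactly once

    def test_odd_team_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            lco_schedule(5)

    def test_win_probability_closed_form(self):
        assert lco_win_probability(1.0, 1.0, 0.0) == 0.5
        assert lco_win_probability(1.0, 3.0, 0.0) == pytest.approx(0.75)
        assert lco_win_probability(0.0, 0.0, 0.0) == 0.5  # both at the ideal

    def test_win_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            f_hat = rng.uniform(-1, 0)
            fj, fk = rng.uniform(0, 5, 2)
            cj = lco_win_probability(fj, fk, f_hat)
            ck = lco_win_probability(fk, fj, f_hat)
            assert cj + ck == pytest.approx(1.0)
            assert 0.0 <= cj <= 1.0

    def test_empirical_win_rate_matches_formula(self):
        """Monte-Carlo over 10^4 matches: observed win frequency of the
        stronger team is within 2% of the closed form."""
        rng = np.random.default_rng(7)
        wins = sum(lco_play_match(1.0, 3.0, 0.0, rng) for _ in range(10_000))
        assert abs(wins / 10_000 - 0.75) < 0.02

    def test_identical_teams_win_half(self):
        rng = np.random.default_rng(8)
        wins = sum(lco_play_match(2.0, 2.0, 0.0, rng) for _ in range(10_000))
        assert abs(wins / 10_000 - 0.5) < 0.02

    def test_best_fitness_non_increasing_over_season(self):
        rng = np.random.default_rng(3)
        cfg = LcoConfig(teams=4, seasons=1)
        positions = [rng.uniform(0, 1, 3) for _ in range(4)]
        teams = [Agent(p, sphere(p)) for p in positions]
        best = min(a.fitness for a in teams)
        for week in lco_schedule(4):
            teams = lco_step(teams, week, cfg, rng, sphere)
            now = min(a.fitness for a in teams)
            assert now <= best
            best = now


class TestBas:
    def test_decay_formulas(self):
        s, d = bas_decay(1.0, 1.0, 0.95, 0.9)
        assert s == pytest.approx(0.96)
        _, d2 = bas_decay(s, d, 0.95, 0.9)
        assert d2 == pytest.approx(0.81)

    def test_decay_fixed_point(self):
        c1 = 0.9
        target = 0.01 / (1 - c1)
        s = 5.0
        for _ in range(500):
            s, _ = bas_decay(s, 1.0, c1, 0.5)
        assert s == pytest.approx(target, rel=1e-9)

    def test_equal_antenna_fitness_freezes_position(self):
        const = lambda x: 1.0  # noqa: E731
        beetle = Agent(np.array([0.5, 0.5]), 1.0)
        cfg = BasConfig()
        out, _ = bas_step(beetle, (0.1, 0.2), const, cfg, np.random.default_rng(0))
        assert np.array_equal(out.position, beetle.position)

    def test_moves_toward_better_antenna(self):
        """1-dim f(x) = (x-2)^2 from z = 0 with q = +1, s = 1: the right
        antenna is better, so the default convention moves by +delta."""
        f = lambda x: float((x[0] - 2.0) ** 2)  # noqa: E731
        beetle = Agent(np.array([0.0]), f(np.array([0.0])))
        cfg = BasConfig(m_dir=-1)
        rng = _StubRng(normal=[1.0])
        out, _ = bas_step(beetle, (1.0, 0.25), f, cfg, rng, lo=-5, hi=5)
        assert out.position[0] == pytest.approx(0.25)

    def test_step_magnitude_is_exactly_delta(self):
        f = lambda x: float(x[0])  # noqa: E731
        beetle = Agent(np.array([0.5]), 0.5)
        out, _ = bas_step(beetle, (0.1, 0.07), f, BasConfig(), _StubRng(normal=[1.0]), lo=0, hi=1)
        assert abs(out.position[0] - 0.5) == pytest.approx(0.07)

    def test_antenna_symmetry_about_position(self):
        rng = np.random.default_rng(4)
        z = rng.uniform(0, 1, 6)
        s = 0.3
        probes = []
        f = lambda x: probes.append(x.copy()) or 0.0  # noqa: E731
        bas_step(Agent(z, 0.0), (s, 0.1), lambda x: 0.0, BasConfig(), rng, probe=f)
        z_r, z_l = probes
        assert np.allclose(z_r - z, -(z_l - z))
        assert np.linalg.norm(z_r - z) == pytest.approx(s)


class TestCso:
    def test_pursuit_arithmetic(self):
        """Y = 0, L_k = 1, r = 0.5, fl = 2 -> new position 1."""
        crows = [Agent(np.array([0.0]), 0.0), Agent(np.array([0.5]), 0.25)]
        memories = [Agent(np.array([0.0]), 0.0), Agent(np.array([1.0]), 1.0)]
        cfg = CsoConfig(flock_size=2, ap=0.1, fl=2.0)
        rng = _StubRng(uniform_value=0.5, integers_value=0)
        out, _ = cso_step(crows, memories, cfg, rng, sphere, lo=-2, hi=2)
        assert out[0].position[0] == pytest.approx(1.0)

    def test_ap_one_forces_evasion(self):
        """With AP = 1 every draw r < 1 triggers evasion; with fl = 0 a
        pursuit would leave positions unchanged, so any movement proves
        the evasion branch ran."""
        rng = np.random.default_rng(0)
        crows = [Agent(np.array([0.5]), 0.25), Agent(np.array([0.5]), 0.25)]
        memories = [a.copy() for a in crows]
        cfg = CsoConfig(flock_size=2, ap=1.0, fl=0.0)
        out, _ = cso_step(crows, memories, cfg, rng, sphere)
        assert any(a.position[0] != 0.5 for a in out)

    def test_memory_fitness_non_increasing(self):
        rng = np.random.default_rng(6)
        crows = [Agent(x := rng.uniform(0, 1, 3), sphere(x)) for _ in range(4)]
        crows = [Agent(a.position, sphere(a.position)) for a in crows]
        memories = [a.copy() for a in crows]
        cfg = CsoConfig(flock_size=4)
        prev = [m.fitness for m in memories]
        for _ in range(20):
            crows, memories = cso_step(crows, memories, cfg, rng, sphere)
            now = [m.fitness for m in memories]
            assert all(b <= a for a, b in zip(prev, now))
            prev = now


class TestFfo:
    def test_smell_concentration_reciprocal_distance(self):
        assert smell_concentration(np.array([2.0, 0.0])) == pytest.approx(0.5)
        assert smell_concentration(np.array([1e9, 0.0])) == pytest.approx(0.0, abs=1e-8)
        assert math.isfinite(smell_concentration(np.zeros(3)))

    def test_zero_radius_freezes_center(self):
        cfg = FfoConfig(swarm_size=5, scatter_radius=0.0)
        center = np.array([0.4, 0.6])
        rng = np.random.default_rng(0)
        new_center, best, sc = ffo_step(center, cfg, sphere, rng, radius=0.0, best_fitness=sphere(center))
        assert np.array_equal(new_center, center)
        assert np.allclose(best.position, center)

    def test_center_moves_only_on_improvement(self):
        cfg = FfoConfig(swarm_size=8, scatter_radius=0.2)
        rng = np.random.default_rng(1)
        center = np.array([0.5, 0.5])
        new_center, best, _ = ffo_step(center, cfg, sphere, rng, best_fitness=0.0)
        assert np.array_equal(new_center, center)  # historical best unbeatable


class TestMinimizeContracts:
    @pytest.mark.parametrize("alg", sorted(ALGORITHMS))
    def test_constant_fitness_flat_trace(self, alg):
        run = minimize(alg, lambda x: 3.25, 3, seed=0, max_evals=400)
        assert run.best_fitness == 3.25
        assert all(v == 3.25 for v in run.trace)

    @pytest.mark.parametrize("alg", sorted(ALGORITHMS))
    def test_same_seed_identical_runs(self, alg):
        a = minimize(alg, sphere, 4, seed=123, max_evals=600)
        b = minimize(alg, sphere, 4, seed=123, max_evals=600)
        assert a.trace == b.trace
        assert np.array_equal(a.best_position, b.best_position)
        assert a.evaluations == b.evaluations

    @pytest.mark.parametrize("alg", sorted(ALGORITHMS))
    def test_trace_non_increasing_and_positions_in_bounds(self, alg):
        run = minimize(alg, sphere, 4, seed=5, max_evals=800)
        assert all(b <= a for a, b in zip(run.trace, run.trace[1:]))
        assert run.best_fitness == run.trace[-1]
        assert np.all(run.best_position >= 0.0) and np.all(run.best_position <= 1.0)

    def test_budget_cap_respected(self):
        run = minimize("tlbo", sphere, 3, seed=0, max_evals=100)
        assert run.evaluations <= 100

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            minimize("annealing", sphere, 3)

    def test_non_finite_fitness_names_position(self):
        with pytest.raises(NonFiniteFitnessError, match="position"):
            minimize("iwo", lambda x: float("nan"), 2, seed=0)
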