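"""Correlation fitness, synthetic targets and the PSO-SA optimizer."""

import io

import numpy as np
import pytest

from somiteclock import (
    FitnessSpec,
    OptimizerConfig,
    SimulationConfig,
    build_notch_model,
    fitness,
    generate_target_profiles,
    pearson_corr,
    pso_sa_optimize,
)
from somiteclock.calibration import (
    ExpressionProfile,
    profiles_from_csv,
    profiles_to_csv,
)


class TestPearsonCorr:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 0, 1, 0), (1, 1, 0, 0), 0.0),
        ],
    )
    def test_values(self, x, y, expected):
        assert pearson_corr(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 2], [1, 2, 3])

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(20), rng.random(20)
        assert pearson_corr(x, 3.7 * y + 11.0) == pytest.approx(
            pearson_corr(x, y), abs=1e-12)


class TestGenerateTargets:
    def test_antiphase_gene_perfectly_anticorrelated(self):
        profiles = generate_target_profiles(
            {"A": "in_phase", "B": "antiphase"}, noise_sd=0.0, seed=1)
        a, b = profiles
        assert pearson_corr(a.values, b.values) == pytest.approx(-1.0, abs=1e-12)

    def test_noiseless_profile_has_requested_period(self):
        (p,) = generate_target_profiles(
            {"A": "in_phase"}, period=120.0, n_points=241, span=480.0,
            noise_sd=0.0)
        # autocorrelation at one period equals 1 for an exact sinusoid
        n = len(p.times)
        shift = 60  # 120 min at dt=2
        c = pearson_corr(p.values[: n - shift], p.values[shift:])
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_under_seed(self):
        a = generate_target_profiles(noise_sd=0.2, seed=42)
        b = generate_target_profiles(noise_sd=0.2, seed=42)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.values, pb.values)

    def test_csv_round_trip(self):
        profiles = generate_target_profiles(noise_sd=0.1, seed=7)
        buf = io.StringIO()
        profiles_to_csv(profiles, buf)
        buf.seek(0)
        back = profiles_from_csv(buf)
        assert [p.gene for p in back] == [p.gene for p in profiles]
        for pa, pb in zip(profiles, back):
            assert np.allclose(pa.values, pb.values, rtol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_target_profiles(n_points=4)


class TestFitness:
    def test_self_consistency_near_zero(self, notch_model):
        """Targets sampled from the model itself score S ~ 0."""
        from somiteclock import integrate

        traj = integrate(notch_model, SimulationConfig(t_end=240.0))
        profiles = []
        for gene, sp in notch_model.readouts.items():
            times = np.linspace(0, 240, 13)
            vals = np.interp(times, traj.times, traj[sp])
            profiles.append(ExpressionProfile(gene, times, vals, "simulated"))
        spec = FitnessSpec(profiles, notch_model.readouts)
        s = fitness(notch_model, None, spec)
        assert s < 0.05

    def test_anticorrelated_targets_near_worst(self, notch_model):
        from somiteclock import integrate

        traj = integrate(notch_model, SimulationConfig(t_end=240.0))
        profiles = []
        for gene, sp in notch_model.readouts.items():
            times = np.linspace(0, 240, 13)
            vals = np.interp(times, traj.times, traj[sp])
            profiles.append(
                ExpressionProfile(gene, times, vals.max() - vals, "simulated"))
        spec = FitnessSpec(profiles, notch_model.readouts)
        n = spec.n_genes
        assert fitness(notch_model, None, spec) > 1.9 * n

    def test_dead_model_maps_to_worst_score(self, notch_model):
        profiles = generate_target_profiles(
            {"Lfng": "in_phase", "Hes7": "in_phase"}, seed=0)
        spec = FitnessSpec(profiles, notch_model.readouts)
        dead = dict(notch_model.parameters.values)
        dead["V_tx_hes7"] = 0.0  # no pacemaker, no oscillation
        s = fitness(build_notch_model(dead), None, spec)
        assert s == pytest.approx(2.0 * spec.n_genes)


def sphere(p):
    return sum(v * v for v in p.values())


class TestPsoSa:
    def test_sphere_optimum_recovered(self):
        cfg = OptimizerConfig(
            swarm_size=25, iterations=79,  # 25 * 80 = 2000 evaluations
            bounds={f"p{i}": (-5.0, 5.0) for i in range(5)}, seed=3)
        res = pso_sa_optimize(sphere, cfg)
        assert res.n_evaluations <= 2000
        assert res.best_score < 1e-2

    def test_identical_seeds_bitwise_identical(self):
        cfg = OptimizerConfig(swarm_size=10, iterations=30,
                              bounds={"a": (0.0, 2.0), "b": (0.0, 2.0)}, seed=9)
        r1 = pso_sa_optimize(sphere, cfg)
        r2 = pso_sa_optimize(sphere, cfg)
        assert np.array_equal(r1.trace, r2.trace)
        assert r1.best_params == r2.best_params

    def test_published_best_monotone_in_zero_temperature_limit(self):
        """At T = 0 the acceptance is greedy, so the accepted global best
        never rises (the T -> 0 contract of the annealed acceptance)."""
        cfg = OptimizerConfig(swarm_size=12, iterations=60,
                              initial_temperature=0.0, cooling=0.8,
                              bounds={"a": (0.0, 3.0), "b": (0.0, 3.0)}, seed=5)
        res = pso_sa_optimize(sphere, cfg)
        assert np.all(np.diff(res.trace) <= 1e-15)

    def test_zero_iteration_budget_returns_initial_best(self):
        cfg = OptimizerConfig(swarm_size=8, iterations=0,
                              bounds={"a": (0.0, 1.0)}, seed=1)
        res = pso_sa_optimize(sphere, cfg)
        assert not res.converged
        assert res.n_evaluations == 8

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValueError):
            pso_sa_optimize(sphere, OptimizerConfig(bounds={}))

    def test_multimodal_two_well_mostly_reaches_global_well(self):
        """Deceptive two-well: broad basin at x=4, narrow global well at x=1.

        f(x) = 0.2|x-4| + 0.5 - 2 exp(-30 (x-1)^2); global minimum -0.9 at
        x=1, broad-basin floor 0.5.  A score below -0.5 means the narrow
        well was found.
        """

        def two_well(p):
            x = p["x"]
            return 0.2 * abs(x - 4.0) + 0.5 - 2.0 * np.exp(-30 * (x - 1.0) ** 2)

        hits = 0
        for seed in range(20):
            cfg = OptimizerConfig(
                swarm_size=25, iterations=100, initial_temperature=1.0,
                cooling=0.92, bounds={"x": (0.0, 6.0)}, seed=seed)
            if pso_sa_optimize(two_well, cfg).best_score < -0.5:
                hits += 1
        assert hits >= 17

    def test_high_temperature_accepts_worse_bests(self):
        """The SA embedding is live: at a high, slowly-cooled temperature the
        accepted global best rises transiently for some seed, which never
        happens at T0 = 0."""

        def rastrigin1d(p):
            x = p["x"]
            return x * x + 2.0 - 2.0 * np.cos(3 * np.pi * x)

        def any_rise(t0):
            for seed in range(10):
                cfg = OptimizerConfig(
                    swarm_size=8, iterations=40, initial_temperature=t0,
                    cooling=0.999, bounds={"x": (0.0, 4.0)}, seed=seed)
                res = pso_sa_optimize(rastrigin1d, cfg)
                if np.any(np.diff(res.trace) > 1e-12):
                    return True
            return False

        assert any_rise(50.0)
        assert not any_rise(0.0)
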