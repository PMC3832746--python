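import numpy as np
import pytest

from gmaid.estimation import (
    ParameterBounds,
    feasibility_restore,
    fit_parameters,
    multistart_fit,
    parse_parameter_id,
    profile_parameter,
    simulate_then_seed,
)
from gmaid.network import PowerLawParameters
from gmaid.reference import generate_experiment, generate_replicates
from gmaid.signs import SignAssignment


class TestFitParameters:
    def test_noise_free_parameter_recovery(self, ref, truth_signs, default_mesh, noise_free_exp):
        # the classical fixed-structure problem: every rate constant within
        # 0.5% and every kinetic order within 0.01 of the generating values
        net, params = ref
        fit = fit_parameters(net, [noise_free_exp], truth_signs, mesh=default_mesh)
        assert fit.rss < 1.45e-6
        np.testing.assert_allclose(fit.params.gamma, params.gamma, rtol=5e-3)
        assert np.max(np.abs(fit.params.f - params.f)) < 0.01

    def test_fit_from_truth_is_a_no_op(self, ref, truth_signs, default_mesh, noise_free_exp):
        net, params = ref
        fit = fit_parameters(
            net, [noise_free_exp], truth_signs, mesh=default_mesh, init=params
        )
        assert fit.rss < 1e-6
        np.testing.assert_allclose(fit.params.gamma, params.gamma, rtol=1e-3)

    def test_sign_zero_entries_stay_zero(self, ref, default_mesh, noise_free_exp):
        net, params = ref
        base = SignAssignment.baseline(net)
        fit = fit_parameters(net, [noise_free_exp], base, mesh=default_mesh)
        assert fit.params.f[0, 2] == 0.0
        assert fit.params.f[4, 3] == 0.0
        # dropping both true regulators must cost fit quality
        assert fit.rss > 1e-3

    def test_bounds_respected(self, ref, truth_signs, default_mesh, noise_free_exp):
        net, _ = ref
        tight = ParameterBounds(gamma_hi=5.0)
        fit = fit_parameters(
            net, [noise_free_exp], truth_signs, bounds=tight, mesh=default_mesh
        )
        assert np.all(fit.params.gamma <= 5.0 + 1e-12)

    def test_widening_bounds_never_hurts(self, ref, truth_signs, default_mesh, noise_free_exp):
        net, _ = ref
        narrow = fit_parameters(
            net, [noise_free_exp], truth_signs,
            bounds=ParameterBounds(gamma_hi=5.0), mesh=default_mesh,
        )
        wide = fit_parameters(
            net, [noise_free_exp], truth_signs,
            bounds=ParameterBounds(gamma_hi=50.0), mesh=default_mesh,
            init=narrow.params,
        )
        assert wide.rss <= narrow.rss + 1e-12


class TestMultistart:
    def test_single_start_reduces_to_plain_fit(self, toy):
        net, truth, exp, mesh = toy
        signs = SignAssignment.from_parameters(net, truth)
        a = fit_parameters(net, [exp], signs, mesh=mesh)
        b = multistart_fit(net, [exp], signs, mesh=mesh, n_starts=1, seed=0)
        assert a.rss == pytest.approx(b.rss, rel=1e-12)

    def test_same_seed_reproduces_result(self, toy):
        net, truth, exp, mesh = toy
        signs = SignAssignment.from_parameters(net, truth)
        a = multistart_fit(net, [exp], signs, mesh=mesh, n_starts=4, seed=9)
        b = multistart_fit(net, [exp], signs, mesh=mesh, n_starts=4, seed=9)
        assert a.rss == b.rss
        np.testing.assert_array_equal(a.params.gamma, b.params.gamma)
        np.testing.assert_array_equal(a.params.f, b.params.f)

    def test_run_log_is_kept(self, toy):
        net, truth, exp, mesh = toy
        signs = SignAssignment.from_parameters(net, truth)
        fit = multistart_fit(net, [exp], signs, mesh=mesh, n_starts=3, seed=2)
        assert fit.n_starts_used == 3
        assert len(fit.start_log) == 3


class TestProfile:
    def test_target_fixed_at_optimum_matches_unconstrained(self, toy):
        net, truth, exp, mesh = toy
        signs = SignAssignment.from_parameters(net, truth)
        free = fit_parameters(net, [exp], signs, mesh=mesh)
        val = free.params.f[0, 1]
        fixed = profile_parameter(
            net, [exp], signs, ("f", 0, 1), [val], mesh=mesh
        )[0]
        assert fixed.rss == pytest.approx(free.rss, rel=1e-4, abs=1e-10)

    def test_parameter_id_parsing(self):
        assert parse_parameter_id("f32") == ("f", 2, 1)
        assert parse_parameter_id("gamma3") == ("gamma", 2)
        assert parse_parameter_id(("f", 0, 2)) == ("f", 0, 2)
        with pytest.raises(ValueError):
            parse_parameter_id("q7")

    def test_sweep_reveals_compensation(self, ref, truth_signs, default_mesh, noise_free_exp):
        # fixing f32 off its true value degrades the fit smoothly, while the
        # refitted parameters absorb most of the perturbation
        net, params = ref
        res = profile_parameter(
            net, [noise_free_exp], truth_signs, "f32", [0.70, 0.75, 0.80],
            mesh=default_mesh,
        )
        rss = [r.rss for r in res]
        assert rss[1] < 1e-6  # true value reproduces the data
        assert rss[0] > rss[1] and rss[2] > rss[1]
        assert max(rss) < 5e-3  # compensation keeps residuals small


class TestInitializationStrategies:
    def test_feasibility_restore_zero_slack_at_truth(self, ref, truth_signs, default_mesh, noise_free_exp):
        net, params = ref
        res = feasibility_restore(
            net, [noise_free_exp], truth_signs, mesh=default_mesh, init=params
        )
        assert res.feasible
        assert res.max_slack < 1e-6

    def test_feasibility_restore_from_default_guess(self, ref, truth_signs, default_mesh, noise_free_exp):
        net, _ = ref
        res = feasibility_restore(
            net, [noise_free_exp], truth_signs, mesh=default_mesh
        )
        assert res.feasible and res.max_slack < 1e-6

    def test_contradictory_bounds_reported_not_raised(self, ref, truth_signs, default_mesh, noise_free_exp):
        # substrate lower bound above the global upper bound leaves an empty
        # interval: an infeasibility report, not a crash
        net, _ = ref
        bad = ParameterBounds(f_hi=0.4, substrate_f_lo=0.5)
        res = feasibility_restore(
            net, [noise_free_exp], truth_signs, mesh=default_mesh, bounds=bad
        )
        assert not res.feasible
        assert "f[" in res.message

    def test_simulate_then_seed_matches_ode(self, ref, truth_signs, default_mesh, noise_free_exp):
        from gmaid.network import simulate

        net, params = ref
        _, states_list = simulate_then_seed(
            net, truth_signs, params, default_mesh, [noise_free_exp]
        )
        states = states_list[0]
        # spot-check a handful of collocation nodes against the integrator
        mesh = default_mesh
        for e in (0, 7, 19):
            t = mesh.element_boundaries[e] + mesh.colloc_roots[-1] * mesh.element_lengths[e]
            truth = simulate(net, params, noise_free_exp.x0, np.array([1e-12, t])).states[-1]
            np.testing.assert_allclose(states[e, -1], truth, rtol=1e-6)

    def test_seeding_is_deterministic(self, ref, truth_signs, default_mesh, noise_free_exp):
        net, params = ref
        _, a = simulate_then_seed(net, truth_signs, params, default_mesh, [noise_free_exp])
        _, b = simulate_then_seed(net, truth_signs, params, default_mesh, [noise_free_exp])
        np.testing.assert_array_equal(a[0], b[0])


class TestMultiExperimentPrecision:
    def test_three_experiments_tighten_estimates(self, ref, truth_signs):
        # fitting the three X3-perturbation series jointly yields estimates
        # with smaller spread across noise replicates than single-series fits
        net, params = ref
        n_rep, sd = 8, 0.10
        # spreads are compared across noise realizations, so per-fit
        # terminal precision can be relaxed well below the noise scale
        opts = dict(ftol=1e-9, xtol=1e-9, gtol=1e-8, max_nfev=400, x_scale=1.0)
        single_f54, triple_f54 = [], []
        for rep in range(n_rep):
            exp_mid = generate_experiment(
                x3_init=1.2, noise_sd_fraction=sd, seed=100 + rep
            )
            fit1 = fit_parameters(net, [exp_mid], truth_signs, **opts)
            single_f54.append(fit1.params.f[4, 3])
            exps = [
                generate_experiment(
                    x3_init=x3, noise_sd_fraction=sd, seed=1000 + 10 * rep + i
                )
                for i, x3 in enumerate((0.2, 1.2, 2.2))
            ]
            fit3 = fit_parameters(net, exps, truth_signs, **opts)
            triple_f54.append(fit3.params.f[4, 3])
        assert np.std(triple_f54) < np.std(single_f54)
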