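import numpy as np
import pytest
from scipy.special import roots_jacobi

from gmaid.collocation import (
    collocation_integrate,
    legendre_points,
    make_mesh,
    radau_points,
    reconstruct_trajectory,
    transcribe,
)
from gmaid.network import simulate


class TestPoints:
    def test_one_point_radau_is_implicit_euler(self):
        np.testing.assert_allclose(radau_points(1), [1.0], atol=1e-14)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_radau_matches_jacobi_oracle(self, n):
        # interior right-Radau points are the (shifted) roots of the Jacobi
        # polynomial P_{n-1}^{(1,0)}; the right endpoint completes the set
        x, _ = roots_jacobi(n - 1, 1, 0)
        expected = np.sort(np.append((x + 1) / 2, 1.0))
        np.testing.assert_allclose(radau_points(n), expected, atol=1e-10)

    def test_radau_three_point_values(self):
        np.testing.assert_allclose(
            radau_points(3), [0.155051, 0.644949, 1.0], atol=1e-6
        )

    def test_legendre_excludes_endpoint(self):
        pts = legendre_points(3)
        assert pts[-1] < 1.0 and pts[0] > 0.0

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_mesh(0, 1, 5, 3, scheme="chebyshev")


class TestMesh:
    def test_diff_matrix_exact_on_quadratic(self):
        # d/dtau tau^2 = 2 tau must be reproduced exactly at the collocation
        # points (the basis spans all polynomials of degree <= K)
        mesh = make_mesh(0, 1, 1, 3, grading=1.0)
        nodes = mesh.nodes
        vals = nodes**2
        deriv = mesh.diff_matrix @ vals
        np.testing.assert_allclose(deriv, 2 * mesh.colloc_roots, atol=1e-12)

    @pytest.mark.parametrize("degree", [0, 1, 2, 3, 4])
    def test_diff_matrix_exact_on_low_degree_polynomials(self, degree):
        mesh = make_mesh(0, 1, 1, 4, grading=1.0)
        coeffs = np.arange(1.0, degree + 2.0)
        poly = np.polynomial.Polynomial(coeffs)
        deriv = poly.deriv()
        np.testing.assert_allclose(
            mesh.diff_matrix @ poly(mesh.nodes),
            deriv(mesh.colloc_roots),
            atol=1e-11,
        )

    def test_boundaries_span_horizon(self):
        mesh = make_mesh(1.0, 4.0, 6, 3)
        assert mesh.element_boundaries[0] == 1.0
        assert mesh.element_boundaries[-1] == 4.0
        assert np.all(np.diff(mesh.element_boundaries) > 0)

    def test_grading_shrinks_early_elements(self):
        mesh = make_mesh(0, 10, 10, 3, grading=1.3)
        lengths = mesh.element_lengths
        assert lengths[0] < lengths[-1]
        assert np.allclose(np.diff(np.log(lengths)), np.log(1.3))

    def test_every_sampling_time_locates_in_one_element(self, default_mesh):
        for t in np.linspace(0, 10, 20):
            e, tau = default_mesh.locate(float(t))
            assert 0 <= e < default_mesh.n_elements
            assert -1e-9 <= tau <= 1 + 1e-9

    def test_locate_outside_horizon_raises(self, default_mesh):
        with pytest.raises(ValueError):
            default_mesh.locate(11.0)


class TestIntegrate:
    def test_decay_closed_form(self, decay):
        net, params = decay
        mesh = make_mesh(0, 1, 10, 3, grading=1.0)
        states, _ = collocation_integrate(net, params, np.array([1.0]), mesh)
        assert states[-1, -1, 0] == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_agrees_with_adaptive_integrator(self, ref, default_mesh):
        # the transcription must reproduce the ODE solution to < 1e-4
        # relative at the sampling times, for every X3 perturbation
        net, params = ref
        times = np.linspace(0, 10, 20)
        for x3 in (0.2, 1.2, 2.2):
            x0 = np.array([0.5, 0.5, x3, 0.5])
            truth = simulate(net, params, x0, times)
            states, _ = collocation_integrate(net, params, x0, default_mesh)
            prob = transcribe(net, default_mesh, [_as_exp(times, truth, x0)])
            pred = prob.predict(states, 0)
            rel = np.abs(pred - truth.states.T) / truth.states.T
            assert rel.max() < 1e-4

    def test_sensitivities_match_finite_differences(self, ref, default_mesh):
        net, params = ref
        x0 = np.array([0.5, 0.5, 1.2, 0.5])
        entries = [("gamma", 2), ("f", 0, 2)]
        states, sens = collocation_integrate(
            net, params, x0, default_mesh, param_entries=entries
        )
        eps = 1e-6
        from gmaid.network import PowerLawParameters

        for col, ent in enumerate(entries):
            gamma = np.array(params.gamma)
            f = np.array(params.f)
            if ent[0] == "gamma":
                gamma[ent[1]] += eps
            else:
                f[ent[1], ent[2]] += eps
            states2, _ = collocation_integrate(
                net, PowerLawParameters(gamma=gamma, f=f), x0, default_mesh
            )
            fd = (states2 - states) / eps
            assert np.max(np.abs(fd - sens[..., col])) < 1e-5


class TestTranscription:
    def test_constraint_and_variable_counts(self, ref, default_mesh, noise_free_exp):
        net, _ = ref
        single = transcribe(net, default_mesh, [noise_free_exp])
        triple = transcribe(net, default_mesh, [noise_free_exp] * 3)
        K, E = default_mesh.n_colloc_points, default_mesh.n_elements
        assert single.n_collocation_constraints == 4 * E * K
        # three experiments share the parameter block but not the states
        assert (
            triple.n_decision_variables - triple.n_parameters
            == 3 * (single.n_decision_variables - single.n_parameters)
        )
        assert triple.n_parameters == single.n_parameters

    def test_true_parameters_are_a_near_optimal_feasible_point(
        self, ref, default_mesh, noise_free_exp
    ):
        # substituting the original parameters and the collocation states
        # satisfies all constraints and leaves only the transcription bias
        net, params = ref
        prob = transcribe(net, default_mesh, [noise_free_exp])
        states, _ = prob.solve_states(params)
        colloc = prob.collocation_residuals(params, states[0])
        cont = prob.continuity_residuals(states[0], noise_free_exp.x0)
        assert np.abs(colloc).max() < 1e-9
        assert np.abs(cont).max() < 1e-12
        assert prob.objective(params, states) < 1e-5

    def test_empty_experiment_list_rejected(self, ref, default_mesh):
        net, _ = ref
        with pytest.raises(ValueError):
            transcribe(net, default_mesh, [])

    def test_sampling_time_outside_horizon_rejected(self, ref, noise_free_exp):
        net, _ = ref
        short_mesh = make_mesh(0, 5, 10, 3)
        with pytest.raises(ValueError):
            transcribe(net, short_mesh, [noise_free_exp])


class TestReconstruct:
    def test_matches_boundary_states(self, ref, default_mesh, noise_free_exp):
        net, params = ref
        states, _ = collocation_integrate(
            net, params, noise_free_exp.x0, default_mesh
        )
        traj = reconstruct_trajectory(states, default_mesh, n_dense=41)
        # element starts are interpolated exactly
        e0 = default_mesh.element_boundaries[0]
        assert traj.states[0] == pytest.approx(states[0, 0], rel=1e-12)

    def test_constant_solution_stays_constant(self, ref, default_mesh):
        net, params = ref
        const = np.tile(
            np.array([0.7, 1.1, 0.9, 1.3]),
            (default_mesh.n_elements, default_mesh.n_colloc_points + 1, 1),
        )
        traj = reconstruct_trajectory(const, default_mesh, n_dense=17)
        np.testing.assert_allclose(traj.states, np.tile(const[0, 0], (17, 1)))

    def test_dense_reconstruction_tracks_integrator(
        self, ref, default_mesh, noise_free_exp
    ):
        net, params = ref
        states, _ = collocation_integrate(
            net, params, noise_free_exp.x0, default_mesh
        )
        traj = reconstruct_trajectory(states, default_mesh, n_dense=101)
        truth = simulate(net, params, noise_free_exp.x0, traj.times)
        rel = np.abs(traj.states - truth.states) / truth.states
        assert rel.max() < 1e-3


def _as_exp(times, traj, x0):
    from gmaid.reference import Experiment

    return Experiment(times=times, observations=traj.states.T, x0=x0)
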