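import numpy as np
import pytest

from gmaid.collocation import make_mesh
from gmaid.network import PowerLawParameters, StoichiometricNetwork, simulate
from gmaid.reference import Experiment, generate_experiment, reference_network
from gmaid.signs import SignAssignment


@pytest.fixture(scope="session")
def ref():
    """Benchmark network with its original parameter values."""
    return reference_network()


@pytest.fixture(scope="session")
def truth_signs(ref):
    net, params = ref
    return SignAssignment.from_parameters(net, params)


@pytest.fixture(scope="session")
def noise_free_exp():
    return generate_experiment(noise_sd_fraction=0.0, seed=1)


@pytest.fixture(scope="session")
def default_mesh():
    return make_mesh(0.0, 10.0)


@pytest.fixture(scope="session")
def toy():
    """Two-reaction toy: X1 produced under inhibition by X2, converted to X2.

    Small enough (15 admissible sign assignments at one modifier per
    reaction) for exhaustive enumeration oracles.
    """
    net = StoichiometricNetwork(
        n_dependent=2,
        n_independent=0,
        mu=[[1.0, -1.0], [0.0, 1.0]],
        substrates=(frozenset(), frozenset({0})),
        candidate_modifiers=(frozenset({0, 1}), frozenset({1})),
        independent_values=np.array([]),
    )
    truth = PowerLawParameters(gamma=[2.0, 1.0], f=[[0.0, -0.5], [0.8, 0.0]])
    times = np.linspace(0.0, 2.0, 12)
    x0 = np.array([1.0, 0.5])
    traj = simulate(net, truth, x0, times)
    exp = Experiment(times=times, observations=traj.states.T, x0=x0)
    mesh = make_mesh(0.0, 2.0, n_elements=8, n_colloc_points=3, grading=1.0)
    return net, truth, exp, mesh


@pytest.fixture(scope="session")
def decay():
    """Single first-order decay reaction with closed-form solution e^(-t)."""
    net = StoichiometricNetwork(
        n_dependent=1,
        n_independent=0,
        mu=[[-1.0]],
        substrates=(frozenset({0}),),
        candidate_modifiers=(frozenset(),),
        independent_values=np.array([]),
    )
    params = PowerLawParameters(gamma=[1.0], f=[[1.0]])
    return net, params
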