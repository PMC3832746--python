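"""Generalized Mass Action (GMA) network representation and simulation.

A GMA model describes a biochemical network of ``n`` dependent and ``m``
independent metabolites connected by ``p`` processes.  Each process rate is a
product of power laws,

    v_r = gamma_r * prod_j X_j ** f_{r,j},

and the mass balances are ``dX_i/dt = sum_r mu_{i,r} v_r`` for the dependent
metabolites.  The kinetic order ``f_{r,j}`` encodes both the reaction
structure (substrates have positive orders) and the regulatory structure
(positive = activation, negative = inhibition, zero = no effect), which is
what makes the formalism convenient for systematic topology search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StoichiometricNetwork",
    "PowerLawParameters",
    "Trajectory",
    "SimulationError",
    "evaluate_rates",
    "derivatives",
    "rate_state_jacobian",
    "simulate",
    "network_to_dict",
    "network_from_dict",
]

#: States below this value are treated as having left the positive domain on
#: which power-law rates are defined.  Crossing it is an error, never a clamp.
POSITIVITY_FLOOR = 1e-9


class SimulationError(RuntimeError):
    """Numerical integration failed or a state left the positive domain."""


@dataclass(frozen=True)
class StoichiometricNetwork:
    """Stoichiometry plus the role (substrate / candidate modifier) of each
    metabolite in each process.

    Metabolites are indexed ``0 .. n_dependent-1`` (dependent, i.e. the state
    variables) followed by ``n_dependent .. n_dependent+n_independent-1``
    (independent, held at fixed concentrations).
    """

    n_dependent: int
    n_independent: int
    mu: np.ndarray  # (n_dependent, n_reactions) stoichiometric coefficients
    substrates: tuple[frozenset[int], ...]  # per reaction
    candidate_modifiers: tuple[frozenset[int], ...]  # per reaction
    independent_values: np.ndarray = field(default=None)  # (n_independent,)
    metabolite_names: tuple[str, ...] = ()

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if mu.shape[0] != self.n_dependent:
            raise ValueError(
                f"mu has {mu.shape[0]} rows, expected {self.n_dependent}"
            )
        if len(self.substrates) != self.n_reactions:
            raise ValueError("substrates must list one set per reaction")
        if len(self.candidate_modifiers) != self.n_reactions:
            raise ValueError("candidate_modifiers must list one set per reaction")
        object.__setattr__(
            self, "substrates", tuple(frozenset(s) for s in self.substrates)
        )
        object.__setattr__(
            self,
            "candidate_modifiers",
            tuple(frozenset(s) for s in self.candidate_modifiers),
        )
        n_total = self.n_dependent + self.n_independent
        for r, (subs, mods) in enumerate(
            zip(self.substrates, self.candidate_modifiers)
        ):
            if subs & mods:
                raise ValueError(
                    f"reaction {r}: substrates and candidate modifiers overlap"
                )
            for j in subs | mods:
                if not 0 <= j < n_total:
                    raise ValueError(
                        f"reaction {r}: metabolite index {j} out of range"
                    )
        iv = self.independent_values
        if iv is None:
            iv = np.ones(self.n_independent)
        iv = np.asarray(iv, dtype=float)
        if iv.shape != (self.n_independent,):
            raise ValueError("independent_values must have length n_independent")
        object.__setattr__(self, "independent_values", iv)
        if not self.metabolite_names:
            names = tuple(f"X{i + 1}" for i in range(self.n_dependent)) + tuple(
                f"X0_{i}" if self.n_independent > 1 else "X0"
                for i in range(self.n_independent)
            )
            object.__setattr__(self, "metabolite_names", names)

    @property
    def n_reactions(self) -> int:
        return self.mu.shape[1]

    @property
    def n_metabolites(self) -> int:
        """Total metabolite count, dependent plus independent."""
        return self.n_dependent + self.n_independent

    def full_concentrations(self, state: np.ndarray) -> np.ndarray:
        """Concatenate a dependent-state vector with the fixed independents."""
        state = np.asarray(state, dtype=float)
        return np.concatenate([state, self.independent_values])

    def allowed_entries(self, reaction: int) -> frozenset[int]:
        return self.substrates[reaction] | self.candidate_modifiers[reaction]


@dataclass(frozen=True)
class PowerLawParameters:
    """Apparent rate constants ``gamma`` (length p, > 0) and kinetic orders
    ``f`` ((p, n+m), zero outside each reaction's substrate/modifier sets)."""

    gamma: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        gamma = np.asarray(self.gamma, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "f", f)
        if np.any(gamma <= 0):
            raise ValueError("all rate constants gamma must be strictly positive")
        if f.shape[0] != gamma.shape[0]:
            raise ValueError("f must have one row per reaction")

    def validate_against(self, network: StoichiometricNetwork) -> None:
        """Check the structural zero/sign pattern imposed by the network."""
        if self.f.shape != (network.n_reactions, network.n_metabolites):
            raise ValueError(
                f"f has shape {self.f.shape}, expected "
                f"({network.n_reactions}, {network.n_metabolites})"
            )
        for r in range(network.n_reactions):
            allowed = network.allowed_entries(r)
            for j in range(network.n_metabolites):
                if j not in allowed and self.f[r, j] != 0.0:
                    raise ValueError(
                        f"f[{r},{j}] must be zero: metabolite {j} is neither "
                        f"substrate nor candidate modifier of reaction {r}"
                    )
            for j in network.substrates[r]:
                if self.f[r, j] <= 0:
                    raise ValueError(
                        f"f[{r},{j}] must be positive: metabolite {j} is a "
                        f"substrate of reaction {r}"
                    )


@dataclass(frozen=True)
class Trajectory:
    """Concentration time courses of the dependent metabolites."""

    times: np.ndarray  # (k,)
    states: np.ndarray  # (k, n_dependent)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if states.shape[0] != times.shape[0]:
            raise ValueError("states must have one row per time point")
        if np.any(states <= 0):
            raise ValueError("states must be strictly positive")


def _check_positive(network: StoichiometricNetwork, conc: np.ndarray) -> None:
    bad = np.flatnonzero(conc <= 0)
    if bad.size:
        name = network.metabolite_names[bad[0]]
        raise ValueError(
            f"non-positive concentration for metabolite {name} "
            f"({conc[bad[0]]!r}); power-law rates are undefined at zero"
        )


def evaluate_rates(
    network: StoichiometricNetwork,
    params: PowerLawParameters,
    state: np.ndarray,
) -> np.ndarray:
    """Power-law process rates v_r = gamma_r * prod_j X_j**f_{r,j}.

    ``state`` holds the dependent metabolites only; independent concentrations
    come from the network.  Metabolites with a zero kinetic order contribute a
    factor of one.
    """
    conc = network.full_concentrations(state)
    _check_positive(network, conc)
    # exp(f @ log X) is the log-domain form of the product; identical on the
    # positive domain and better conditioned for extreme orders.
    return params.gamma * np.exp(params.f @ np.log(conc))


def derivatives(
    network: StoichiometricNetwork,
    params: PowerLawParameters,
    state: np.ndarray,
) -> np.ndarray:
    """Mass-balance time derivatives dX_i/dt = sum_r mu_{i,r} v_r."""
    return network.mu @ evaluate_rates(network, params, state)


def rate_state_jacobian(
    network: StoichiometricNetwork,
    params: PowerLawParameters,
    state: np.ndarray,
    rates: np.ndarray | None = None,
) -> np.ndarray:
    """Jacobian of the dependent-metabolite derivatives w.r.t. the state.

    d(dX_i/dt)/dX_j = sum_r mu_{i,r} f_{r,j} v_r / X_j  (power-law identity).
    """
    state = np.asarray(state, dtype=float)
    if rates is None:
        rates = evaluate_rates(network, params, state)
    n = network.n_dependent
    dv_dx = params.f[:, :n] * (rates[:, None] / state[None, :])
    return network.mu @ dv_dx


def simulate(
    network: StoichiometricNetwork,
    params: PowerLawParameters,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the GMA ODE with an adaptive high-accuracy integrator.

    This is the ground-truth reference that the collocation transcription is
    validated against.  A state falling below the positivity floor aborts the
    integration with a :class:`SimulationError` naming the failing time.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial state must be strictly positive")
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing sequence")

    def rhs(t, x):
        if np.any(x <= POSITIVITY_FLOOR):
            raise SimulationError(
                f"state crossed the positivity floor at t={t:.6g}"
            )
        return network.mu @ (params.gamma * np.exp(params.f @ np.log(
            np.concatenate([x, network.independent_values]))))

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    states = sol.y.T
    if np.any(states <= POSITIVITY_FLOOR):
        t_bad = times[np.any(states <= POSITIVITY_FLOOR, axis=1)][0]
        raise SimulationError(f"state crossed the positivity floor at t={t_bad:.6g}")
    return Trajectory(times=times, states=states)


# ---------------------------------------------------------------------------
# JSON serialization


def network_to_dict(
    network: StoichiometricNetwork, params: PowerLawParameters | None = None
) -> dict:
    doc = {
        "metabolites": {
            "dependent": list(network.metabolite_names[: network.n_dependent]),
            "independent": list(network.metabolite_names[network.n_dependent:]),
            "independent_values": network.independent_values.tolist(),
        },
        "reactions": [f"v{r + 1}" for r in range(network.n_reactions)],
        "mu": network.mu.tolist(),
        "substrates": [sorted(s) for s in network.substrates],
        "candidate_modifiers": [sorted(s) for s in network.candidate_modifiers],
    }
    if params is not None:
        doc["gamma"] = params.gamma.tolist()
        doc["f"] = params.f.tolist()
    return doc


def network_from_dict(
    doc: dict,
) -> tuple[StoichiometricNetwork, PowerLawParameters | None]:
    met = doc["metabolites"]
    dep = list(met["dependent"])
    indep = list(met.get("independent", []))
    network = StoichiometricNetwork(
        n_dependent=len(dep),
        n_independent=len(indep),
        mu=np.asarray(doc["mu"], dtype=float),
        substrates=tuple(frozenset(s) for s in doc["substrates"]),
        candidate_modifiers=tuple(
            frozenset(s) for s in doc["candidate_modifiers"]
        ),
        independent_values=np.asarray(
            met.get("independent_values", [1.0] * len(indep)), dtype=float
        ),
        metabolite_names=tuple(dep) + tuple(indep),
    )
    params = None
    if "gamma" in doc:
        params = PowerLawParameters(
            gamma=np.asarray(doc["gamma"], dtype=float),
            f=np.asarray(doc["f"], dtype=float),
        )
        params.validate_against(network)
    return network, params


def save_network(path, network, params=None) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network, params), fh, indent=2)


def load_network(path):
    with open(path) as fh:
        return network_from_dict(json.load(fh))
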