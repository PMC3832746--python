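"""Ternary regulatory sign patterns and their big-M/disjunctive encoding.

Whether metabolite j influences process r is encoded by a three-way choice
for the kinetic order f_{r,j}: negative (inhibitor), zero (no effect) or
positive (activator/substrate).  In the mixed-integer formulation each choice
carries a binary indicator (y-, y, y+), exactly one of which is active, and
the big-M inequalities

    f_{r,j} <= -eps + M (1 - y-)
    -eps - M (1 - y) <= f_{r,j} <= eps + M (1 - y)
    f_{r,j} >= eps - M (1 - y+)

confine f to the selected branch while leaving the other branches vacuous.
The model-selection objective is the Akaike criterion, which charges two
units per active (nonzero) kinetic order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import StoichiometricNetwork

__all__ = [
    "SignAssignment",
    "BigMConfig",
    "aic",
    "apply_sign_bounds",
    "big_m_feasible",
    "binary_variable_count",
]


@dataclass(frozen=True)
class BigMConfig:
    """Threshold eps separating "zero" from "active" orders, and the big-M
    constant that switches off inactive branches of the disjunction.

    M must dominate the kinetic-order range (M >= f_hi - f_lo + eps) so that
    every branch whose indicator is off is satisfied by any f within bounds.
    """

    epsilon: float = 1e-3
    big_m: float = 3.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.big_m <= self.epsilon:
            raise ValueError("big_m must exceed epsilon")


@dataclass(frozen=True)
class SignAssignment:
    """Regulatory sign per (reaction, dependent metabolite): -1, 0 or +1.

    Substrate entries are forced to +1 and entries outside a reaction's
    substrate/candidate-modifier sets to 0; only candidate-modifier entries
    are genuinely free.
    """

    signs: np.ndarray  # (n_reactions, n_dependent), values in {-1, 0, +1}

    def __post_init__(self):
        signs = np.asarray(self.signs, dtype=int)
        signs.setflags(write=False)
        object.__setattr__(self, "signs", signs)
        if not np.isin(signs, (-1, 0, 1)).all():
            raise ValueError("signs must contain only -1, 0, +1")

    def validate_against(self, network: StoichiometricNetwork) -> None:
        p, n = self.signs.shape
        if (p, n) != (network.n_reactions, network.n_dependent):
            raise ValueError(
                f"signs has shape {(p, n)}, expected "
                f"({network.n_reactions}, {network.n_dependent})"
            )
        for r in range(p):
            for j in range(n):
                if j in network.substrates[r]:
                    if self.signs[r, j] != 1:
                        raise ValueError(
                            f"substrate entry ({r},{j}) must have sign +1"
                        )
                elif j not in network.candidate_modifiers[r]:
                    if self.signs[r, j] != 0:
                        raise ValueError(
                            f"entry ({r},{j}) is neither substrate nor candidate "
                            "modifier and must have sign 0"
                        )

    @classmethod
    def baseline(cls, network: StoichiometricNetwork) -> "SignAssignment":
        """No regulation: substrates +1, everything else 0."""
        signs = np.zeros((network.n_reactions, network.n_dependent), dtype=int)
        for r in range(network.n_reactions):
            for j in network.substrates[r]:
                if j < network.n_dependent:
                    signs[r, j] = 1
        return cls(signs=signs)

    @classmethod
    def from_parameters(cls, network, params, threshold: float = 0.0):
        """Sign pattern read off a parameter set's nonzero kinetic orders."""
        base = cls.baseline(network).signs.copy()
        base.setflags(write=True)
        n = network.n_dependent
        for r in range(network.n_reactions):
            for j in network.candidate_modifiers[r]:
                if j < n and abs(params.f[r, j]) > threshold:
                    base[r, j] = int(np.sign(params.f[r, j]))
        return cls(signs=base)

    def with_sign(self, reaction: int, metabolite: int, sign: int):
        signs = np.array(self.signs)
        signs[reaction, metabolite] = sign
        return SignAssignment(signs=signs)

    @property
    def n_active(self) -> int:
        """Number of nonzero kinetic orders = sum of (y- + y+) indicators."""
        return int(np.count_nonzero(self.signs))

    def modifier_count(self, network: StoichiometricNetwork, reaction: int) -> int:
        return sum(
            1
            for j in network.candidate_modifiers[reaction]
            if j < network.n_dependent and self.signs[reaction, j] != 0
        )

    def indicator_triples(self) -> np.ndarray:
        """Binary (y-, y, y+) triple per entry, shape (p, n, 3)."""
        y = np.zeros(self.signs.shape + (3,), dtype=int)
        y[..., 0] = self.signs == -1
        y[..., 1] = self.signs == 0
        y[..., 2] = self.signs == 1
        return y

    def key(self) -> bytes:
        return self.signs.tobytes()

    def __hash__(self):
        return hash(self.key())

    def __eq__(self, other):
        return isinstance(other, SignAssignment) and np.array_equal(
            self.signs, other.signs
        )

    def to_records(self) -> list[dict]:
        return [
            {"reaction": r, "metabolite": j, "sign": int(self.signs[r, j])}
            for r in range(self.signs.shape[0])
            for j in range(self.signs.shape[1])
            if self.signs[r, j] != 0
        ]


def binary_variable_count(network: StoichiometricNetwork) -> int:
    """Indicator count of the full mixed-integer encoding.

    Three binaries (y-, y, y+) for every (reaction, dependent metabolite)
    pair, substrates included (their indicators are fixed, not removed).
    """
    return 3 * network.n_reactions * network.n_dependent


def aic(rss: float, k_points: int, n_active: int) -> float:
    """Akaike criterion k*ln(rss/k) + 2*n_active (additive constant omitted).

    ``k_points`` is the total residual count (sampling times x metabolites,
    summed over experiments); ``n_active`` the number of nonzero kinetic
    orders.  The caller must floor rss away from zero.
    """
    if rss <= 0:
        raise ValueError("rss must be strictly positive (floor it before calling)")
    if k_points < 1:
        raise ValueError("k_points must be at least 1")
    if n_active < 0:
        raise ValueError("n_active must be non-negative")
    return k_points * math.log(rss / k_points) + 2 * n_active


def apply_sign_bounds(sign: int, bounds, cfg: BigMConfig) -> tuple[float, float]:
    """Interval for a kinetic order under a fixed sign.

    sign -1 -> [f_lo, -eps]; sign 0 -> [-eps, +eps] (the order is pinned to 0
    in the fixed-sign fit); sign +1 -> [+eps, f_hi].  For M >= f_hi - f_lo +
    eps these intervals coincide with the feasible set of the big-M rows with
    the corresponding indicator active (see :func:`big_m_feasible`).
    """
    eps = cfg.epsilon
    if sign == -1:
        return (bounds.f_lo, -eps)
    if sign == 0:
        return (-eps, eps)
    if sign == 1:
        return (eps, bounds.f_hi)
    raise ValueError(f"invalid sign {sign!r}; expected -1, 0 or +1")


def big_m_feasible(
    f: float, y_minus: int, y_zero: int, y_plus: int, bounds, cfg: BigMConfig
) -> bool:
    """Whether f satisfies all big-M rows for the given indicator triple.

    The global bounds f_lo <= f <= f_hi apply alongside the disjunction rows.
    """
    if y_minus + y_zero + y_plus != 1:
        return False
    eps, M = cfg.epsilon, cfg.big_m
    if not bounds.f_lo <= f <= bounds.f_hi:
        return False
    if f > -eps + M * (1 - y_minus):
        return False
    if not -eps - M * (1 - y_zero) <= f <= eps + M * (1 - y_zero):
        return False
    if f < eps - M * (1 - y_plus):
        return False
    return True
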