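"""Simultaneous topology and parameter identification.

The mixed-integer estimation problem couples the dynamic least-squares fit
with a three-way sign choice (negative / zero / positive) for every candidate
kinetic order, minimizing the Akaike criterion

    AIC = k ln(RSS/k) + 2 * (number of nonzero kinetic orders).

It is solved by nonlinear branch-and-bound over the sign triples: each node
fixes a subset of the signs and bounds the best attainable AIC of its subtree
by a relaxed-sign NLP (undecided orders free over their full range) plus the
complexity charge already incurred.  A rounding heuristic on each node's
relaxed solution supplies incumbents early.  Alternative topologies are
enumerated by re-solving under integer cuts that exclude every previously
returned sign assignment.

All node solves are local (trust-region least squares), so — as with any
local MINLP strategy — bounds and hence optimality claims are heuristic;
the search additionally honors an explicit node budget.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .collocation import make_mesh
from .estimation import (
    EstimationError,
    FitResult,
    ParameterBounds,
    fit_parameters,
    multistart_fit,
)
from .network import StoichiometricNetwork
from .signs import BigMConfig, SignAssignment, aic

logger = logging.getLogger(__name__)


def default_search_mesh(experiments):
    """Coarser transcription for node solves: the mesh bias (~1e-5 in rss)
    is far below the noise level that dominates identification runs."""
    exps = list(experiments)
    t0 = min(float(e.times[0]) for e in exps)
    tf = max(float(e.times[-1]) for e in exps)
    return make_mesh(t0, tf, n_elements=12, n_colloc_points=3, grading=1.2)

__all__ = [
    "IntegerCut",
    "TopologyRanking",
    "TopologyEntry",
    "SearchExhausted",
    "integer_cut",
    "solve_minlp",
    "identify_topologies",
    "candidate_pairs",
    "enumerate_assignments",
]

_RSS_FLOOR = 1e-12  # keeps the AIC log finite on perfect fits


class SearchExhausted(RuntimeError):
    """No admissible sign assignment remains under the given cuts."""


@dataclass(frozen=True)
class IntegerCut:
    """No-good cut excluding exactly one sign assignment.

    Over the indicator binaries the cut reads
    sum_{(r,j,s) in ONE} y - sum_{(r,j,s) in ZERO} y <= |ONE| - 1,
    which the generating assignment violates (left side |ONE|) and every
    other assignment satisfies.
    """

    assignment: SignAssignment

    def evaluate(self, other: SignAssignment) -> tuple[int, int]:
        """(left-hand side, right-hand side) of the cut at ``other``."""
        y_gen = self.assignment.indicator_triples()
        y_oth = other.indicator_triples()
        ones = y_gen == 1
        lhs = int(y_oth[ones].sum()) - int(y_oth[~ones].sum())
        return lhs, int(ones.sum()) - 1

    def satisfied_by(self, other: SignAssignment) -> bool:
        lhs, rhs = self.evaluate(other)
        return lhs <= rhs


def integer_cut(assignment: SignAssignment) -> IntegerCut:
    """Linear inequality violated by ``assignment`` and by nothing else."""
    return IntegerCut(assignment=assignment)


@dataclass
class TopologyEntry:
    sign_pattern: SignAssignment
    fit: FitResult
    aic: float
    iteration: int


@dataclass
class TopologyRanking:
    """Enumerated topologies sorted by ascending Akaike criterion."""

    entries: list[TopologyEntry]
    cuts: list[IntegerCut]
    exhausted: bool = False

    def sorted_by_rss(self) -> list[TopologyEntry]:
        return sorted(self.entries, key=lambda e: e.fit.rss)

    def contains(self, predicate) -> bool:
        return any(predicate(e.sign_pattern) for e in self.entries)


def candidate_pairs(network: StoichiometricNetwork) -> list[tuple[int, int]]:
    """Orderly list of the free (reaction, dependent metabolite) sign choices."""
    return [
        (r, j)
        for r in range(network.n_reactions)
        for j in sorted(network.candidate_modifiers[r])
        if j < network.n_dependent
    ]


def enumerate_assignments(
    network: StoichiometricNetwork, max_modifiers_per_reaction: int
):
    """All admissible sign assignments (exhaustive; for small networks)."""
    pairs = candidate_pairs(network)
    by_reaction: dict[int, list[int]] = {}
    for r, j in pairs:
        by_reaction.setdefault(r, []).append(j)
    per_reaction_options = []
    for r in range(network.n_reactions):
        cands = by_reaction.get(r, [])
        options = []
        for n_act in range(0, max_modifiers_per_reaction + 1):
            for chosen in itertools.combinations(cands, n_act):
                for signs in itertools.product((-1, 1), repeat=n_act):
                    options.append(dict(zip(chosen, signs)))
        per_reaction_options.append(options)
    base = SignAssignment.baseline(network)
    for combo in itertools.product(*per_reaction_options):
        signs = np.array(base.signs)
        for r, choice in enumerate(combo):
            for j, s in choice.items():
                signs[r, j] = s
        yield SignAssignment(signs=signs)


class _BranchAndBound:
    """Best-bound-first search over partial sign assignments.

    State is retained between calls so that iterative enumeration under
    integer cuts reuses every relaxed-node bound and leaf fit (cuts exclude
    leaves only; the relaxations are unchanged).
    """

    def __init__(
        self,
        network,
        experiments,
        bounds: ParameterBounds,
        cfg: BigMConfig,
        mesh,
        max_modifiers: int,
        seed: int,
        leaf_starts: int = 3,
        node_limit: int = 400,
    ):
        self.network = network
        self.experiments = list(experiments)
        self.bounds = bounds
        self.cfg = cfg
        self.mesh = mesh or default_search_mesh(experiments)
        self.max_modifiers = max_modifiers
        self.seed = seed
        self.leaf_starts = leaf_starts
        self.node_limit = node_limit
        self.pairs = candidate_pairs(network)
        self.k_points = sum(e.observations.size for e in self.experiments)
        self.base = SignAssignment.baseline(network)
        self.node_cache: dict = {}  # partial key -> (bound, relaxed params)
        self.leaf_cache: dict = {}  # assignment -> FitResult
        self._heap_count = itertools.count()
        # node solves trade a little terminal precision for speed: rss
        # differences that matter to the AIC ranking are far above 1e-9
        self.fit_opts = dict(
            ftol=1e-9, xtol=1e-9, gtol=1e-8, max_nfev=120, x_scale=1.0
        )

    # -- helpers ------------------------------------------------------------

    def _propagate(self, fixed: dict) -> dict | None:
        """Force remaining candidates of saturated reactions to zero."""
        fixed = dict(fixed)
        per_reaction = {}
        for (r, j), s in fixed.items():
            if s != 0:
                per_reaction[r] = per_reaction.get(r, 0) + 1
        for r, count in per_reaction.items():
            if count > self.max_modifiers:
                return None
            if count == self.max_modifiers:
                for (rr, j) in self.pairs:
                    if rr == r and (rr, j) not in fixed:
                        fixed[(rr, j)] = 0
        return fixed

    def _key(self, fixed: dict) -> tuple:
        return tuple(sorted(fixed.items()))

    def _assignment_from(self, fixed: dict) -> SignAssignment:
        signs = np.array(self.base.signs)
        for (r, j), s in fixed.items():
            signs[r, j] = s
        return SignAssignment(signs=signs)

    def _aic_of(self, fit: FitResult, assignment: SignAssignment) -> float:
        return aic(max(fit.rss, _RSS_FLOOR), self.k_points, assignment.n_active)

    def _fit_leaf(self, assignment: SignAssignment, warm=None) -> FitResult | None:
        if assignment in self.leaf_cache:
            return self.leaf_cache[assignment]
        try:
            fit = multistart_fit(
                self.network, self.experiments, assignment,
                bounds=self.bounds, mesh=self.mesh,
                n_starts=self.leaf_starts, seed=self.seed, cfg=self.cfg,
                init=warm, **self.fit_opts,
            )
        except EstimationError:
            fit = None
        self.leaf_cache[assignment] = fit
        return fit

    def _relax(self, fixed: dict, warm=None):
        """Relaxed-sign NLP: undecided orders free over the full range."""
        key = self._key(fixed)
        if key in self.node_cache:
            return self.node_cache[key]
        undecided = {p for p in self.pairs if p not in fixed}
        pattern = self._assignment_from(fixed)
        n_active_fixed = pattern.n_active  # undecided count as inactive here
        try:
            fit = multistart_fit(
                self.network, self.experiments, pattern,
                bounds=self.bounds, mesh=self.mesh,
                n_starts=1, seed=self.seed, cfg=self.cfg,
                init=warm, free_full_range=undecided, **self.fit_opts,
            )
            bound = aic(
                max(fit.rss, _RSS_FLOOR), self.k_points, n_active_fixed
            )
        except EstimationError:
            # treat an unsolved node as unbounded-below: never prune it
            fit, bound = None, -np.inf
        self.node_cache[key] = (bound, fit)
        return bound, fit

    def _round_relaxed(self, fixed: dict, relaxed_fit: FitResult) -> SignAssignment:
        """Primal heuristic: threshold the relaxed orders, keeping at most
        max_modifiers (largest magnitude) per reaction."""
        signs = np.array(self._assignment_from(fixed).signs)
        by_reaction: dict[int, list[tuple[float, int]]] = {}
        for (r, j) in self.pairs:
            if (r, j) in fixed:
                continue
            val = relaxed_fit.params.f[r, j]
            if abs(val) >= self.cfg.epsilon:
                by_reaction.setdefault(r, []).append((abs(val), j, int(np.sign(val))))
        for r, items in by_reaction.items():
            already = sum(
                1 for (rr, j), s in fixed.items() if rr == r and s != 0
            )
            room = self.max_modifiers - already
            for _, j, s in sorted(items, reverse=True)[:max(room, 0)]:
                signs[r, j] = s
        return SignAssignment(signs=signs)

    def _branch_pair(self, fixed: dict, relaxed_fit) -> tuple[int, int]:
        """Undecided pair whose relaxed order is farthest from the sign
        boundaries (+-epsilon); lexicographic tie-break."""
        eps = self.cfg.epsilon
        best, best_score = None, -1.0
        for (r, j) in self.pairs:
            if (r, j) in fixed:
                continue
            if relaxed_fit is not None:
                val = relaxed_fit.params.f[r, j]
                score = min(abs(val - eps), abs(val + eps))
            else:
                score = 0.0
            if score > best_score + 1e-15:
                best, best_score = (r, j), score
        return best

    # -- main solve ---------------------------------------------------------

    def solve(self, cuts: list[IntegerCut]) -> tuple[SignAssignment, FitResult]:
        """Best admissible assignment under the cuts, by AIC."""
        excluded = {c.assignment for c in cuts}

        def admissible(a: SignAssignment) -> bool:
            return a not in excluded

        incumbent = None  # (aic, assignment, fit)
        for a, fit in self.leaf_cache.items():
            if fit is not None and admissible(a):
                val = self._aic_of(fit, a)
                if incumbent is None or val < incumbent[0]:
                    incumbent = (val, a, fit)

        heap = []
        root = self._propagate({})
        bound, relaxed = self._relax(root)
        heapq.heappush(heap, (bound, next(self._heap_count), root, relaxed))
        nodes_used = 0

        while heap and nodes_used < self.node_limit:
            bound, _, fixed, relaxed = heapq.heappop(heap)
            if incumbent is not None and bound >= incumbent[0] - 1e-9:
                continue
            # primal heuristic at every node
            if relaxed is not None:
                cand = self._round_relaxed(fixed, relaxed)
                fit = self._fit_leaf(cand, warm=relaxed.params)
                nodes_used += 1
                if fit is not None and admissible(cand):
                    val = self._aic_of(fit, cand)
                    if incumbent is None or val < incumbent[0]:
                        incumbent = (val, cand, fit)
            undecided = [p for p in self.pairs if p not in fixed]
            if not undecided:
                a = self._assignment_from(fixed)
                fit = self._fit_leaf(
                    a, warm=relaxed.params if relaxed is not None else None
                )
                nodes_used += 1
                if fit is not None and admissible(a):
                    val = self._aic_of(fit, a)
                    if incumbent is None or val < incumbent[0]:
                        incumbent = (val, a, fit)
                continue
            pair = self._branch_pair(fixed, relaxed)
            warm = relaxed.params if relaxed is not None else None
            for sign in (-1, 0, 1):
                child = dict(fixed)
                child[pair] = sign
                child = self._propagate(child)
                if child is None:
                    continue
                cbound, crelax = self._relax(child, warm=warm)
                nodes_used += 1
                if incumbent is not None and cbound >= incumbent[0] - 1e-9:
                    continue
                heapq.heappush(
                    heap, (cbound, next(self._heap_count), child, crelax)
                )

        if incumbent is None:
            # fall back: evaluate the no-regulation baseline
            base = self.base
            if admissible(base):
                fit = self._fit_leaf(base)
                if fit is not None:
                    incumbent = (self._aic_of(fit, base), base, fit)
        if incumbent is None:
            raise SearchExhausted(
                "no admissible sign assignment found under the given cuts"
            )
        _, assignment, fit = incumbent
        return assignment, fit


def _relax_and_round(bb: _BranchAndBound, cuts):
    """One-shot strategy: root relaxation, threshold, fixed-sign fit."""
    excluded = {c.assignment for c in cuts}
    _, relaxed = bb._relax(bb._propagate({}))
    if relaxed is None:
        raise EstimationError("root relaxation failed")
    cand = bb._round_relaxed({}, relaxed)
    if cand in excluded:
        raise SearchExhausted("rounded assignment already excluded by cuts")
    fit = bb._fit_leaf(cand, warm=relaxed.params)
    if fit is None:
        raise EstimationError("rounded assignment could not be fitted")
    return cand, fit


def solve_minlp(
    network,
    experiments,
    bounds: ParameterBounds | None = None,
    cfg: BigMConfig | None = None,
    mesh=None,
    max_modifiers_per_reaction: int = 1,
    cuts: list[IntegerCut] | None = None,
    strategy: str = "branch_and_bound",
    seed: int = 0,
    leaf_starts: int = 3,
    node_limit: int = 400,
    _search: _BranchAndBound | None = None,
) -> tuple[SignAssignment, FitResult]:
    """AIC-minimizing sign assignment (and its fit) under integer cuts.

    Substrates are fixed positive and excluded from the modifier count; each
    reaction activates at most ``max_modifiers_per_reaction`` of its candidate
    modifiers.  Strategy "branch_and_bound" (default) explores sign branches
    with relaxed-sign NLP bounds; "relax_and_round" solves one relaxation and
    thresholds it.
    """
    bb = _search or _BranchAndBound(
        network, experiments, bounds or ParameterBounds(), cfg or BigMConfig(),
        mesh, max_modifiers_per_reaction, seed,
        leaf_starts=leaf_starts, node_limit=node_limit,
    )
    cuts = list(cuts or [])
    if strategy == "branch_and_bound":
        return bb.solve(cuts)
    if strategy == "relax_and_round":
        return _relax_and_round(bb, cuts)
    raise ValueError(f"unknown strategy {strategy!r}")


def identify_topologies(
    network,
    experiments,
    bounds: ParameterBounds | None = None,
    cfg: BigMConfig | None = None,
    mesh=None,
    max_modifiers_per_reaction: int = 1,
    n_topologies: int = 5,
    seed: int = 0,
    leaf_starts: int = 3,
    node_limit: int = 400,
    strategy: str = "branch_and_bound",
) -> TopologyRanking:
    """Iteratively enumerate ranked alternative regulatory topologies.

    Each iteration solves the mixed-integer problem, then adds an integer cut
    excluding the returned assignment, until ``n_topologies`` are collected
    or the admissible space is exhausted.  The final ranking is sorted by
    ascending AIC (with local solves, per-iteration monotonicity of the AIC
    is not guaranteed, so the report is re-sorted).
    """
    if n_topologies < 1:
        raise ValueError("n_topologies must be at least 1")
    bb = _BranchAndBound(
        network, experiments, bounds or ParameterBounds(), cfg or BigMConfig(),
        mesh, max_modifiers_per_reaction, seed,
        leaf_starts=leaf_starts, node_limit=node_limit,
    )
    entries: list[TopologyEntry] = []
    cuts: list[IntegerCut] = []
    exhausted = False
    for it in range(n_topologies):
        try:
            assignment, fit = solve_minlp(
                network, experiments, strategy=strategy, cuts=cuts, _search=bb,
            )
        except SearchExhausted:
            exhausted = True
            break
        entries.append(
            TopologyEntry(
                sign_pattern=assignment,
                fit=fit,
                aic=aic(
                    max(fit.rss, _RSS_FLOOR),
                    bb.k_points,
                    assignment.n_active,
                ),
                iteration=it,
            )
        )
        cuts.append(integer_cut(assignment))
        logger.info(
            "topology %d: rss=%.4g aic=%.2f active=%d",
            it, fit.rss, entries[-1].aic, assignment.n_active,
        )
    # polish: node solves run under a cheap evaluation cap, so re-fit each
    # returned topology to full convergence before reporting
    for entry in entries:
        try:
            refined = fit_parameters(
                network, list(experiments), entry.sign_pattern,
                bounds=bb.bounds, mesh=bb.mesh, cfg=bb.cfg,
                init=entry.fit.params,
            )
        except EstimationError:
            continue
        if refined.rss <= entry.fit.rss:
            entry.fit = refined
            entry.aic = aic(
                max(refined.rss, _RSS_FLOOR), bb.k_points,
                entry.sign_pattern.n_active,
            )
    entries.sort(key=lambda e: e.aic)
    return TopologyRanking(entries=entries, cuts=cuts, exhausted=exhausted)
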