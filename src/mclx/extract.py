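"""Multi-confidence-level (MCL) tissue-specific model extraction.

Given a flux-consistent metabolic network and a three-tier confidence
partition of its reactions (high ``C_h``, medium ``C_m``, low ``C_x``), the
extraction selects a subnetwork ``R_p`` that

1. contains every high-confidence reaction, and
2. maximises ``|R_p & C_m| - w_low * |R_p & C_x|`` (``w_low = 0.5``),

i.e. keeps as many medium-confidence reactions as possible while penalising
low-confidence ballast; the weight 0.5 balances parsimony against medium
coverage.  Enumerating elementary flux modes is combinatorially infeasible
at genome scale, so the algorithm instead samples feasible flux
distributions: it solves many LPs with randomised objectives supported on
``C_h | C_m``, records each solution's Boolean activity pattern as a column
of a flux-distribution matrix (``fdMatrix``), scores columns by
``#active medium - 0.5 * #active low``, and greedily adds whole columns --
first the best-scoring columns that cover remaining high-confidence
reactions, then any column while the best score stays positive.  Rows of
added reactions are zeroed so a reaction contributes to the score at most
once.  The whole pass repeats on the partial model with freshly sampled
columns until the model size reaches a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lp import FEASIBILITY_TOLERANCE, LPSystem
from .network import ConfidenceTiers, MetabolicNetwork

__all__ = [
    "ExtractionParams",
    "FluxDistributionMatrix",
    "ExtractionResult",
    "CoverageError",
    "ConvergenceError",
    "random_objective",
    "build_fd_matrix",
    "score_columns",
    "score_of_set",
    "greedy_select",
    "extract_mcl",
]

log = logging.getLogger(__name__)


class CoverageError(RuntimeError):
    """Some high-confidence reaction cannot carry flux in any sampled or
    targeted flux distribution."""

    def __init__(self, uncovered):
        self.uncovered = sorted(uncovered)
        super().__init__(
            f"high-confidence reactions not coverable: {self.uncovered}"
        )


class ConvergenceError(RuntimeError):
    """Outer loop failed to reach a size fixed point."""

    def __init__(self, sizes):
        self.sizes = sizes
        super().__init__(
            f"no fixed point after {len(sizes)} iterations; sizes: {sizes}"
        )


@dataclass
class ExtractionParams:
    """Tunable parameters of the extraction.

    ``n_columns``: randomized flux distributions sampled per outer iteration
    (10,000 at production scale; a few hundred suffice for toy networks).
    ``k``: number of high/medium-confidence reactions drawn into each random
    objective.  ``activity_tolerance``: |flux| above which a reaction counts
    as active.  ``low_weight``: penalty per active low-confidence reaction.
    ``parsimonious``: post-process each LP solution to minimum total flux so
    activity patterns hug elementary modes instead of arbitrary vertices.
    """

    n_columns: int = 10_000
    k: int = 3
    activity_tolerance: float = FEASIBILITY_TOLERANCE
    low_weight: float = 0.5
    parsimonious: bool = True
    max_outer_iterations: int = 20

    def __post_init__(self):
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class FluxDistributionMatrix:
    """Boolean reaction-activity patterns of randomized LP solutions.

    ``activity[i, j]`` is True when reaction ``rxn_ids[i]`` carries
    |flux| > tolerance in the j-th sampled flux distribution; ``objectives``
    records the random objective support that generated each column.
    """

    activity: np.ndarray  # bool, shape (n_reactions, n_columns)
    rxn_ids: list[str]
    objectives: list[tuple[str, ...]]
    seed: int | None = None
    n_degenerate: int = 0

    @property
    def n_columns(self) -> int:
        return self.activity.shape[1]


def random_objective(
    tiers: ConfidenceTiers, rng: np.random.Generator, k: int = 3
) -> dict[str, float]:
    """Draw a unit-weight objective over k high/medium-confidence reactions.

    Low-confidence reactions never enter the objective.  When fewer than k
    candidates exist, all of them are used.
    """
    pool = sorted(tiers.high | tiers.medium)
    if not pool:
        raise ValueError("high and medium confidence tiers are both empty")
    k = min(k, len(pool))
    chosen = rng.choice(len(pool), size=k, replace=False)
    return {pool[i]: 1.0 for i in chosen}


def _activity_column(system: LPSystem, result, tol: float) -> np.ndarray:
    if not result.ok:
        return np.zeros(len(system.rxn_ids), dtype=bool)
    v = np.array([result.fluxes[r] for r in system.rxn_ids])
    return np.abs(v) > tol


def build_fd_matrix(
    net: MetabolicNetwork | LPSystem,
    tiers: ConfidenceTiers,
    n_columns: int,
    rng: np.random.Generator | int,
    params: ExtractionParams | None = None,
) -> FluxDistributionMatrix:
    """Sample ``n_columns`` randomized flux distributions on a network.

    Infeasible or degenerate solves contribute all-zero columns, which are
    retained (they score zero and are never selected) and counted in
    ``n_degenerate``.
    """
    params = params or ExtractionParams(n_columns=n_columns)
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    system = net if isinstance(net, LPSystem) else LPSystem.from_network(net)
    cols, objectives, degenerate = [], [], 0
    for _ in range(n_columns):
        objective = random_objective(tiers, rng, params.k)
        result = system.solve(
            objective, sense="max", parsimonious=params.parsimonious
        )
        col = _activity_column(system, result, params.activity_tolerance)
        if not col.any():
            degenerate += 1
        cols.append(col)
        objectives.append(tuple(sorted(objective)))
    activity = np.column_stack(cols) if cols else np.zeros((len(system.rxn_ids), 0), bool)
    return FluxDistributionMatrix(
        activity=activity,
        rxn_ids=list(system.rxn_ids),
        objectives=objectives,
        seed=seed,
        n_degenerate=degenerate,
    )


def score_columns(
    activity: np.ndarray,
    medium_mask: np.ndarray,
    low_mask: np.ndarray,
    low_weight: float = 0.5,
) -> np.ndarray:
    """Score = #active medium-confidence - low_weight * #active low-confidence.

    Rows already added to the model are expected to be zeroed out of
    ``activity`` so they no longer contribute.
    """
    return medium_mask @ activity - low_weight * (low_mask @ activity)


def score_of_set(rxn_ids, tiers: ConfidenceTiers, low_weight: float = 0.5) -> float:
    """Extraction objective of a finished reaction set."""
    rxn_ids = set(rxn_ids)
    return len(rxn_ids & tiers.medium) - low_weight * len(rxn_ids & tiers.low)


def _targeted_column(
    system: LPSystem, rid: str, params: ExtractionParams
) -> np.ndarray:
    """Activity pattern of an LP that maximises |flux| through one reaction.

    Used as a fallback when no sampled column activates a high-confidence
    reaction: maximise the reaction's flux (and minimise it, if reversible)
    to ascertain whether it can be active at all.
    """
    for sense in ("max", "min"):
        res = system.solve({rid: 1.0}, sense=sense, parsimonious=params.parsimonious)
        if res.ok and abs(res.fluxes[rid]) > params.activity_tolerance:
            return _activity_column(system, res, params.activity_tolerance)
        if sense == "max" and system.lower[system.index[rid]] >= 0:
            break  # irreversible: minimising cannot activate it
    return np.zeros(len(system.rxn_ids), dtype=bool)


@dataclass
class _GreedyTrace:
    selected_columns: list[int] = field(default_factory=list)
    selected_scores: list[float] = field(default_factory=list)
    n_fallback_columns: int = 0


def greedy_select(
    matrix: FluxDistributionMatrix,
    tiers: ConfidenceTiers,
    params: ExtractionParams,
    system: LPSystem | None = None,
) -> tuple[set[str], _GreedyTrace]:
    """One coverage-then-growth pass over a flux-distribution matrix.

    Phase 1 repeatedly adds the best-scoring column that activates at least
    one not-yet-covered high-confidence reaction, until all of ``C_h`` is
    covered.  Phase 2 keeps adding the best-scoring column while the best
    score is positive.  After every addition the added reactions' rows are
    zeroed and scores recomputed.  Ties break on the lowest column index.
    """
    activity = matrix.activity.copy()
    rxn_ids = matrix.rxn_ids
    index = {r: i for i, r in enumerate(rxn_ids)}
    medium_mask = np.array([r in tiers.medium for r in rxn_ids], dtype=float)
    low_mask = np.array([r in tiers.low for r in rxn_ids], dtype=float)
    final: set[str] = set()
    remaining_high = {r for r in tiers.high if r in index}
    trace = _GreedyTrace()

    def add_column(col: np.ndarray, col_idx: int, score: float):
        active = {rxn_ids[i] for i in np.flatnonzero(col)}
        final.update(active)
        remaining_high.difference_update(active)
        activity[col, :] = False  # zero the added reactions' rows
        trace.selected_columns.append(col_idx)
        trace.selected_scores.append(float(score))

    # Phase 1: cover every high-confidence reaction.
    while remaining_high:
        high_rows = [index[r] for r in remaining_high]
        has_high = activity[high_rows, :].any(axis=0)
        if not has_high.any():
            # fallback: target one uncovered reaction directly
            if system is None:
                raise CoverageError(remaining_high)
            rid = min(remaining_high)
            col = _targeted_column(system, rid, params)
            if not col[index[rid]]:
                raise CoverageError(remaining_high)
            trace.n_fallback_columns += 1
            scores = score_columns(
                col[:, None], medium_mask, low_mask, params.low_weight
            )
            add_column(col, -1, scores[0])
            continue
        scores = score_columns(activity, medium_mask, low_mask, params.low_weight)
        scores = np.where(has_high, scores, -np.inf)
        best = int(np.argmax(scores))
        add_column(activity[:, best].copy(), best, scores[best])

    # Phase 2: grow while the best score is positive.
    while True:
        scores = score_columns(activity, medium_mask, low_mask, params.low_weight)
        best = int(np.argmax(scores)) if scores.size else 0
        if not scores.size or scores[best] <= 0:
            break
        add_column(activity[:, best].copy(), best, scores[best])
    return final, trace


@dataclass
class ExtractionResult:
    """Extracted model plus the convergence trajectory."""

    network: MetabolicNetwork
    reactions: set[str]
    iterations: int
    sizes: list[tuple[int, int]]  # (n_reactions, n_metabolites) per iteration
    objective_score: float
    traces: list[_GreedyTrace]

    @property
    def converged(self) -> bool:
        return True


def extract_mcl(
    net: MetabolicNetwork,
    tiers: ConfidenceTiers,
    params: ExtractionParams | None = None,
    seed: int | None = None,
) -> ExtractionResult:
    """Run the full MCL extraction until the model size stops changing.

    ``net`` should be flux-consistent (dead ends removed) before extraction.
    Each outer iteration samples a fresh flux-distribution matrix on the
    current model scope, re-runs coverage and growth from scratch, and the
    loop stops when the reaction count repeats.  Raises
    :class:`ConvergenceError` after ``max_outer_iterations`` without a fixed
    point and :class:`CoverageError` if a high-confidence reaction can carry
    no flux.
    """
    params = params or ExtractionParams()
    rng = np.random.default_rng(seed)
    missing = tiers.high - set(net.reactions)
    if missing:
        raise CoverageError(missing)
    current = net
    sizes: list[tuple[int, int]] = []
    traces: list[_GreedyTrace] = []
    prev_n = None
    for _ in range(params.max_outer_iterations):
        scoped = tiers.restrict(current.reactions)
        system = LPSystem.from_network(current)
        matrix = build_fd_matrix(system, scoped, params.n_columns, rng, params)
        final, trace = greedy_select(matrix, scoped, params, system)
        traces.append(trace)
        extracted = net.subnetwork(final, name=f"{net.name}[mcl]")
        sizes.append((len(extracted.reactions), len(extracted.metabolites)))
        log.info("extraction iteration %d: %d reactions, %d metabolites",
                 len(sizes), *sizes[-1])
        if prev_n is not None and len(final) == prev_n:
            return ExtractionResult(
                network=extracted,
                reactions=final,
                iterations=len(sizes),
                sizes=sizes,
                objective_score=score_of_set(final, tiers, params.low_weight),
                traces=traces,
            )
        prev_n = len(final)
        current = extracted
    raise ConvergenceError(sizes)
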