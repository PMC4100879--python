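"""MCL extraction: scoring, coverage, growth, convergence, optimality."""

import numpy as np
import pytest

from mclx.extract import (
    CoverageError,
    ExtractionParams,
    FluxDistributionMatrix,
    build_fd_matrix,
    extract_mcl,
    greedy_select,
    random_objective,
    score_columns,
    score_of_set,
)
from mclx.fixtures import ToyNetworkSpec, make_toy_network, random_toy_spec
from mclx.network import ConfidenceTiers
from mclx.reference import optimal_extraction_by_enumeration

from conftest import make_net


def _tiers(high=(), medium=(), low=()):
    return ConfidenceTiers(high=set(high), medium=set(medium), low=set(low))


# -- random objectives ------------------------------------------------------

def test_random_objective_support_and_weights():
    tiers = _tiers(high={"r1"}, medium={"r2"}, low={"r3", "r4"})
    rng = np.random.default_rng(0)
    obj = random_objective(tiers, rng, k=2)
    assert obj == {"r1": 1.0, "r2": 1.0}  # only possible draw


def test_random_objective_never_touches_low_tier():
    tiers = _tiers(high={"h1", "h2"}, medium={"m1", "m2"}, low={"x1", "x2"})
    rng = np.random.default_rng(1)
    for _ in range(200):
        assert not set(random_objective(tiers, rng, k=3)) & tiers.low


def test_random_objective_is_seed_deterministic():
    tiers = _tiers(high={"h1", "h2"}, medium={"m1", "m2", "m3"})
    r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
    seq1 = [random_objective(tiers, r1, 2) for _ in range(20)]
    seq2 = [random_objective(tiers, r2, 2) for _ in range(20)]
    assert seq1 == seq2


def test_random_objective_empty_pool_is_error():
    with pytest.raises(ValueError, match="both empty"):
        random_objective(_tiers(low={"r1"}), np.random.default_rng(0))


# -- fdMatrix ---------------------------------------------------------------

def test_fd_matrix_single_pathway_pattern(chain_net):
    tiers = ConfidenceTiers.from_assignment(chain_net, high={"R1"})
    matrix = build_fd_matrix(chain_net, tiers, n_columns=5,
                             rng=np.random.default_rng(0),
                             params=ExtractionParams(n_columns=5, k=1))
    # the only flux route activates all three reactions
    active = {frozenset(np.array(matrix.rxn_ids)[col])
              for col in matrix.activity.T.astype(bool) if col.any()}
    assert active == {frozenset({"EX_in", "R1", "EX_out"})}
    assert matrix.n_columns == 5


def test_fd_matrix_rejects_zero_columns(chain_net):
    tiers = ConfidenceTiers.from_assignment(chain_net, high={"R1"})
    with pytest.raises(ValueError):
        build_fd_matrix(chain_net, tiers, 0, np.random.default_rng(0))


def test_fd_matrix_infeasible_net_gives_zero_columns_logged():
    net = make_net([("R", "1 X[c] -> 1 Y[c]", 1, 10)])
    tiers = ConfidenceTiers.from_assignment(net, high={"R"})
    matrix = build_fd_matrix(net, tiers, 4, np.random.default_rng(0))
    assert not matrix.activity.any()
    assert matrix.n_degenerate == 4


# -- column scoring ---------------------------------------------------------

def test_score_formula_on_stated_arithmetic():
    # 3 active medium + 4 active low -> 3 - 0.5*4 = 1.0
    activity = np.ones((7, 1), dtype=bool)
    medium = np.array([1, 1, 1, 0, 0, 0, 0], dtype=float)
    low = np.array([0, 0, 0, 1, 1, 1, 1], dtype=float)
    assert score_columns(activity, medium, low)[0] == pytest.approx(1.0)
    assert score_columns(np.zeros((7, 1), bool), medium, low)[0] == 0.0
    # the low-tier weight is exactly one half
    assert score_columns(activity, medium, low, low_weight=0.5)[0] == 1.0


# -- greedy coverage and growth ---------------------------------------------

def _manual_matrix(rxn_ids, columns):
    activity = np.zeros((len(rxn_ids), len(columns)), dtype=bool)
    index = {r: i for i, r in enumerate(rxn_ids)}
    for j, col in enumerate(columns):
        for rid in col:
            activity[index[rid], j] = True
    return FluxDistributionMatrix(activity=activity, rxn_ids=list(rxn_ids),
                                  objectives=[() for _ in columns])


def test_cover_all_high_single_column():
    rxns = ["a", "b", "c"]
    matrix = _manual_matrix(rxns, [{"a", "b", "c"}])
    final, trace = greedy_select(matrix, _tiers(high=set(rxns)),
                                 ExtractionParams(n_columns=1))
    assert final == set(rxns)
    assert trace.selected_columns == [0]


def test_two_disjoint_pathways_both_selected():
    rxns = ["h1", "m1", "h2", "x1"]
    matrix = _manual_matrix(rxns, [{"h1", "m1"}, {"h2", "x1"}])
    final, trace = greedy_select(
        matrix, _tiers(high={"h1", "h2"}, medium={"m1"}, low={"x1"}),
        ExtractionParams(n_columns=2),
    )
    assert final == set(rxns)
    # the medium-rewarded column scores higher and is taken first
    assert trace.selected_columns == [0, 1]


def test_added_rows_are_zeroed_and_growth_stops_at_nonpositive():
    rxns = ["h1", "m1", "m2", "x1", "x2", "x3"]
    cols = [
        {"h1", "m1"},            # coverage pick
        {"m1", "m2", "x1"},      # after zeroing m1: 1 - 0.5 = 0.5 > 0 -> added
        {"x2", "x3"},            # score -1: never added
    ]
    matrix = _manual_matrix(rxns, cols)
    final, trace = greedy_select(
        matrix, _tiers(high={"h1"}, medium={"m1", "m2"},
                       low={"x1", "x2", "x3"}),
        ExtractionParams(n_columns=3),
    )
    assert final == {"h1", "m1", "m2", "x1"}
    assert trace.selected_scores == pytest.approx([1.0, 0.5])


def test_growth_noop_when_all_scores_nonpositive():
    rxns = ["h1", "x1", "x2"]
    matrix = _manual_matrix(rxns, [{"h1"}, {"x1", "x2"}])
    final, _ = greedy_select(matrix, _tiers(high={"h1"}, low={"x1", "x2"}),
                             ExtractionParams(n_columns=2))
    assert final == {"h1"}


def test_uncoverable_high_reaction_raises_with_ids():
    rxns = ["h1", "m1"]
    matrix = _manual_matrix(rxns, [{"m1"}])
    with pytest.raises(CoverageError) as err:
        greedy_select(matrix, _tiers(high={"h1"}, medium={"m1"}),
                      ExtractionParams(n_columns=1))
    assert "h1" in str(err.value)


# -- full extraction --------------------------------------------------------

def test_all_high_network_is_returned_whole(chain_net):
    tiers = ConfidenceTiers.from_assignment(chain_net,
                                            high=set(chain_net.reactions))
    result = extract_mcl(chain_net, tiers,
                         ExtractionParams(n_columns=20), seed=0)
    assert result.reactions == set(chain_net.reactions)
    assert result.objective_score == 0.0


def test_extraction_drops_low_pathway_keeps_medium():
    toy = make_toy_network(ToyNetworkSpec(lengths=(3, 3),
                                          tier_plan=("medium", "low")))
    result = extract_mcl(toy.network, toy.tiers,
                         ExtractionParams(n_columns=100), seed=1)
    assert result.reactions == toy.optimal_reactions
    assert result.objective_score == pytest.approx(3.0)  # 3 medium, 0 low


def test_extraction_seed_determinism():
    toy = make_toy_network(ToyNetworkSpec(lengths=(2, 3, 2),
                                          tier_plan=("medium", "low", "high")))
    params = ExtractionParams(n_columns=60)
    a = extract_mcl(toy.network, toy.tiers, params, seed=9)
    b = extract_mcl(toy.network, toy.tiers, params, seed=9)
    assert a.reactions == b.reactions
    assert a.sizes == b.sizes


def test_extraction_monotone_sizes_and_report():
    toy = make_toy_network(ToyNetworkSpec(lengths=(3, 3),
                                          tier_plan=("medium", "low")))
    result = extract_mcl(toy.network, toy.tiers,
                         ExtractionParams(n_columns=80), seed=3)
    assert result.iterations == len(result.sizes) >= 2
    # across outer iterations the model never grows
    counts = [n for n, _ in result.sizes]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


@pytest.mark.parametrize("seed", range(5))
def test_extraction_matches_enumeration_optimum(seed):
    """Greedy extraction attains the exhaustive-search objective optimum."""
    toy = make_toy_network(random_toy_spec(seed + 50))
    opt_set, opt_score = optimal_extraction_by_enumeration(toy.network, toy.tiers)
    result = extract_mcl(toy.network, toy.tiers,
                         ExtractionParams(n_columns=200), seed=seed)
    assert result.objective_score == pytest.approx(opt_score)
    assert toy.tiers.high <= result.reactions


def test_high_tier_flux_consistent_in_output():
    from mclx.lp import find_blocked

    toy = make_toy_network(ToyNetworkSpec(lengths=(2, 2),
                                          tier_plan=("low", "low")))
    result = extract_mcl(toy.network, toy.tiers,
                         ExtractionParams(n_columns=80), seed=2)
    blocked = find_blocked(result.network)
    assert not (toy.tiers.high & blocked)


def test_replicate_model_sizes_agree_within_ten_percent():
    """Robustness: replicate extractions from different seeds are similar."""
    toy = make_toy_network(ToyNetworkSpec(lengths=(3, 2, 3),
                                          tier_plan=("medium", "medium", "low")))
    sizes = []
    for seed in range(5):
        res = extract_mcl(toy.network, toy.tiers,
                          ExtractionParams(n_columns=150), seed=seed)
        sizes.append(len(res.reactions))
    assert max(sizes) <= 1.1 * min(sizes)
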