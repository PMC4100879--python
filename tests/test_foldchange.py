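"""Fold-change perturbation: statuses, bound protocol, calls, t-scores."""

import math

import numpy as np
import pandas as pd
import pytest

from mclx.directions import DECREASED, INCREASED, UNCHANGED, DirectionCall, normalized_delta
from mclx.fixtures import make_catabolism_fixture, synthetic_expression
from mclx.foldchange import (
    GeneFoldChange,
    aggregate_transport_deltas,
    call_flux_directions,
    gene_directions,
    perturb_bounds,
    reaction_status,
    reaction_statuses,
    read_foldchange_table,
    subsystem_tscores,
)
from mclx.network import Reaction

from conftest import make_net


def _records(*pairs):
    return [GeneFoldChange(g, d, 2.0 if d > 0 else 0.5, 0.01) for g, d in pairs]


# -- regulation statuses ----------------------------------------------------

def test_single_up_gene_simple_rule():
    rxn = Reaction("R", {}, gpr="g1")
    status = reaction_status(rxn, gene_directions(_records(("g1", 1))))
    assert status.status == 1
    assert status.genes == ("g1",)


def test_probe_majority_vote_on_same_gene():
    # 2 up + 1 down records for one gene id -> up
    dirs = gene_directions(_records(("g1", 1), ("g1", 1), ("g1", -1)))
    assert dirs == {"g1": 1}
    # exact tie -> unchanged
    assert gene_directions(_records(("g2", 1), ("g2", -1))) == {"g2": 0}


def test_distinct_genes_combine_through_gpr_logic():
    dirs = {"g_up": 1, "g_down": -1}
    assert reaction_status(Reaction("R", {}, gpr="g_up and g_down"), dirs).status == -1
    assert reaction_status(Reaction("R", {}, gpr="g_up or g_down"), dirs).status == 1


def test_reaction_without_mapped_gene_is_unchanged():
    status = reaction_status(Reaction("R", {}, gpr="g9"), {"g1": 1})
    assert status.status == 0
    assert status.rule == "no mapped DE gene"


def test_foldchange_table_filter(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tlog2_fold_change\tp_value\n"
        "keep_up\t1.0\t0.01\n"
        "keep_down\t-0.8\t0.001\n"
        "weak_fc\t0.2\t0.001\n"      # |fc| < 1.5
        "weak_p\t2.0\t0.2\n"          # p >= 0.05
    )
    records = read_foldchange_table(path)
    assert {r.gene: r.direction for r in records} == {"keep_up": 1, "keep_down": -1}


# -- bound protocol ---------------------------------------------------------

@pytest.fixture
def status_net():
    return make_net(
        [
            ("SRC_A", "-> 1 A[e]", 0, 1000),
            ("T_A", "1 A[e] -> 1 A[c]", -1000, 1000),
            ("R_up", "1 A[c] <=> 1 B[c]", -1000, 1000, "g_up"),
            ("R_down", "1 B[c] -> 1 C[c]", 0, 1000, "g_down"),
            ("T_C", "1 C[c] -> 1 C[e]", 0, 1000),
            ("EX_C", "1 C[e] ->", 0, 1000),
        ]
    )


def test_perturb_bounds_protocol(status_net):
    statuses = reaction_statuses(
        status_net, gene_directions(_records(("g_up", 1), ("g_down", -1)))
    )
    control, disease = perturb_bounds(status_net, statuses)
    # affected reactions shrink to a tenth of the normal magnitude
    assert (control.reactions["R_up"].lower_bound,
            control.reactions["R_up"].upper_bound) == (-100.0, 100.0)
    assert (control.reactions["R_down"].lower_bound,
            control.reactions["R_down"].upper_bound) == (0.0, 100.0)
    # unaffected reactions keep normal bounds
    assert (control.reactions["T_A"].lower_bound,
            control.reactions["T_A"].upper_bound) == (-1000.0, 1000.0)
    # exchanges pinned to [1, 1000] in both models
    for model in (control, disease):
        for ex in ("SRC_A", "EX_C"):
            assert (model.reactions[ex].lower_bound,
                    model.reactions[ex].upper_bound) == (1.0, 1000.0)
    # disease: up doubled, down halved
    assert (disease.reactions["R_up"].lower_bound,
            disease.reactions["R_up"].upper_bound) == (-200.0, 200.0)
    assert (disease.reactions["R_down"].lower_bound,
            disease.reactions["R_down"].upper_bound) == (0.0, 50.0)


def test_all_unchanged_statuses_give_all_unchanged_calls(status_net):
    statuses = reaction_statuses(status_net, {})
    control, disease = perturb_bounds(status_net, statuses)
    calls, deltas = call_flux_directions(control, disease, "all", epsilon=0.01)
    assert all(c.call == UNCHANGED for c in calls)
    assert (deltas.abs() < 1e-9).all()


def test_delta_arithmetic_on_decided_formula():
    # bounds (0,10) -> (0,20): delta = 10 / 7.5
    assert normalized_delta(0, 10, 0, 20) == pytest.approx(10 / 7.5)


def test_scaling_all_bounds_preserves_calls(status_net):
    """The normalized delta is scale-free: scaling every bound by a common
    factor scales the FVA intervals identically and keeps every call."""
    statuses = reaction_statuses(
        status_net, gene_directions(_records(("g_down", -1)))
    )
    control, disease = perturb_bounds(status_net, statuses)
    calls1, deltas1 = call_flux_directions(control, disease, "all", epsilon=0.1)
    for model in (control, disease):
        for rxn in model.reactions.values():
            rxn.lower_bound *= 3.0
            rxn.upper_bound *= 3.0
    calls2, deltas2 = call_flux_directions(control, disease, "all", epsilon=0.1)
    assert [c.call for c in calls1] == [c.call for c in calls2]
    assert np.allclose(deltas1.to_numpy(), deltas2.to_numpy(), atol=1e-7)


# -- planted catabolism fixture --------------------------------------------

def test_planted_down_catabolism_accumulates_substrate():
    """Halving the sole catabolic chain's bounds shrinks uptake of V: the
    uptake-oriented transporter's summed delta is negative (reduced
    clearance from blood, extracellular accumulation)."""
    net, planted, subsystem_of = make_catabolism_fixture()
    records = _records(*[(g, -1) for g in planted])
    statuses = reaction_statuses(net, gene_directions(records))
    control, disease = perturb_bounds(net, statuses)
    calls, deltas = call_flux_directions(control, disease, "all", epsilon=0.1)
    agg = {c.item: c for c in aggregate_transport_deltas(net, deltas, 0.1)}
    assert agg["V"].delta < 0
    assert agg["V"].call == DECREASED
    # hand LP: chain flux in [1,100] control vs [1,50] disease, delta -50/38
    expected = normalized_delta(1.0, 100.0, 1.0, 50.0)
    assert agg["V"].delta == pytest.approx(expected)
    ts = {s.subsystem: s for s in subsystem_tscores(calls, subsystem_of, seed=11)}
    assert ts["V degradation"].t_score < 0
    assert ts["V degradation"].n_down == ts["V degradation"].n_reactions


def test_end_to_end_from_synthetic_expression_table(tmp_path):
    """Planted DE table -> filter -> statuses -> bounds -> negative delta."""
    net, planted, _ = make_catabolism_fixture()
    gene_map = {rid: r.gpr for rid, r in net.reactions.items() if r.gpr}
    table = synthetic_expression(gene_map, planted, n_noise_genes=10, seed=4)
    path = tmp_path / "expr.tsv"
    table.to_csv(path, sep="\t", index=False)
    records = read_foldchange_table(path)
    assert {r.gene for r in records} == set(planted)  # noise filtered out
    statuses = reaction_statuses(net, gene_directions(records))
    control, disease = perturb_bounds(net, statuses)
    _, deltas = call_flux_directions(control, disease, "transport", epsilon=0.1)
    agg = {c.item: c for c in aggregate_transport_deltas(net, deltas, 0.1)}
    assert agg["V"].call == DECREASED


# -- subsystem t-scores -----------------------------------------------------

def _calls(codes):
    name = {-1: DECREASED, 0: UNCHANGED, 1: INCREASED}
    return [DirectionCall(f"r{i}", name[c], float(c), 0.1)
            for i, c in enumerate(codes)]


def test_tiny_all_down_subsystem_scores_weak():
    """Two all-down reactions are matched by chance 1/9 of the time, so the
    t-score magnitude stays small."""
    calls = _calls([-1, -1])
    scores = subsystem_tscores(calls, {"r0": "S", "r1": "S"}, seed=3)
    assert abs(scores[0].t_score) < 3


def test_large_all_down_subsystem_scores_strongly_negative():
    calls = _calls([-1] * 30)
    sub = {f"r{i}": "S" for i in range(30)}
    scores = subsystem_tscores(calls, sub, seed=0)
    assert scores[0].t_score < -5


def test_balanced_subsystem_scores_near_zero():
    calls = _calls([1, -1] * 15)
    sub = {f"r{i}": "S" for i in range(30)}
    scores = subsystem_tscores(calls, sub, seed=0)
    assert abs(scores[0].t_score) < 2


def test_singleton_subsystem_reports_missing_t():
    scores = subsystem_tscores(_calls([1]), {"r0": "S"}, seed=0)
    assert math.isnan(scores[0].t_score)
    assert scores[0].n_reactions == 1


def test_t_sign_matches_call_balance_for_large_subsystems():
    rng = np.random.default_rng(12)
    for _ in range(10):
        n_up = int(rng.integers(0, 13))
        codes = [1] * n_up + [-1] * (12 - n_up)
        if n_up == 6:
            continue
        scores = subsystem_tscores(_calls(codes),
                                   {f"r{i}": "S" for i in range(12)},
                                   seed=int(rng.integers(0, 1000)))
        s = scores[0]
        if abs(s.t_score) > 1:  # sign is only meaningful away from 0
            assert np.sign(s.t_score) == np.sign(s.n_up - s.n_down)


def test_down_calls_dominate_up_calls_on_mixed_networks():
    """A single downregulated step throttles a whole pathway, while an
    upregulated step cannot force higher flux through unchanged neighbours,
    so down calls outnumber up calls on balanced perturbations."""
    from mclx.fixtures import ToyNetworkSpec, make_toy_network

    wins = 0
    n_trials = 50
    for seed in range(n_trials):
        rng = np.random.default_rng(seed + 1000)
        n_path = int(rng.integers(2, 4))
        toy = make_toy_network(ToyNetworkSpec(
            lengths=tuple(int(rng.integers(2, 4)) for _ in range(n_path)),
            tier_plan=tuple("medium" for _ in range(n_path)),
        ))
        net = toy.network
        genes = sorted(toy.gene_map.values())
        # balanced perturbation: every enzyme flips a fair coin
        records = _records(*[(g, 1 if rng.random() < 0.5 else -1)
                             for g in genes])
        statuses = reaction_statuses(net, gene_directions(records))
        control, disease = perturb_bounds(net, statuses)
        calls, _ = call_flux_directions(control, disease, "all", epsilon=0.05)
        n_down = sum(c.call == DECREASED for c in calls)
        n_up = sum(c.call == INCREASED for c in calls)
        wins += n_down >= n_up
    assert wins >= 0.8 * n_trials
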