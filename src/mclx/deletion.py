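"""In-silico gene-deletion biomarker prediction (OMIM-style validation).

For a disorder defined by a set of causal genes, the affected reactions are
those whose GPR rule can no longer be satisfied once the genes are deleted.
Two models are then compared:

* **reference** -- the healthy network, with the affected reactions forced
  on (lower bound set to 1) so that the contrast against their removal is
  maximal: if zero flux were still allowed, the healthy model might simply
  not use them and the knockout would show nothing;
* **disease** -- the network with the affected reactions removed.

FVA over the exchange reactions yields boundary flux intervals for both
models; the normalized bound change per exchange is thresholded at
``+/- epsilon`` into concentration direction calls (an exchange written in
secretion orientation accumulates its metabolite in the blood compartment
when its flux bounds shift upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import gpr as gpr_mod
from .directions import DirectionCall, call_from_delta, delta_table
from .lp import InfeasibleModelError, LPSystem
from .network import MetabolicNetwork

__all__ = [
    "DisorderSpec",
    "DeletionResult",
    "genes_to_reactions",
    "run_deletion",
    "read_disorder_table",
]


@dataclass
class DisorderSpec:
    """A disorder: causal genes plus (optionally) the known phenotype as
    direction calls on boundary metabolites/exchanges."""

    name: str
    genes: set[str]
    phenotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"disorder {self.name!r} has no genes")


@dataclass
class DeletionResult:
    disorder: str
    simulable: bool
    affected_reactions: set[str]
    calls: list[DirectionCall] = field(default_factory=list)
    deltas: pd.Series | None = None
    reason: str = ""


def genes_to_reactions(net: MetabolicNetwork, genes) -> set[str]:
    """Reactions disabled by deleting ``genes``.

    Full Boolean GPR evaluation, not mere gene mention: a reaction is
    affected only when its rule evaluates False with the listed genes absent
    and all other genes present (so an OR-isozyme rescues it).
    """
    deleted = set(genes)
    affected = set()
    for rid, rxn in net.reactions.items():
        tree = gpr_mod.parse_gpr(rxn.gpr)
        if tree is None:
            continue
        if not gpr_mod.eval_bool(tree, lambda g: g not in deleted):
            affected.add(rid)
    return affected


def run_deletion(
    net: MetabolicNetwork,
    disorder: DisorderSpec,
    epsilon: float,
    forced_lower_bound: float = 1.0,
) -> DeletionResult:
    """Simulate one disorder and call exchange-flux directions.

    Returns a non-simulable result (``simulable=False``) instead of raising
    when forcing the affected reactions on leaves no feasible steady state;
    such disorders are excluded from ROC scoring.
    """
    affected = genes_to_reactions(net, disorder.genes)
    scope = [r for r in net.exchange_ids() if r not in affected]
    if not affected:
        deltas = pd.Series(0.0, index=scope, name="delta")
        calls = [DirectionCall(r, call_from_delta(0.0, epsilon), 0.0, epsilon)
                 for r in scope]
        return DeletionResult(disorder.name, True, affected, calls, deltas,
                              reason="no reactions mapped to disorder genes")

    reference = net.copy()
    for rid in affected:
        rxn = reference.reactions[rid]
        # forced on unconditionally, overriding a negative lower bound
        rxn.lower_bound = forced_lower_bound
        if rxn.upper_bound < rxn.lower_bound:
            return DeletionResult(
                disorder.name, False, affected,
                reason=f"reaction {rid} cannot reach the forced bound",
            )
    disease = net.subnetwork([r for r in net.reactions if r not in affected])

    try:
        ref_bounds = LPSystem.from_network(reference).variability(scope)
    except InfeasibleModelError:
        return DeletionResult(
            disorder.name, False, affected,
            reason="reference model infeasible after forcing affected reactions on",
        )
    try:
        dis_bounds = LPSystem.from_network(disease).variability(scope)
    except InfeasibleModelError:
        return DeletionResult(
            disorder.name, False, affected,
            reason="disease model infeasible after reaction removal",
        )
    deltas = delta_table(ref_bounds, dis_bounds)
    calls = [
        DirectionCall(rid, call_from_delta(d, epsilon), float(d), epsilon)
        for rid, d in deltas.items()
    ]
    return DeletionResult(disorder.name, True, affected, calls, deltas)


_ARROW = {"+": "increased", "-": "decreased", "0": "unchanged"}


def read_disorder_table(path) -> list[DisorderSpec]:
    """Read a tab-separated disorder table.

    Columns: disorder_name, comma-separated gene list, optional phenotype
    column of ``metabolite:+|-|0`` entries separated by commas.
    """
    disorders = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected disorder_name<TAB>genes"
                )
            name = fields[0].strip()
            genes = {g.strip() for g in fields[1].split(",") if g.strip()}
            phenotype = {}
            if len(fields) > 2 and fields[2].strip():
                for entry in fields[2].split(","):
                    met, _, arrow = entry.strip().rpartition(":")
                    if arrow not in _ARROW:
                        raise ValueError(
                            f"{path}:{lineno}: bad phenotype entry {entry!r}"
                        )
                    phenotype[met] = _ARROW[arrow]
            disorders.append(DisorderSpec(name=name, genes=genes, phenotype=phenotype))
    return disorders
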