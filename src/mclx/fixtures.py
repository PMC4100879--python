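"""Synthetic toy fixtures with planted ground truth.

Every stage of the pipeline is testable offline: this module generates toy
metabolic networks (parallel linear pathways through a shared extracellular
compartment), confidence tiers with a known optimal extraction, planted
differential-expression tables, and loads the two packaged reference
tables (the 20-amino-acid direction table and the OMIM disorder gene
lists).

Toy network layout
------------------
All pathways convert one shared extracellular source species ``S[e]`` into
one shared sink species ``P[e]`` through pathway-private cytosolic
intermediates.  The two boundary exchanges (uptake of S, secretion of P)
are high-confidence; each pathway's internal reactions are assigned a tier
by the spec's plan.  The optimal extraction therefore keeps the exchanges,
every high/medium pathway, and drops low pathways -- unless no high/medium
pathway exists, in which case the cheapest low pathway is forced in to give
the high-confidence exchanges a feasible flux route.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deletion import DisorderSpec
from .evaluation import ARROW_TO_CALL
from .network import ConfidenceTiers, MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "ToyNetworkSpec",
    "ToyNetwork",
    "make_toy_network",
    "random_toy_spec",
    "make_deletion_fixture",
    "make_catabolism_fixture",
    "synthetic_expression",
    "table2_fixture",
    "table2_directions",
    "omim_disorders",
]

TIERS = ("high", "medium", "low")


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Blueprint for a parallel-pathway toy network.

    ``lengths[p]`` is the number of internal reactions in pathway p and
    ``tier_plan[p]`` the confidence tier of all of them.  The shared uptake
    and secretion exchanges are always high confidence.
    """

    lengths: tuple[int, ...]
    tier_plan: tuple[str, ...]
    planted: dict[str, str] = field(default_factory=dict)  # gene -> up|down
    seed: int = 0

    def __post_init__(self):
        if not self.lengths:
            raise ValueError("spec needs at least one pathway")
        if any(l < 1 for l in self.lengths):
            raise ValueError("pathway lengths must be >= 1")
        if len(self.tier_plan) != len(self.lengths):
            raise ValueError("tier_plan and lengths must align")
        if any(t not in TIERS for t in self.tier_plan):
            raise ValueError(f"tiers must be among {TIERS}")


@dataclass
class ToyNetwork:
    network: MetabolicNetwork
    tiers: ConfidenceTiers
    gene_map: dict[str, str]  # reaction id -> gene id
    optimal_reactions: set[str]
    optimal_score: float
    pathway_reactions: dict[int, list[str]]


def _pathway_ids(p: int, length: int) -> list[str]:
    return [f"P{p}_R{k}" for k in range(1, length + 1)]


def make_toy_network(spec: ToyNetworkSpec) -> ToyNetwork:
    """Build the network, tiers and planted extraction optimum for a spec."""
    net = MetabolicNetwork(name=f"toy[{'-'.join(map(str, spec.lengths))}]")
    src = net.add_metabolite(Metabolite("S", "e"))
    sink = net.add_metabolite(Metabolite("P", "e"))
    # dietary supply written in source orientation so the exchange protocol
    # ([1, 1000] in the written direction) keeps the network feasible
    net.add_reaction(
        Reaction("EX_S", {src.id: 1.0}, lower_bound=0.0, upper_bound=1000.0,
                 subsystem="exchange")
    )
    net.add_reaction(
        Reaction("EX_P", {sink.id: -1.0}, lower_bound=0.0, upper_bound=1000.0,
                 subsystem="exchange")
    )
    gene_map: dict[str, str] = {}
    pathway_reactions: dict[int, list[str]] = {}
    tier_sets: dict[str, set[str]] = {t: set() for t in TIERS}
    tier_sets["high"] |= {"EX_S", "EX_P"}
    for p, (length, tier) in enumerate(zip(spec.lengths, spec.tier_plan), start=1):
        ids = _pathway_ids(p, length)
        pathway_reactions[p] = ids
        mets = [src.id]
        for k in range(1, length):
            mets.append(net.add_metabolite(Metabolite(f"P{p}_M{k}", "c")).id)
        mets.append(sink.id)
        for k, rid in enumerate(ids):
            gene = f"g_{rid}"
            gene_map[rid] = gene
            net.add_reaction(
                Reaction(
                    rid,
                    {mets[k]: -1.0, mets[k + 1]: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    gpr=gene,
                    subsystem=f"pathway_{p}",
                )
            )
            tier_sets[tier].add(rid)
    tiers = ConfidenceTiers.from_assignment(
        net, high=tier_sets["high"], medium=tier_sets["medium"], low=tier_sets["low"]
    )
    kept = [
        p
        for p, tier in enumerate(spec.tier_plan, start=1)
        if tier in ("high", "medium")
    ]
    if not kept:
        # the high-confidence exchanges need one flux route: cheapest low pathway
        order = sorted(range(1, len(spec.lengths) + 1),
                       key=lambda p: (spec.lengths[p - 1], p))
        kept = [order[0]]
    optimal = {"EX_S", "EX_P"} | {
        rid for p in kept for rid in pathway_reactions[p]
    }
    score = sum(
        spec.lengths[p - 1]
        * {"high": 0.0, "medium": 1.0, "low": -0.5}[spec.tier_plan[p - 1]]
        for p in kept
    )
    return ToyNetwork(
        network=net,
        tiers=tiers,
        gene_map=gene_map,
        optimal_reactions=optimal,
        optimal_score=score,
        pathway_reactions=pathway_reactions,
    )


def random_toy_spec(seed: int, max_pathways: int = 3, max_length: int = 3) -> ToyNetworkSpec:
    """Draw a small random spec (network stays within ~12 reactions)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_pathways + 1))
    lengths = tuple(int(rng.integers(1, max_length + 1)) for _ in range(n))
    # at least one high/medium pathway is drawn with prob ~1; allow all-low too
    plan = tuple(str(rng.choice(TIERS)) for _ in range(n))
    return ToyNetworkSpec(lengths=lengths, tier_plan=plan, seed=seed)


def make_deletion_fixture() -> tuple[MetabolicNetwork, DisorderSpec]:
    """Small network where the disorder gene's reaction is the sole consumer
    of an internal metabolite; removing it frees the metabolite's secretion.

    Topology: S is taken up and converted to P in the cytosol; P is either
    secreted to the blood (transport + exchange) or consumed toward Q by the
    gene-gX reaction.  Deleting gX leaves secretion as P's only fate, so the
    P exchange flux interval widens upward.
    """
    net = MetabolicNetwork(name="deletion-toy")
    for species, comp in [("S", "e"), ("P", "c"), ("P", "e"), ("Q", "e")]:
        net.add_metabolite(Metabolite(species, comp))
    net.add_reaction(Reaction("EX_S", {"S[e]": -1.0}, -1000.0, 0.0,
                              subsystem="exchange"))
    net.add_reaction(Reaction("R_SP", {"S[e]": -1.0, "P[c]": 1.0}, 0.0, 1000.0,
                              gpr="gS", subsystem="synthesis"))
    net.add_reaction(Reaction("R_PQ", {"P[c]": -1.0, "Q[e]": 1.0}, 0.0, 1000.0,
                              gpr="gX", subsystem="catabolism"))
    net.add_reaction(Reaction("T_P", {"P[c]": -1.0, "P[e]": 1.0}, 0.0, 1000.0,
                              subsystem="transport"))
    net.add_reaction(Reaction("EX_P", {"P[e]": -1.0}, 0.0, 1000.0,
                              subsystem="exchange"))
    net.add_reaction(Reaction("EX_Q", {"Q[e]": -1.0}, 0.0, 1000.0,
                              subsystem="exchange"))
    disorder = DisorderSpec(name="toy disorder", genes={"gX"},
                            phenotype={"EX_P": "increased"})
    return net, disorder


CATABOLIC_CHAIN_LENGTH = 6


def make_catabolism_fixture() -> tuple[MetabolicNetwork, dict[str, str], dict[str, str]]:
    """Planted down-catabolism fixture for the fold-change pipeline.

    The amino acid V enters the blood compartment from a dietary source
    exchange, is taken up into the cytosol by an uptake-oriented transporter
    and degraded to W by the sole catabolic chain (subsystem
    ``V degradation``), whose product leaves through transport and exchange.
    Every chain gene is planted *down*.  Halving the chain's bounds shrinks
    the flux interval of every chain reaction and of the V transporter:
    the transporter's summed delta goes negative, meaning reduced clearance
    of V from the blood, i.e. extracellular accumulation of V.

    Returns (network, planted gene directions, reaction -> subsystem map).
    """
    net = MetabolicNetwork(name="catabolism-toy")
    net.add_metabolite(Metabolite("V", "e"))
    net.add_metabolite(Metabolite("V", "c"))
    net.add_metabolite(Metabolite("W", "c"))
    net.add_metabolite(Metabolite("W", "e"))
    net.add_reaction(Reaction("SRC_V", {"V[e]": 1.0}, 0.0, 1000.0,
                              subsystem="exchange"))
    net.add_reaction(Reaction("T_V", {"V[e]": -1.0, "V[c]": 1.0}, -1000.0, 1000.0,
                              subsystem="transport"))
    chain_mets = ["V[c]"]
    for k in range(1, CATABOLIC_CHAIN_LENGTH):
        chain_mets.append(net.add_metabolite(Metabolite(f"I{k}", "c")).id)
    chain_mets.append("W[c]")
    planted: dict[str, str] = {}
    for k in range(CATABOLIC_CHAIN_LENGTH):
        rid = f"C{k + 1}"
        net.add_reaction(
            Reaction(rid, {chain_mets[k]: -1.0, chain_mets[k + 1]: 1.0},
                     0.0, 1000.0, gpr=f"g_{rid}", subsystem="V degradation")
        )
        planted[f"g_{rid}"] = "down"
    net.add_reaction(Reaction("T_W", {"W[c]": -1.0, "W[e]": 1.0}, 0.0, 1000.0,
                              subsystem="transport"))
    net.add_reaction(Reaction("EX_W", {"W[e]": -1.0}, 0.0, 1000.0,
                              subsystem="exchange"))
    subsystem_of = {rid: rxn.subsystem for rid, rxn in net.reactions.items()}
    return net, planted, subsystem_of


def synthetic_expression(
    gene_map: dict[str, str],
    planted: dict[str, str],
    n_noise_genes: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate a significance-filtered DE gene table with planted signals.

    Planted genes receive |log2FC| >= log2(1.5) with the planted sign and
    p < 0.05; noise genes receive sub-threshold records that the upstream
    filter (p < 0.05 and fold change > 1.5) removes.  Output columns:
    gene_id, log2_fold_change, p_value.
    """
    genes = set(gene_map.values()) if gene_map else set()
    unknown = set(planted) - genes if genes else set()
    if unknown:
        raise ValueError(f"planted genes not in gene map: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(planted):
        direction = planted[gene]
        if direction not in ("up", "down"):
            raise ValueError(f"planted direction must be up/down, got {direction!r}")
        magnitude = math.log2(1.5) + float(rng.uniform(0.2, 1.5))
        sign = 1.0 if direction == "up" else -1.0
        rows.append((gene, sign * magnitude, float(rng.uniform(1e-5, 0.049))))
    for i in range(n_noise_genes):
        # below either the fold-change or the significance cutoff
        if rng.random() < 0.5:
            lfc = float(rng.uniform(-0.5, 0.5)) * math.log2(1.5)
            p = float(rng.uniform(1e-4, 0.049))
        else:
            lfc = float(rng.normal(0, 1))
            p = float(rng.uniform(0.05, 1.0))
        rows.append((f"noise_{i}", lfc, p))
    return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change", "p_value"])


def _data_path(name: str):
    return importlib.resources.files("mclx.data").joinpath(name)


def table2_fixture() -> pd.DataFrame:
    """The packaged 20-amino-acid direction table.

    Columns: the Zucker diabetic fatty rat plasma reference plus four model
    prediction columns (exchange/transport readouts of the genome-scale and
    the extracted multi-tissue model), arrows encoded as {+, -, 0}.
    """
    with importlib.resources.as_file(_data_path("table2.tsv")) as path:
        df = pd.read_csv(path, sep="\t", index_col="amino_acid")
    return df


def table2_directions(column: str) -> pd.Series:
    """One column of the packaged table as a direction-call Series."""
    df = table2_fixture()
    if column not in df.columns:
        raise KeyError(f"unknown column {column!r}; have {list(df.columns)}")
    return df[column].map(ARROW_TO_CALL)


def omim_disorders() -> list[DisorderSpec]:
    """The 17 amino-acid disorders' causal gene sets (no phenotype arrows)."""
    with importlib.resources.as_file(_data_path("omim_disorders.tsv")) as path:
        out = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, genes = line.rstrip("\n").split("\t")
                out.append(
                    DisorderSpec(name=name,
                                 genes={g for g in genes.split(",") if g})
                )
    return out
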