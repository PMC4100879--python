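"""Expression-fold-change perturbation analysis.

A differential-expression gene table (significance-filtered upstream:
p < 0.05 and fold change > 1.5) is mapped onto reaction regulation statuses
through the GPR rules, then turned into a pair of models:

* **control** -- status-affected reactions are first shrunk to one tenth of
  the normal bound magnitude (|bound| 100 instead of 1000) so that a
  subsequent doubling can actually relax a constraint in a steady-state
  model; unaffected reactions keep normal bounds; exchange reactions are
  pinned to [1, 1000] in their written direction;
* **disease** -- the control, with upregulated reactions' bounds doubled
  and downregulated reactions' bounds halved.

FVA on both models gives flux-bound intervals whose normalized changes are
thresholded into direction calls.  Plasma-concentration readout uses either
the exchange reactions directly or, more completely, the per-amino-acid sum
of deltas over all of its cytosol<->extracellular transport reactions
(an unaffected parallel route can mask the effect on a single exchange).
Subsystem-level summaries compare the coded calls (down=-1, unchanged=0,
up=+1) of each subsystem against an equally sized uniform random selector
with a Welch two-sample t statistic; strongly negative t means the
subsystem is coherently downregulated beyond chance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gpr as gpr_mod
from .directions import (
    DECREASED,
    INCREASED,
    UNCHANGED,
    DirectionCall,
    call_from_delta,
    delta_table,
)
from .lp import LPSystem
from .network import MetabolicNetwork

__all__ = [
    "GeneFoldChange",
    "RegulationStatus",
    "SubsystemScore",
    "read_foldchange_table",
    "gene_directions",
    "reaction_status",
    "reaction_statuses",
    "perturb_bounds",
    "call_flux_directions",
    "aggregate_transport_deltas",
    "subsystem_tscores",
]

FOLD_CHANGE_CUTOFF = 1.5
P_VALUE_CUTOFF = 0.05

NORMAL_BOUND = 1000.0
AFFECTED_BOUND = 100.0  # one tenth of normal, applied to regulated reactions
EXCHANGE_BOUNDS = (1.0, 1000.0)

_CODE = {DECREASED: -1, UNCHANGED: 0, INCREASED: 1}


@dataclass(frozen=True)
class GeneFoldChange:
    gene: str
    direction: int  # +1 up, -1 down
    fold_change: float
    p_value: float


@dataclass
class RegulationStatus:
    reaction: str
    status: int  # +1 up, -1 down, 0 unchanged
    genes: tuple[str, ...] = ()
    rule: str = ""  # which rule resolved the status


@dataclass
class SubsystemScore:
    subsystem: str
    n_reactions: int
    n_up: int
    n_down: int
    n_unchanged: int
    t_score: float  # NaN when undefined (subsystem smaller than 2)


def read_foldchange_table(path) -> list[GeneFoldChange]:
    """Read a DE gene table and apply the significance filter.

    Two tab-separated dialects (with header):
    ``gene_id  log2_fold_change  p_value`` (direction from the sign) or the
    pre-filtered ``gene_id  direction`` with direction in {up, down}.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    records: list[GeneFoldChange] = []
    if "direction" in cols:
        for _, row in df.iterrows():
            direction = str(row[df.columns[cols.index("direction")]]).lower()
            if direction not in ("up", "down"):
                raise ValueError(f"bad direction {direction!r}")
            records.append(
                GeneFoldChange(
                    gene=str(row[df.columns[0]]),
                    direction=1 if direction == "up" else -1,
                    fold_change=math.nan,
                    p_value=math.nan,
                )
            )
        return records
    lfc_col = df.columns[1]
    p_col = df.columns[2]
    for _, row in df.iterrows():
        lfc = float(row[lfc_col])
        p = float(row[p_col])
        if p >= P_VALUE_CUTOFF or abs(lfc) < math.log2(FOLD_CHANGE_CUTOFF):
            continue  # upstream filter: not significantly changed
        records.append(
            GeneFoldChange(
                gene=str(row[df.columns[0]]),
                direction=1 if lfc > 0 else -1,
                fold_change=2.0 ** lfc,
                p_value=p,
            )
        )
    return records


def gene_directions(records) -> dict[str, int]:
    """Collapse multiple probe records per gene by majority vote.

    When several records share one gene ID, up and down counts are summed
    and compared; a tie yields unchanged (0).
    """
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    for rec in records:
        if rec.direction > 0:
            up[rec.gene] = up.get(rec.gene, 0) + 1
        else:
            down[rec.gene] = down.get(rec.gene, 0) + 1
    out = {}
    for gene in set(up) | set(down):
        n_up, n_down = up.get(gene, 0), down.get(gene, 0)
        out[gene] = 0 if n_up == n_down else (1 if n_up > n_down else -1)
    return out


def reaction_status(rxn, directions: dict[str, int]) -> RegulationStatus:
    """Regulation status of one reaction from per-gene directions.

    Distinct genes combine through the GPR logic: AND takes the most
    restrictive branch (down dominates), OR the least restrictive (up
    dominates).  Reactions with no mapped DE gene are unchanged.
    """
    tree = gpr_mod.parse_gpr(rxn.gpr)
    genes = gpr_mod.genes_in(tree)
    mapped = tuple(sorted(g for g in genes if directions.get(g, 0) != 0))
    if tree is None or not mapped:
        return RegulationStatus(rxn.id, 0, mapped, rule="no mapped DE gene")
    status = gpr_mod.eval_direction(tree, directions)
    return RegulationStatus(rxn.id, status, mapped, rule="gpr logic")


def reaction_statuses(
    net: MetabolicNetwork, directions: dict[str, int]
) -> dict[str, RegulationStatus]:
    return {
        rid: reaction_status(rxn, directions) for rid, rxn in net.reactions.items()
    }


def _base_bounds(rxn, magnitude: float) -> tuple[float, float]:
    return (-magnitude if rxn.reversible else 0.0), magnitude


def perturb_bounds(
    net: MetabolicNetwork,
    statuses: dict[str, RegulationStatus],
    exchange_lower_bound: float = EXCHANGE_BOUNDS[0],
) -> tuple[MetabolicNetwork, MetabolicNetwork]:
    """Build the (control, disease) model pair from regulation statuses.

    The default exchange lower bound of 1 forces boundary flux in each
    exchange's written direction; pass 0 for exploratory runs on networks
    where the forced boundary flux is infeasible.
    """
    control = net.copy()
    for rid, rxn in control.reactions.items():
        if net.is_exchange(rid):
            rxn.lower_bound, rxn.upper_bound = (
                exchange_lower_bound,
                EXCHANGE_BOUNDS[1],
            )
            continue
        status = statuses.get(rid)
        magnitude = AFFECTED_BOUND if status and status.status != 0 else NORMAL_BOUND
        rxn.lower_bound, rxn.upper_bound = _base_bounds(net.reactions[rid], magnitude)
    disease = control.copy()
    for rid, rxn in disease.reactions.items():
        if net.is_exchange(rid):
            continue
        status = statuses.get(rid)
        if status is None or status.status == 0:
            continue
        factor = 2.0 if status.status > 0 else 0.5
        rxn.lower_bound *= factor
        rxn.upper_bound *= factor
    return control, disease


def _scope_ids(net: MetabolicNetwork, scope: str) -> list[str]:
    if scope == "exchange":
        return net.exchange_ids()
    if scope == "transport":
        return [r for r in net.reactions if net.is_transport(r)]
    if scope == "all":
        return list(net.reactions)
    raise ValueError(f"unknown scope {scope!r}")


def call_flux_directions(
    control: MetabolicNetwork,
    disease: MetabolicNetwork,
    scope: str = "exchange",
    epsilon: float = 0.1,
) -> tuple[list[DirectionCall], pd.Series]:
    """FVA both models over a reaction scope and call direction per reaction.

    ``scope`` is ``exchange``, ``transport`` or ``all``.  Returns the calls
    and the underlying normalized deltas (indexed by reaction id).
    """
    ids = _scope_ids(control, scope)
    ref = LPSystem.from_network(control).variability(ids)
    dis = LPSystem.from_network(disease).variability(ids)
    deltas = delta_table(ref, dis)
    calls = [
        DirectionCall(rid, call_from_delta(d, epsilon), float(d), epsilon)
        for rid, d in deltas.items()
    ]
    return calls, deltas


def aggregate_transport_deltas(
    net: MetabolicNetwork, deltas: pd.Series, epsilon: float = 0.1
) -> list[DirectionCall]:
    """Per-metabolite calls: sum of signed deltas over its transporters.

    Every transport reaction moving a species between a tissue cytosol and
    the shared extracellular compartment contributes its delta to that
    species, across all tissues.  The summed delta is thresholded like a
    per-reaction delta.  Interpreting the sign requires the transporters'
    written orientation: for uptake-oriented transporters a negative sum
    means reduced clearance from the blood compartment, i.e. extracellular
    accumulation.
    """
    per_species: dict[str, float] = {}
    for rid, d in deltas.items():
        if rid not in net.reactions or not net.is_transport(rid):
            continue
        for species in net.transported_species(rid):
            per_species[species] = per_species.get(species, 0.0) + float(d)
    return [
        DirectionCall(species, call_from_delta(d, epsilon), d, epsilon)
        for species, d in sorted(per_species.items())
    ]


def subsystem_tscores(
    calls: list[DirectionCall],
    subsystem_of: dict[str, str],
    seed: int | None = None,
) -> list[SubsystemScore]:
    """Welch t of each subsystem's coded calls against a random selector.

    The second sample is drawn once per subsystem, uniformly from
    {-1, 0, +1} and of the same size as the subsystem (a random selector
    picks each of down/unchanged/up a third of the time, so e.g. an
    all-down pair of reactions is matched by chance 1/9 of the time and
    scores weakly).  Output is sorted by t ascending: the more negative the
    t-score, the more coherently downregulated the subsystem.  Subsystems
    with fewer than two reactions get a NaN t-score.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for call in calls:
        name = subsystem_of.get(call.item)
        if not name:
            continue
        groups.setdefault(name, []).append(_CODE[call.call])
    scores = []
    for name in sorted(groups):
        codes = np.array(groups[name], dtype=float)
        n = len(codes)
        counts = {
            "up": int((codes > 0).sum()),
            "down": int((codes < 0).sum()),
            "unchanged": int((codes == 0).sum()),
        }
        if n < 2:
            t = math.nan
        else:
            random_sample = rng.integers(-1, 2, size=n).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t = float(stats.ttest_ind(codes, random_sample, equal_var=False).statistic)
        scores.append(
            SubsystemScore(
                subsystem=name,
                n_reactions=n,
                n_up=counts["up"],
                n_down=counts["down"],
                n_unchanged=counts["unchanged"],
                t_score=t,
            )
        )
    scores.sort(key=lambda s: (math.isnan(s.t_score), s.t_score))
    return scores
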