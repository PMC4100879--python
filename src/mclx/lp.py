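"""Flux balance analysis and flux variability analysis.

All linear programs share the steady-state constraint ``S @ v = 0`` with
box bounds per reaction and are solved with the HiGHS solvers behind
``scipy.optimize.linprog``.  Infeasibility and unboundedness are reported as
statuses on the result object, never as exceptions: the extraction loop
routinely probes configurations that have no feasible flux.

FVA here is the plain per-reaction min/max over the steady-state polytope,
with no optimality constraint on a biomass objective: for mammalian
multi-tissue systems no single cellular objective is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = [
    "FluxResult",
    "LPSystem",
    "solve_lp",
    "fva",
    "find_blocked",
    "InfeasibleModelError",
    "FEASIBILITY_TOLERANCE",
]

#: Conventional LP feasibility / flux-activity tolerance (flux units).
FEASIBILITY_TOLERANCE = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


class InfeasibleModelError(RuntimeError):
    """Raised by FVA when the base model has no feasible steady state."""


@dataclass
class FluxResult:
    """Outcome of one LP solve.

    ``status`` is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``;
    ``fluxes`` and ``objective_value`` are only set for optimal solves.
    """

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class LPSystem:
    """Cached LP formulation of a network, reused across many solves."""

    S: np.ndarray
    rxn_ids: list[str]
    lower: np.ndarray
    upper: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {r: j for j, r in enumerate(self.rxn_ids)}

    @classmethod
    def from_network(cls, net: MetabolicNetwork) -> "LPSystem":
        S, _, rxn_ids = net.stoichiometric_matrix()
        lower = np.array([net.reactions[r].lower_bound for r in rxn_ids])
        upper = np.array([net.reactions[r].upper_bound for r in rxn_ids])
        return cls(S=S, rxn_ids=rxn_ids, lower=lower, upper=upper)

    def objective_vector(self, objective: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.rxn_ids))
        for rid, w in objective.items():
            if rid not in self.index:
                raise KeyError(f"objective references unknown reaction {rid!r}")
            c[self.index[rid]] = w
        return c

    def _linprog(self, c, bounds=None):
        lower = self.lower if bounds is None else bounds[0]
        upper = self.upper if bounds is None else bounds[1]
        b_eq = np.zeros(self.S.shape[0])
        return linprog(
            c,
            A_eq=self.S if self.S.size else None,
            b_eq=b_eq if self.S.size else None,
            bounds=np.column_stack([lower, upper]),
            method="highs",
        )

    def solve(
        self,
        objective: dict[str, float],
        sense: str = "max",
        parsimonious: bool = False,
    ) -> FluxResult:
        """Optimise a linear flux objective at steady state.

        With ``parsimonious=True`` a second LP minimises the total absolute
        flux while holding the objective at its optimum (pFBA), so the
        returned flux vector activates as few reactions as possible.
        """
        if sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")
        c = self.objective_vector(objective)
        sign = -1.0 if sense == "max" else 1.0
        res = self._linprog(sign * c)
        status = _STATUS.get(res.status, "numerical")
        if status != "optimal":
            return FluxResult(status=status)
        obj = float(c @ res.x)
        v = res.x
        if parsimonious:
            slim = self._parsimonious(c, obj, sense)
            if slim is not None:
                v = slim
        return FluxResult(
            status="optimal",
            objective_value=obj,
            fluxes={r: float(v[j]) for j, r in enumerate(self.rxn_ids)},
        )

    def _parsimonious(self, c, obj, sense):
        """min sum(t), t >= |v|, objective held at its optimum."""
        n = len(self.rxn_ids)
        cost = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = np.hstack([self.S, np.zeros((self.S.shape[0], n))]) if self.S.size else None
        b_eq = np.zeros(self.S.shape[0]) if self.S.size else None
        eye = np.eye(n)
        A_ub = [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
        b_ub = [np.zeros(n), np.zeros(n)]
        # objective >= obj - tol (max) / <= obj + tol (min)
        sign = -1.0 if sense == "max" else 1.0
        A_ub.append(np.concatenate([sign * c, np.zeros(n)])[None, :])
        b_ub.append(np.array([sign * obj + FEASIBILITY_TOLERANCE]))
        bounds = np.vstack(
            [
                np.column_stack([self.lower, self.upper]),
                np.column_stack(
                    [np.zeros(n), np.maximum(np.abs(self.lower), np.abs(self.upper))]
                ),
            ]
        )
        res = linprog(
            cost,
            A_eq=A_eq,
            b_eq=b_eq,
            A_ub=np.vstack(A_ub),
            b_ub=np.concatenate(b_ub),
            bounds=bounds,
            method="highs",
        )
        if res.status != 0:
            return None
        return res.x[:n]

    def variability(self, rxn_ids=None) -> pd.DataFrame:
        """Per-reaction min/max flux over the steady-state polytope."""
        targets = list(rxn_ids) if rxn_ids is not None else list(self.rxn_ids)
        unknown = [r for r in targets if r not in self.index]
        if unknown:
            raise KeyError(f"fva over unknown reactions: {unknown}")
        feas = self._linprog(np.zeros(len(self.rxn_ids)))
        if feas.status == 2:
            raise InfeasibleModelError("base model has no feasible steady state")
        rows = {}
        for rid in targets:
            j = self.index[rid]
            c = np.zeros(len(self.rxn_ids))
            c[j] = 1.0
            lo = self._linprog(c)
            hi = self._linprog(-c)
            vmin = float(lo.x[j]) if lo.status == 0 else (
                -np.inf if lo.status == 3 else np.nan
            )
            vmax = float(hi.x[j]) if hi.status == 0 else (
                np.inf if hi.status == 3 else np.nan
            )
            rows[rid] = (vmin, vmax)
        df = pd.DataFrame.from_dict(rows, orient="index", columns=["min", "max"])
        df.index.name = "reaction_id"
        return df


def solve_lp(
    net: MetabolicNetwork,
    objective: dict[str, float],
    sense: str = "max",
    parsimonious: bool = False,
) -> FluxResult:
    """One-shot FBA on a network (see :meth:`LPSystem.solve`)."""
    return LPSystem.from_network(net).solve(objective, sense, parsimonious)


def fva(net: MetabolicNetwork, rxn_ids=None) -> pd.DataFrame:
    """Flux variability analysis: min/max attainable flux per reaction.

    Returns a DataFrame indexed by reaction id with columns ``min``/``max``.
    Raises :class:`InfeasibleModelError` if the base model is infeasible.
    """
    return LPSystem.from_network(net).variability(rxn_ids)


def find_blocked(
    net: MetabolicNetwork, tolerance: float = FEASIBILITY_TOLERANCE
) -> set[str]:
    """Reactions whose entire FVA interval lies within ``[-tol, +tol]``."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    table = fva(net)
    return {
        rid
        for rid, row in table.iterrows()
        if -tolerance <= row["min"] and row["max"] <= tolerance
    }


def write_bounds_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")
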