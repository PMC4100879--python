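"""Direction calls on flux-bound changes.

Both perturbation analyses (gene deletion and expression fold change)
compare a reference/control FVA bounds table against a perturbed/disease
one and call each reaction ``increased``, ``decreased`` or ``unchanged``.
The normalized bound change for reaction i is

    delta_i = ((diseaseMin_i + diseaseMax_i) - (refMin_i + refMax_i))
              / max(|mean(refMin_i, refMax_i, diseaseMin_i, diseaseMax_i)|, tol)

i.e. the shift in the bound sum, normalized by the absolute mean of all four
bounds (guarded against division by ~0 so identical all-zero intervals give
delta 0).  The call is ``increased`` when delta > epsilon, ``decreased``
when delta < -epsilon, else ``unchanged``; epsilon is the ROC sweep
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INCREASED",
    "DECREASED",
    "UNCHANGED",
    "DirectionCall",
    "normalized_delta",
    "call_from_delta",
    "calls_from_deltas",
    "delta_table",
    "epsilon_grid",
]

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"

#: Floor for the normalization denominator (flux units).
DELTA_DENOM_TOLERANCE = 1e-6


@dataclass
class DirectionCall:
    item: str  # reaction or metabolite id
    call: str
    delta: float
    epsilon: float


def normalized_delta(
    ref_min: float,
    ref_max: float,
    dis_min: float,
    dis_max: float,
    tolerance: float = DELTA_DENOM_TOLERANCE,
) -> float:
    num = (dis_min + dis_max) - (ref_min + ref_max)
    denom = abs((ref_min + ref_max + dis_min + dis_max) / 4.0)
    return num / max(denom, tolerance)


def call_from_delta(delta: float, epsilon: float) -> str:
    if delta > epsilon:
        return INCREASED
    if delta < -epsilon:
        return DECREASED
    return UNCHANGED


def delta_table(
    ref: pd.DataFrame, perturbed: pd.DataFrame, tolerance: float = DELTA_DENOM_TOLERANCE
) -> pd.Series:
    """Per-reaction normalized deltas from two FVA bounds tables.

    Both tables must have ``min``/``max`` columns; items are intersected on
    the index (a reaction absent from the perturbed model contributes the
    degenerate interval (0, 0), since a removed reaction carries no flux).
    """
    idx = ref.index
    out = {}
    for rid in idx:
        r = ref.loc[rid]
        if rid in perturbed.index:
            d = perturbed.loc[rid]
            dmin, dmax = float(d["min"]), float(d["max"])
        else:
            dmin = dmax = 0.0
        out[rid] = normalized_delta(
            float(r["min"]), float(r["max"]), dmin, dmax, tolerance
        )
    return pd.Series(out, name="delta")


def calls_from_deltas(deltas: pd.Series, epsilon: float) -> pd.Series:
    return deltas.map(lambda d: call_from_delta(d, epsilon))


def epsilon_grid(n: int = 201, low: float = 1e-3, high: float = 1000.0) -> np.ndarray:
    """Threshold sweep for ROC curves: 0 plus log-spaced values up to 1000."""
    if n < 2:
        raise ValueError("grid needs at least 2 values")
    return np.concatenate([[0.0], np.logspace(np.log10(low), np.log10(high), n - 1)])
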