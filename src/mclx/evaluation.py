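"""Confusion-matrix scoring of direction calls and threshold-swept ROC.

Direction tables are pandas Series mapping items (metabolites or exchange
reactions) to {"increased", "decreased", "unchanged"}.  Against a ground
truth the convention is:

* TP -- predicted a change, truth changed in the same direction;
* FP -- predicted a change when the truth is unchanged *or* in the opposite
  direction (a direction mismatch is a false positive, not simultaneously a
  false negative);
* TN -- both unchanged;
* FN -- predicted unchanged, truth changed.

Sweeping the call threshold epsilon over a grid turns a table of normalized
flux-bound deltas into an ROC curve; the area under the curve (AUC, trapezoid
over FPR-sorted points with anchors (0,0) and (1,1)) summarises how well
large bound changes line up with true concentration changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .directions import DECREASED, INCREASED, UNCHANGED, calls_from_deltas

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "round2",
    "roc",
    "auc_from_points",
    "random_selector",
    "ARROW_TO_CALL",
    "CALL_TO_ARROW",
]

ARROW_TO_CALL = {"+": INCREASED, "-": DECREASED, "0": UNCHANGED}
CALL_TO_ARROW = {v: k for k, v in ARROW_TO_CALL.items()}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.TP, self.FP, self.TN, self.FN)


def _check_calls(series: pd.Series, name: str):
    bad = set(series.unique()) - {INCREASED, DECREASED, UNCHANGED}
    if bad:
        raise ValueError(f"{name} contains non-direction values: {sorted(bad)}")


def confusion(truth: pd.Series, predicted: pd.Series) -> ConfusionCounts:
    """Count TP/FP/TN/FN between two direction tables over the same items."""
    if set(truth.index) != set(predicted.index):
        only_t = sorted(set(truth.index) - set(predicted.index))
        only_p = sorted(set(predicted.index) - set(truth.index))
        raise ValueError(
            f"item sets differ; only in truth: {only_t}, only in prediction: {only_p}"
        )
    _check_calls(truth, "truth")
    _check_calls(predicted, "prediction")
    tp = fp = tn = fn = 0
    for item in truth.index:
        t, p = truth[item], predicted[item]
        if p == UNCHANGED:
            if t == UNCHANGED:
                tn += 1
            else:
                fn += 1
        else:
            if t == p:
                tp += 1
            else:  # truth unchanged or opposite direction
                fp += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: int, denom: int) -> float | None:
    return None if denom == 0 else num / denom


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Precision, recall (= TPR), TNR, FPR, accuracy; None on 0/0."""
    return {
        "precision": _ratio(c.TP, c.TP + c.FP),
        "recall": _ratio(c.TP, c.TP + c.FN),
        "TNR": _ratio(c.TN, c.TN + c.FP),
        "FPR": _ratio(c.FP, c.FP + c.TN),
        "accuracy": _ratio(c.TP + c.TN, c.total),
    }


def round2(x: float | None) -> float | None:
    """Presentation rounding to 2 decimals, half away from zero."""
    if x is None:
        return None
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _binary_confusion(truth: pd.Series, deltas: pd.Series, eps: float) -> ConfusionCounts:
    """Magnitude-only confusion: predicted changed iff |delta| > eps."""
    tp = fp = tn = fn = 0
    for item in truth.index:
        changed_true = truth[item] != UNCHANGED
        changed_pred = abs(deltas[item]) > eps
        if changed_pred and changed_true:
            tp += 1
        elif changed_pred:
            fp += 1
        elif changed_true:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def roc(
    truth: pd.Series, deltas: pd.Series, epsilons, mode: str = "directional"
) -> tuple[pd.DataFrame, float]:
    """Threshold sweep: per epsilon, call deltas and compute (FPR, TPR).

    ``mode="directional"`` applies the full direction-aware confusion
    convention (a wrong-direction call is a false positive), matching the
    fixed-threshold scoring; its chance level sits below 0.5 because a
    random direction is usually wrong.  ``mode="magnitude"`` scores the
    standard binary question -- does |delta| separate changed from
    unchanged items -- whose chance level is the textbook 0.5.

    Points with an undefined rate (zero denominator) are dropped from the
    curve.  Returns the point table and the trapezoidal AUC.
    """
    if mode not in ("directional", "magnitude"):
        raise ValueError(f"unknown roc mode {mode!r}")
    epsilons = np.asarray(list(epsilons), dtype=float)
    if epsilons.size < 2:
        raise ValueError("epsilon grid needs at least 2 values")
    rows = []
    for eps in epsilons:
        if mode == "directional":
            c = confusion(truth, calls_from_deltas(deltas, eps))
        else:
            c = _binary_confusion(truth, deltas, eps)
        m = metrics(c)
        rows.append(
            {
                "epsilon": eps,
                "TPR": m["recall"],
                "FPR": m["FPR"],
                "TP": c.TP,
                "FP": c.FP,
                "TN": c.TN,
                "FN": c.FN,
            }
        )
    table = pd.DataFrame(rows)
    pts = table.dropna(subset=["TPR", "FPR"])
    return table, auc_from_points(pts["FPR"].to_numpy(), pts["TPR"].to_numpy())


def auc_from_points(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoid AUC with (0,0) and (1,1) anchors appended."""
    fpr = np.concatenate([[0.0], np.asarray(fpr, float), [1.0]])
    tpr = np.concatenate([[0.0], np.asarray(tpr, float), [1.0]])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def random_selector(items, seed: int | None = None) -> pd.Series:
    """Uniform random direction call per item (the chance baseline)."""
    rng = np.random.default_rng(seed)
    choices = np.array([INCREASED, DECREASED, UNCHANGED])
    items = list(items)
    return pd.Series(rng.choice(choices, size=len(items)), index=items)


def write_roc_table(table: pd.DataFrame, auc: float, path) -> None:
    with open(path, "w") as fh:
        fh.write("epsilon\tFPR\tTPR\n")
        for _, row in table.iterrows():
            fpr = "" if row["FPR"] is None or pd.isna(row["FPR"]) else f"{row['FPR']:.6g}"
            tpr = "" if row["TPR"] is None or pd.isna(row["TPR"]) else f"{row['TPR']:.6g}"
            fh.write(f"{row['epsilon']:.6g}\t{fpr}\t{tpr}\n")
        fh.write(f"# AUC\t{auc:.6g}\n")
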