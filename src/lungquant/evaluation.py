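"""Per-class Dice validation of predicted masks against ground truth.

Dice for class ``c`` is ``2|T_c ∩ P_c| / (|T_c| + |P_c|)`` over the
evaluated region; 1.0 is perfect agreement.  Evaluation can be
restricted to an annotated region so that unannotated pixels never
influence any score.  A class absent from both masks has no defined
Dice and is excluded from the macro average (not scored 0 or 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ComparisonError
from .masks import TissueMask


@dataclass
class DiceReport:
    """Per-class Dice scores plus supports and averages.

    ``per_class[name]`` is NaN when the class is absent from both masks
    inside the region (undefined, excluded from ``macro_average``).
    ``pooled`` is the micro average: all classes' intersections and
    supports are pooled before the ratio is taken.
    """

    per_class: dict[str, float]
    support_truth: dict[str, int]
    support_pred: dict[str, int]
    macro_average: float
    pooled: float

    def defined_classes(self) -> list[str]:
        return [c for c, d in self.per_class.items() if not math.isnan(d)]


def dice_per_class(
    truth: TissueMask, pred: TissueMask, region: np.ndarray | None = None
) -> DiceReport:
    """Compute per-class Dice between a ground-truth and a predicted mask.

    Both masks must share geometry and legend.  ``region``, if given, is
    a binary raster marking the annotated pixels to evaluate.
    """
    if truth.shape != pred.shape:
        raise ComparisonError(
            f"mask shapes differ: {truth.shape} vs {pred.shape}"
        )
    if truth.legend.class_names != pred.legend.class_names:
        raise ComparisonError("masks carry different legends")

    t = truth.labels
    p = pred.labels
    if region is not None:
        region = np.asarray(region)
        if region.shape != t.shape:
            raise ComparisonError(
                f"region shape {region.shape} != mask shape {t.shape}"
            )
        sel = region.astype(bool)
        t = t[sel]
        p = p[sel]
    t = t.ravel()
    p = p.ravel()

    n = truth.legend.n_classes
    count_t = np.bincount(t, minlength=n).astype(np.int64)
    count_p = np.bincount(p, minlength=n).astype(np.int64)
    agree = t == p
    inter = np.bincount(t[agree], minlength=n).astype(np.int64)

    denom = count_t + count_p
    per_class: dict[str, float] = {}
    support_truth: dict[str, int] = {}
    support_pred: dict[str, int] = {}
    defined: list[float] = []
    for e in sorted(truth.legend.entries, key=lambda e: e.class_id):
        i = e.class_id
        support_truth[e.class_name] = int(count_t[i])
        support_pred[e.class_name] = int(count_p[i])
        if denom[i] == 0:
            per_class[e.class_name] = float("nan")
        else:
            d = 2.0 * inter[i] / denom[i]
            per_class[e.class_name] = d
            defined.append(d)

    macro = float(np.mean(defined)) if defined else float("nan")
    total_denom = int(denom.sum())
    pooled = 2.0 * int(inter.sum()) / total_denom if total_denom else float("nan")
    return DiceReport(
        per_class=per_class,
        support_truth=support_truth,
        support_pred=support_pred,
        macro_average=macro,
        pooled=pooled,
    )
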