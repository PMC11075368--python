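"""Confusion-matrix metrics, an exhaustive-search oracle, correlation
summaries, and label-permutation calibration of the cutoff engine."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import JackknifeCurves, Orientation, _as_bool_labels, _as_float_array
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def confusion(ir_labels, y, cutoff: float, orientation: Orientation) -> ConfusionSummary:
    """Confusion matrix with IR as the positive class.

    ``high_is_IR`` predicts IR for ``y >= cutoff``; ``low_is_IR`` for
    ``y <= cutoff`` (ties at the cutoff classify as IR either way).
    """
    ir = _as_bool_labels(ir_labels)
    ya = _as_float_array(y, "y")
    if not ir.any() or ir.all():
        raise DegenerateInputError("both label classes must be present")
    pred = ya >= cutoff if orientation == "high_is_IR" else ya <= cutoff
    return ConfusionSummary(
        tp=int(np.sum(pred & ir)),
        fp=int(np.sum(pred & ~ir)),
        tn=int(np.sum(~pred & ~ir)),
        fn=int(np.sum(~pred & ir)),
    )


def brute_force_best_cutoff(ir_labels, y) -> tuple[float, Orientation, float]:
    """Exhaustive-search oracle: the global maximum-Youden threshold.

    Evaluates every midpoint between consecutive sorted unique values of
    ``y`` (plus -inf/+inf sentinels) under both orientations.  Ties resolve
    to the smaller cutoff, then ``high_is_IR``.
    """
    ir = _as_bool_labels(ir_labels)
    ya = _as_float_array(y, "y")
    uniq = np.unique(ya)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    best: tuple | None = None
    for orientation in ("high_is_IR", "low_is_IR"):
        for c in candidates:
            summary = confusion(ir, ya, float(c), orientation)
            key = (-summary.youden, c, 0 if orientation == "high_is_IR" else 1)
            if best is None or key < best[0]:
                best = (key, (float(c), orientation, summary.youden))
    return best[1]


def correlation_report(
    panel: pd.DataFrame, reference: str = "matsuda"
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation matrix of the panel plus the reference vector.

    Returns the symmetric correlation matrix over all numeric, non-constant
    panel columns and the correlations with the reference variable ordered
    by decreasing magnitude (the reference itself excluded).  Constant
    columns are excluded with a warning.  The count of reference
    correlations with |r| > 0.5 is logged.
    """
    numeric = panel.select_dtypes(include=[np.number])
    if reference not in numeric.columns:
        raise DegenerateInputError(f"panel lacks the reference column {reference!r}")
    if len(numeric) < 3 or numeric.shape[1] < 2:
        raise DegenerateInputError("correlation report needs >= 3 rows and >= 2 columns")
    constant = [c for c in numeric.columns if numeric[c].nunique() <= 1]
    for c in constant:
        logger.warning("constant column %r excluded from the correlation report", c)
    numeric = numeric.drop(columns=constant)
    matrix = numeric.corr(method="spearman")
    vector = matrix[reference].drop(index=reference)
    vector = vector.iloc[np.argsort(-vector.abs().to_numpy(), kind="stable")]
    logger.info(
        "%d of %d reference correlations have |r| > 0.5",
        int((vector.abs() > 0.5).sum()),
        vector.size,
    )
    return matrix, vector


def permutation_youden_null(
    x, y, ir_labels, n_shuffles: int = 1000, seed: int = 0
) -> np.ndarray:
    """Youden indices selected by the jackknife engine under shuffled labels.

    The label-independent smoothing curves are computed once and reused for
    every shuffle, which is numerically identical to rerunning the full
    engine per shuffle.  Used to verify the no-signal calibration of the
    selection procedure (mean Youden near zero).
    """
    ir = _as_bool_labels(ir_labels)
    curves = JackknifeCurves(x, y)
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        out[s] = curves.select(rng.permutation(ir)).youden
    return out
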