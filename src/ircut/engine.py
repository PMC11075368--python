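"""Cutoff selection engine: spatially weighted coordinate smoothing with a
power-parameterized inverse-distance weight matrix, wrapped in a first-order
jackknife with maximum-Youden selection.

Given a reference variable ``x`` (the Matsuda index: low values indicate
insulin resistance), a candidate variable ``y``, and binary IR labels, the
engine proceeds as follows:

1. z-score both variables (sample SD);
2. form the separation/overlap window on each axis — the interval between
   the IR-group extreme and the non-IR-group extreme — and take its midpoint;
3. build a spatial weight matrix from inverse pairwise Euclidean distances
   in the (xz, yz) plane, raised elementwise to a power ``p``, min–max scaled
   over the off-diagonal, then row-standardized to unit row sums;
4. compute the Spearman correlation ``r`` between ``x`` and ``y``;
5. smooth the coordinates: ``x0 = r^2 W xz + (1 - r^2) xz`` (same for y);
6. sweep ``p`` over a fixed grid (0.50 to 2.50, step 0.01) and keep the
   candidate whose smoothed-coordinate means lie closest (Euclidean) to the
   window midpoints; the candidate cutoff is the back-transformed smoothed
   y-mean;
7. repeat the sweep leaving each observation out in turn (first-order
   jackknife) and score every candidate's confusion matrix on the full
   sample; return the candidate with the largest Youden index
   (sensitivity + specificity - 1).

The engine itself is deterministic; all randomness lives in the cohort
simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError

logger = logging.getLogger(__name__)

Orientation = Literal["high_is_IR", "low_is_IR"]
Direction = Literal["IR_low", "IR_high"]

#: default power grid: 0.50 to 2.50 in steps of 0.01 (201 values)
P_GRID = np.round(np.arange(50, 251) * 0.01, 10)


# ---------------------------------------------------------------------------
# data types

@dataclass(frozen=True)
class StandardizedPair:
    """z-scored reference/candidate variables with back-transform parameters."""

    xz: np.ndarray
    yz: np.ndarray
    x_mean: float
    x_sd: float
    y_mean: float
    y_sd: float


@dataclass(frozen=True)
class WindowSpec:
    """Separation or overlap window on one axis.

    ``kind`` is "separation" when the group ranges are disjoint on the axis,
    else "overlap"; ``midpoint`` is the arithmetic mean of the two extremes.
    """

    kind: Literal["separation", "overlap"]
    ir_extreme: float
    nonir_extreme: float
    midpoint: float


@dataclass(frozen=True)
class WeightMatrix:
    """Row-stochastic spatial weight matrix at power ``p`` (zero diagonal)."""

    entries: np.ndarray
    p: float


@dataclass(frozen=True)
class CandidateCutoff:
    """Best candidate from one power sweep."""

    p: float
    x0_mean: float
    y0_mean: float
    distance: float
    cutoff_y: float
    orientation: Orientation


@dataclass(frozen=True)
class CutoffResult:
    """Selected cutoff for one candidate variable (one report row)."""

    variable: str
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    p_selected: float
    replicate_removed: int | None
    spearman_r: float


# ---------------------------------------------------------------------------
# elementary operations

def _as_float_array(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def _as_bool_labels(labels) -> np.ndarray:
    """Accept a boolean mask or {IR, nonIR} strings; True means IR."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return np.asarray([str(v) == "IR" for v in arr.ravel()])


def standardize(x: Sequence[float], y: Sequence[float]) -> StandardizedPair:
    """z-score both variables with the sample SD (n-1 denominator)."""
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise DomainError("x and y must have equal length")
    if xa.size < 3:
        raise DegenerateInputError("standardize requires n >= 3")
    x_sd = float(np.std(xa, ddof=1))
    y_sd = float(np.std(ya, ddof=1))
    if x_sd == 0.0 or y_sd == 0.0:
        raise DegenerateInputError("constant variable cannot be standardized")
    x_mean = float(np.mean(xa))
    y_mean = float(np.mean(ya))
    return StandardizedPair(
        xz=(xa - x_mean) / x_sd,
        yz=(ya - y_mean) / y_sd,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def window_midpoint(values, ir_labels, direction: Direction = "IR_low") -> WindowSpec:
    """Separation/overlap window between the group extremes on one axis.

    For ``IR_low`` variables (Matsuda-like) the extremes are max(IR) and
    min(non-IR); for ``IR_high`` variables, min(IR) and max(non-IR).
    """
    vals = _as_float_array(values, "values")
    ir = _as_bool_labels(ir_labels)
    if ir.size != vals.size:
        raise DomainError("labels and values must have equal length")
    if not ir.any() or ir.all():
        raise DegenerateInputError("both label groups must be non-empty")
    if direction == "IR_low":
        ir_extreme = float(vals[ir].max())
        nonir_extreme = float(vals[~ir].min())
        separated = ir_extreme < nonir_extreme
    elif direction == "IR_high":
        ir_extreme = float(vals[ir].min())
        nonir_extreme = float(vals[~ir].max())
        separated = ir_extreme > nonir_extreme
    else:
        raise DomainError(f"unknown direction {direction!r}")
    return WindowSpec(
        kind="separation" if separated else "overlap",
        ir_extreme=ir_extreme,
        nonir_extreme=nonir_extreme,
        midpoint=(ir_extreme + nonir_extreme) / 2.0,
    )


def spearman_r(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size < 3:
        raise DegenerateInputError("spearman_r requires n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise DegenerateInputError("correlation undefined for a constant input")
    r = float(stats.spearmanr(xa, ya).statistic)
    return r


def _inverse_distances(xz: np.ndarray, yz: np.ndarray) -> np.ndarray:
    """Off-diagonal inverse distances; duplicate points get the largest
    finite inverse distance (closest pairs keep the highest weight without
    infinities).  Diagonal is zero."""
    n = xz.size
    if n < 3:
        raise DegenerateInputError("weight matrix requires n >= 3")
    dx = xz[:, None] - xz[None, :]
    dy = yz[:, None] - yz[None, :]
    d = np.hypot(dx, dy)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    with np.errstate(divide="ignore"):
        inv[off] = 1.0 / d[off]
    finite = inv[off][np.isfinite(inv[off])]
    if finite.size == 0:
        # all points coincide: flat weights (handled by uniform fallback)
        inv[off] = 1.0
        return inv
    inv[off & ~np.isfinite(inv)] = finite.max()
    return inv


def build_weight_matrix(xz, yz, p: float) -> WeightMatrix:
    """Spatial weight matrix at power ``p``.

    Construction order: inverse distances raised elementwise to ``p``,
    min–max scaling of the off-diagonal entries to [0, 1], then row
    standardization to unit row sums.  Degenerate rows (or an entirely flat
    off-diagonal) fall back to uniform weights 1/(n-1).
    """
    if not (0.0 < p <= 10.0):
        raise DomainError(f"power p={p} outside (0, 10]")
    xa = _as_float_array(xz, "xz")
    ya = _as_float_array(yz, "yz")
    n = xa.size
    inv = _inverse_distances(xa, ya)
    off = ~np.eye(n, dtype=bool)
    raw = np.zeros_like(inv)
    raw[off] = inv[off] ** p
    mn = raw[off].min()
    mx = raw[off].max()
    w = np.zeros_like(raw)
    if mx > mn:
        w[off] = (raw[off] - mn) / (mx - mn)
        sums = w.sum(axis=1)
        flat = sums <= 0.0
        w[~flat] /= sums[~flat, None]
        if flat.any():
            w[flat] = off[flat] / (n - 1.0)
    else:
        w[off] = 1.0 / (n - 1.0)
    return WeightMatrix(entries=w, p=float(p))


def smooth_coordinates(
    W: WeightMatrix | np.ndarray, pair: StandardizedPair, r: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially smoothed coordinates x0 = r^2 W xz + (1-r^2) xz (same for y)."""
    entries = W.entries if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    if entries.shape != (pair.xz.size, pair.xz.size):
        raise DomainError("weight matrix dimensions do not match the data")
    r2 = min(r * r, 1.0)
    x0 = r2 * (entries @ pair.xz) + (1.0 - r2) * pair.xz
    y0 = r2 * (entries @ pair.yz) + (1.0 - r2) * pair.yz
    return x0, y0


def candidate_distance(x0, y0, xw: float, yw: float) -> float:
    """Euclidean distance from the smoothed-coordinate means to the window
    midpoints."""
    x0a = _as_float_array(x0, "x0")
    y0a = _as_float_array(y0, "y0")
    if x0a.size == 0:
        raise DegenerateInputError("empty coordinate vector")
    return float(np.hypot(x0a.mean() - xw, y0a.mean() - yw))


# ---------------------------------------------------------------------------
# power sweep

def _smoothed_mean_curves(
    xz: np.ndarray, yz: np.ndarray, p_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """mean(W_p @ xz) and mean(W_p @ yz) for every power on the grid.

    Exploits two algebraic facts to avoid materializing each W_p: x -> x^p is
    monotone, so the off-diagonal min/max of the powered weights are the
    powered min/max; and W_p acts on a vector as
    ``(R v - mn * sum(v)) / (rowsum(R) - (n-1) * mn)`` with ``R`` the powered
    inverse distances.  The powered family is built by cumulative
    multiplication with the per-step factor inv_d**step.
    """
    n = xz.size
    inv = _inverse_distances(xz, yz)
    off = ~np.eye(n, dtype=bool)
    mn0 = inv[off].min()
    mx0 = inv[off].max()
    P = p_grid.size
    if mx0 == mn0:
        # uniform weights at every power
        wx = (xz.sum() - xz) / (n - 1.0)
        wy = (yz.sum() - yz) / (n - 1.0)
        return np.full(P, wx.mean()), np.full(P, wy.mean())

    V = np.column_stack([xz, yz, np.ones(n)])
    T = np.empty((P, n, n))
    T[0] = inv ** p_grid[0]
    if P > 1:
        steps = np.diff(p_grid)
        if not np.allclose(steps, steps[0]):
            raise DomainError("power grid must be uniformly spaced")
        factor = inv ** steps[0]
        for k in range(1, P):
            np.multiply(T[k - 1], factor, out=T[k])
    U = (T.reshape(P * n, n) @ V).reshape(P, n, 3)

    mn = mn0 ** p_grid  # (P,)
    sums = U[:, :, 2] - (n - 1.0) * mn[:, None]  # row sums of unscaled weights
    sx, sy = xz.sum(), yz.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        # (S v)_i = (R v)_i - mn * (sum(v) - v_i): the shift skips the diagonal
        wx = (U[:, :, 0] - mn[:, None] * (sx - xz[None, :])) / sums
        wy = (U[:, :, 1] - mn[:, None] * (sy - yz[None, :])) / sums
    # rows whose scaled weights sum to zero fall back to uniform
    tol = (mx0 ** p_grid - mn)[:, None] * 1e-12
    flat = sums <= tol
    if flat.any():
        ux = (sx - xz) / (n - 1.0)
        uy = (sy - yz) / (n - 1.0)
        wx = np.where(flat, ux[None, :], wx)
        wy = np.where(flat, uy[None, :], wy)
    return wx.mean(axis=1), wy.mean(axis=1)


def sweep_power(
    pair: StandardizedPair,
    windows: tuple[WindowSpec, WindowSpec],
    r: float,
    p_grid: np.ndarray | None = None,
) -> CandidateCutoff:
    """Evaluate every power on the grid and return the minimum-distance
    candidate (ties broken toward the smaller power).

    ``windows`` are the (x-axis, y-axis) windows in z-units.  The candidate
    cutoff is the smoothed y-coordinate mean back-transformed to original
    units; orientation follows the sign of ``r`` (negative r: high y values
    indicate IR)."""
    grid = P_GRID if p_grid is None else np.asarray(p_grid, dtype=float)
    xw, yw = windows[0].midpoint, windows[1].midpoint
    a, b = _smoothed_mean_curves(pair.xz, pair.yz, grid)
    r2 = min(r * r, 1.0)
    x0m = r2 * a + (1.0 - r2) * pair.xz.mean()
    y0m = r2 * b + (1.0 - r2) * pair.yz.mean()
    d = np.hypot(x0m - xw, y0m - yw)
    k = int(np.argmin(d))  # first minimum = smallest p
    return CandidateCutoff(
        p=float(grid[k]),
        x0_mean=float(x0m[k]),
        y0_mean=float(y0m[k]),
        distance=float(d[k]),
        cutoff_y=float(y0m[k] * pair.y_sd + pair.y_mean),
        orientation="high_is_IR" if r < 0 else "low_is_IR",
    )


# ---------------------------------------------------------------------------
# jackknife

def _confusion_counts(
    ir: np.ndarray, y: np.ndarray, cutoff: float, orientation: Orientation
) -> tuple[float, float]:
    """(sensitivity, specificity); ties at the cutoff classify as IR."""
    pred_ir = y >= cutoff if orientation == "high_is_IR" else y <= cutoff
    tp = int(np.sum(pred_ir & ir))
    tn = int(np.sum(~pred_ir & ~ir))
    return tp / int(ir.sum()), tn / int((~ir).sum())


class JackknifeCurves:
    """Label-independent precomputation for the first-order jackknife.

    The smoothed-coordinate mean curves, the per-replicate standardization
    parameters and the per-replicate Spearman correlation depend only on the
    data, not on the labels, so they are computed once; :meth:`select`
    (windows, candidate choice and confusion matrices) can then be rerun
    cheaply against any labeling — this is what makes label-permutation
    calibration and iterative reference refinement inexpensive.  ``select``
    is numerically identical to rebuilding every replicate from scratch.
    """

    def __init__(self, x, y, p_grid: np.ndarray | None = None):
        self.x = _as_float_array(x, "x")
        self.y = _as_float_array(y, "y")
        n = self.x.size
        if self.y.size != n:
            raise DomainError("x and y must have equal length")
        if n < 4:
            raise DegenerateInputError("jackknife requires n >= 4")
        self.n = n
        self.p_grid = P_GRID if p_grid is None else np.asarray(p_grid, dtype=float)
        self._replicates: list[dict | None] = []
        idx = np.arange(n)
        for j in range(n):
            mask = idx != j
            xs, ys = self.x[mask], self.y[mask]
            try:
                pair = standardize(xs, ys)
                r = spearman_r(xs, ys)
                a, b = _smoothed_mean_curves(pair.xz, pair.yz, self.p_grid)
            except DegenerateInputError as exc:
                logger.warning("jackknife replicate %d skipped: %s", j, exc)
                self._replicates.append(None)
                continue
            r2 = min(r * r, 1.0)
            self._replicates.append(
                {
                    "mask": mask,
                    "pair": pair,
                    "r": r,
                    "x0m": r2 * a + (1.0 - r2) * pair.xz.mean(),
                    "y0m": r2 * b + (1.0 - r2) * pair.yz.mean(),
                }
            )

    def select(self, ir_labels, variable: str = "y") -> CutoffResult:
        """Run the max-Youden jackknife selection against a labeling.

        Every replicate's minimum-distance candidate is scored on the full
        sample; ties break toward smaller distance, then smaller replicate
        index."""
        ir = _as_bool_labels(ir_labels)
        if ir.size != self.n:
            raise DomainError("labels length does not match the data")
        if not ir.any() or ir.all():
            raise DegenerateInputError("both label groups must be present")
        best: tuple | None = None
        for j, rep in enumerate(self._replicates):
            if rep is None:
                continue
            mask = rep["mask"]
            ir_sub = ir[mask]
            if not ir_sub.any() or ir_sub.all():
                logger.warning(
                    "jackknife replicate %d skipped: a label group is empty", j
                )
                continue
            pair: StandardizedPair = rep["pair"]
            r: float = rep["r"]
            direction_y: Direction = "IR_high" if r < 0 else "IR_low"
            xwin = window_midpoint(pair.xz, ir_sub, "IR_low")
            ywin = window_midpoint(pair.yz, ir_sub, direction_y)
            d = np.hypot(rep["x0m"] - xwin.midpoint, rep["y0m"] - ywin.midpoint)
            k = int(np.argmin(d))
            cutoff = float(rep["y0m"][k] * pair.y_sd + pair.y_mean)
            orientation: Orientation = "high_is_IR" if r < 0 else "low_is_IR"
            sens, spec = _confusion_counts(ir, self.y, cutoff, orientation)
            youden = sens + spec - 1.0
            key = (-youden, d[k], j)
            if best is None or key < best[0]:
                best = (
                    key,
                    CutoffResult(
                        variable=variable,
                        cutoff=cutoff,
                        sensitivity=sens,
                        specificity=spec,
                        youden=youden,
                        p_selected=float(self.p_grid[k]),
                        replicate_removed=j,
                        spearman_r=r,
                    ),
                )
        if best is None:
            raise DegenerateInputError("every jackknife replicate was skipped")
        return best[1]


def jackknife_select(
    x, y, ir_labels, variable: str = "y", p_grid: np.ndarray | None = None
) -> CutoffResult:
    """Leave-one-out cutoff selection for candidate variable ``y`` against
    reference ``x`` (Matsuda-like: low values indicate IR)."""
    return JackknifeCurves(x, y, p_grid=p_grid).select(ir_labels, variable=variable)


# ---------------------------------------------------------------------------
# Matsuda reference refinement

def refine_matsuda_cutoff(
    matsuda, initial_threshold: float = 4.0, tol: float = 1e-6, max_iter: int = 100
) -> tuple[float, np.ndarray]:
    """Iteratively refine the Matsuda reference cutoff and IR labels.

    Labels are initialized by ``matsuda < initial_threshold``.  Each pass
    recomputes the separation-window midpoint — the arithmetic mean of the
    IR-group maximum and the non-IR-group minimum — stabilized by a
    first-order jackknife: each observation is left out in turn, the midpoint
    of the remaining sample is scored on the full sample, and the
    maximum-Youden midpoint is kept (ties toward the smaller replicate
    index).  Labels are then refreshed from the new cutoff (``matsuda <=
    cutoff`` is IR) and the pass repeats until the cutoff moves less than
    ``tol``.  Classifying by the returned cutoff reproduces the returned
    labels exactly.
    """
    m = _as_float_array(matsuda, "matsuda")
    if np.any(m <= 0):
        raise DomainError("Matsuda values must be positive")
    if m.size < 4:
        raise DegenerateInputError("refinement requires n >= 4")
    ir = m < initial_threshold
    if not ir.any() or ir.all():
        raise DomainError(
            f"initial threshold {initial_threshold} places every subject on one side"
        )
    cutoff = float(initial_threshold)
    idx = np.arange(m.size)
    for _ in range(max_iter):
        best: tuple | None = None
        for j in range(m.size):
            mask = idx != j
            ir_sub = ir[mask]
            if not ir_sub.any() or ir_sub.all():
                logger.warning("refinement replicate %d skipped: empty group", j)
                continue
            win = window_midpoint(m[mask], ir_sub, "IR_low")
            sens, spec = _confusion_counts(ir, m, win.midpoint, "low_is_IR")
            key = (-(sens + spec - 1.0), j)
            if best is None or key < best[0]:
                best = (key, win.midpoint)
        if best is None:
            raise DegenerateInputError("every refinement replicate was skipped")
        new_cutoff = best[1]
        new_ir = m <= new_cutoff
        converged = abs(new_cutoff - cutoff) < tol and np.array_equal(new_ir, ir)
        cutoff, ir = new_cutoff, new_ir
        if converged:
            break
        if not ir.any() or ir.all():
            raise DegenerateInputError("refinement collapsed to a single group")
    return cutoff, ir
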