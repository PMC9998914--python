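"""Sorting seeds into pod valves with a lowess pseudoseptum.

Seeds in a pod sit in two longitudinal chambers (valves) separated by the
pseudoseptum membrane.  In a scan whose long axis is Z, the seed
centroids in the (Z, X) plane form two bands around the pseudoseptum; a
robust lowess curve fit to X-centroid as a function of Z-centroid
approximates the septum, and the sign of each seed's vertical residual
assigns its valve: above the line -> valve 1, below -> valve 2 (a zero
residual goes to valve 1 by a fixed tie-break).  Within each valve seeds
are sequenced beak-to-pedicel (ascending Z) and the spacing between
consecutive same-valve seeds is the Euclidean distance between their
centroids in the (Z, X) plane.

For pods with five seeds or fewer the smoother span is forced to f = 1
(a single global robust linear fit); otherwise the span defaults to 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ValveAssignment", "lowess", "assign_valves", "valve_accuracy", "DEFAULT_SPAN"]

DEFAULT_SPAN = 2.0 / 3.0
SMALL_POD_MAX_SEEDS = 5


@dataclass(frozen=True)
class ValveAssignment:
    seed_id: int
    valve: int  # 1 above the septum curve, 2 below
    residual: float  # signed voxel distance to the lowess line
    sequence_in_valve: int
    spacing_to_previous: float | None  # None for the first seed in a valve


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def _weighted_linear_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float) -> float:
    """Weighted least-squares line evaluated at x0; falls back to the
    weighted mean when the weighted x spread is degenerate."""
    sw = w.sum()
    if sw <= 0:
        return float(np.mean(y))
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-12 * max(1.0, xm * xm):
        return float(ym)
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(ym + slope * (x0 - xm))


def lowess(x: np.ndarray, y: np.ndarray, f: float = DEFAULT_SPAN, iters: int = 3) -> np.ndarray:
    """Cleveland's locally weighted scatterplot smoothing.

    For each x_i a weighted linear fit is made over the ceil(f*n) nearest
    neighbors (tricube distance weights), then `iters` robustifying passes
    reweight by bisquare weights of the scaled residuals.  A single point
    returns y; two points return the interpolating line's values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1D arrays with >= 1 point")
    if not 0.0 < f <= 1.0:
        raise ValueError("span f must lie in (0, 1]")
    n = len(x)
    if n == 1:
        return y.copy()
    r = max(2, int(np.ceil(f * n)))
    r = min(r, n)
    delta = np.ones(n)  # robustness weights
    fitted = np.empty(n)
    for it in range(iters + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            h = np.sort(d)[r - 1]
            if h <= 0.0:
                w = (d <= 0).astype(float)
            else:
                w = _tricube(d / h)
            w *= delta
            fitted[i] = _weighted_linear_fit(x, y, w, x[i])
        if it == iters:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return fitted


def assign_valves(
    records: pd.DataFrame | list[dict], f_override: float | None = None, iters: int = 3
) -> list[ValveAssignment]:
    """Assign every seed of one pod to a valve and sequence it.

    `records` needs "Seed ID Number", "Z-axis centroid" and
    "X-axis centroid" columns/keys.  The regression is X on Z (the pod's
    long axis); f = 1 for pods with <= 5 seeds, else 2/3, unless
    overridden.
    """
    frame = pd.DataFrame(records)
    if frame.empty:
        raise ValueError("no seeds to assign")
    ids = frame["Seed ID Number"].to_numpy()
    z = frame["Z-axis centroid"].to_numpy(dtype=float)
    x = frame["X-axis centroid"].to_numpy(dtype=float)
    order = np.argsort(z, kind="stable")
    if f_override is not None:
        span = f_override
    elif len(frame) <= SMALL_POD_MAX_SEEDS:
        span = 1.0
    else:
        span = DEFAULT_SPAN
    fitted_sorted = lowess(z[order], x[order], f=span, iters=iters)
    fitted = np.empty_like(fitted_sorted)
    fitted[order] = fitted_sorted
    residual = x - fitted
    valve = np.where(residual >= 0.0, 1, 2)  # tie (residual 0) -> valve 1

    assignments: dict[int, ValveAssignment] = {}
    for v in (1, 2):
        members = order[valve[order] == v]
        prev = None
        for seq, i in enumerate(members, start=1):
            spacing = None
            if prev is not None:
                spacing = float(np.hypot(z[i] - z[prev], x[i] - x[prev]))
            assignments[i] = ValveAssignment(
                seed_id=int(ids[i]),
                valve=v,
                residual=float(residual[i]),
                sequence_in_valve=seq,
                spacing_to_previous=spacing,
            )
            prev = i
    return [assignments[i] for i in range(len(frame))]


def valve_accuracy(assignments: list[ValveAssignment], truth: dict[int, int]) -> float:
    """Fraction of seeds in the correct valve, up to valve relabelling.

    Valve numbering is arbitrary (which chamber is "1" depends on scan
    orientation), so the better of the two label permutations is scored.
    """
    if {a.seed_id for a in assignments} != set(truth):
        raise ValueError("assignment and truth seed ids differ")
    same = sum(1 for a in assignments if truth[a.seed_id] == a.valve)
    flipped = sum(1 for a in assignments if truth[a.seed_id] == 3 - a.valve)
    return max(same, flipped) / len(assignments)


def attach_valve_columns(
    records: pd.DataFrame, assignments: list[ValveAssignment]
) -> pd.DataFrame:
    """Return a copy of the seed table with the valve block filled in."""
    frame = pd.DataFrame(records).copy()
    by_id = {a.seed_id: a for a in assignments}
    frame["valve"] = [by_id[i].valve for i in frame["Seed ID Number"]]
    frame["sequence_in_valve"] = [by_id[i].sequence_in_valve for i in frame["Seed ID Number"]]
    frame["spacing_to_previous"] = [
        by_id[i].spacing_to_previous for i in frame["Seed ID Number"]
    ]
    return frame
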