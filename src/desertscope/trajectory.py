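"""Segmented (breakpoint) regression of single-gene expression time
courses.

Fits continuous piecewise-linear models by exhaustive search over
breakpoint placements at observed time points (k = 0..max_breakpoints),
selecting across k by BIC. Adjusted R-squared gates reporting, and
per-segment slopes get a significance-based direction call.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "TrajectoryFit",
    "fit_segmented",
    "filter_fits",
    "classify_shape",
]


@dataclass
class TimeSeries:
    """Ordered (time, expression) pairs for one gene in one structure.

    Replicate samples at one time are kept as repeated x-values."""

    times: np.ndarray
    values: np.ndarray
    gene: str = ""
    structure: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.values = self.values[order]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TrajectoryFit:
    gene: str
    structure: str
    k: int  # number of breakpoints
    breakpoints: list[float]
    slopes: list[float]
    intercepts: list[float]
    slope_p: list[float]
    directions: list[str]  # up | down | flat, per segment
    fitted: np.ndarray
    adj_r2: float
    bic: float
    rejected_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rejected_reason is None


def _design(times: np.ndarray, bps: tuple[float, ...]) -> np.ndarray:
    """Continuous piecewise-linear basis: 1, t, hinge(t - b) per breakpoint."""
    cols = [np.ones_like(times), times]
    cols += [np.maximum(0.0, times - b) for b in bps]
    return np.column_stack(cols)


def _segment_counts(times: np.ndarray, bps: tuple[float, ...]) -> list[int]:
    """Point count per segment; a point at a breakpoint belongs to the
    left segment."""
    edges = [-np.inf, *bps, np.inf]
    return [
        int(np.sum((times > lo) & (times <= hi)))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]


def fit_segmented(
    ts: TimeSeries,
    max_breakpoints: int = 3,
    min_seg_samples: int = 2,
    min_mean_expr: float = 2.0,
    direction_alpha: float = 0.05,
    breakpoint_alpha: float = 0.01,
    continuous: bool = True,
) -> TrajectoryFit:
    """Fit the best piecewise-linear model for one trajectory.

    Candidates place breakpoints at interior observed time points; every
    segment must contain at least ``min_seg_samples`` points. A breakpoint
    marks a significant change of trajectory, so a candidate model is
    admissible only when every slope-change coefficient is significant at
    ``breakpoint_alpha``; BIC (with breakpoint locations counted as
    parameters) selects across k = 0..max_breakpoints. Series with mean
    expression below ``min_mean_expr`` are rejected with reason
    ``low_expression``; series too short for any valid segmentation with
    ``too_short``.
    """
    n = len(ts)
    reject = lambda reason: TrajectoryFit(
        ts.gene, ts.structure, 0, [], [], [], [], [],
        np.array([]), np.nan, np.nan, rejected_reason=reason,
    )
    if n < 3:
        return reject("too_short")
    if float(np.mean(ts.values)) < min_mean_expr:
        return reject("low_expression")

    unique_times = np.unique(ts.times)
    candidates = unique_times[:-1]  # breakpoint at t puts that point left
    candidates = candidates[1:] if len(candidates) > 1 else candidates[:0]

    best: dict | None = None
    tss = float(np.sum((ts.values - ts.values.mean()) ** 2))
    for k in range(0, max_breakpoints + 1):
        for bps in itertools.combinations(candidates, k):
            counts = _segment_counts(ts.times, bps)
            if min(counts) < min_seg_samples:
                continue
            X = _design(ts.times, bps) if continuous else _design_disc(ts.times, bps)
            p_cols = X.shape[1]
            # estimated breakpoint locations count as parameters too
            p_eff = p_cols + k
            if n <= p_eff:
                continue
            beta, _, rank, _ = np.linalg.lstsq(X, ts.values, rcond=None)
            if rank < p_cols:
                continue
            resid = ts.values - X @ beta
            rss = float(resid @ resid)
            dof_c = n - p_eff
            if continuous and k > 0 and dof_c > 0 and rss > 1e-12:
                cov = np.linalg.inv(X.T @ X) * (rss / dof_c)
                hinge_t = beta[2:] / np.sqrt(np.diag(cov)[2:])
                hinge_p = 2 * stats.t.sf(np.abs(hinge_t), dof_c)
                if (hinge_p >= breakpoint_alpha).any():
                    continue
            bic = n * np.log(max(rss, 1e-300) / n) + p_eff * np.log(n)
            if best is None or bic < best["bic"] - 1e-9:
                best = {"k": k, "bps": bps, "beta": beta, "X": X,
                        "rss": rss, "bic": bic, "p": p_cols, "p_eff": p_eff}
    if best is None:
        return reject("too_short")

    X, beta, rss, p = best["X"], best["beta"], best["rss"], best["p"]
    fitted = X @ beta
    dof = n - best["p_eff"]
    adj_r2 = 1.0 - (rss / dof) / (tss / (n - 1)) if tss > 0 and dof > 0 else (
        1.0 if rss <= 1e-12 else 0.0
    )
    sigma2 = rss / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.inv(X.T @ X)

    k = best["k"]
    bps = list(best["bps"])
    slopes, intercepts, slope_ps, directions = [], [], [], []
    for seg in range(k + 1):
        c = np.zeros(p)
        if continuous:
            # slope of segment j = beta[1] + hinge coefficients up to j
            c[1] = 1.0
            c[2 : 2 + seg] = 1.0
        else:
            c[2 * seg + 1] = 1.0
        slope = float(c @ beta)
        var = float(c @ XtX_inv @ c) * sigma2
        if var > 0 and dof > 0:
            tval = slope / np.sqrt(var)
            pval = float(2 * stats.t.sf(abs(tval), dof))
        else:
            pval = 0.0 if abs(slope) > 1e-12 else 1.0
        if continuous:
            # intercept of the segment's extended line
            seg_start = bps[seg - 1] if seg > 0 else float(ts.times[0])
            y_at_start = float(
                (_design(np.array([seg_start]), tuple(bps)) @ beta)[0]
            )
            intercept = y_at_start - slope * seg_start
        else:
            intercept = float(beta[2 * seg])
        slopes.append(slope)
        intercepts.append(intercept)
        slope_ps.append(pval)
        if pval < direction_alpha:
            directions.append("up" if slope > 0 else "down")
        else:
            directions.append("flat")
    return TrajectoryFit(
        gene=ts.gene,
        structure=ts.structure,
        k=k,
        breakpoints=bps,
        slopes=slopes,
        intercepts=intercepts,
        slope_p=slope_ps,
        directions=directions,
        fitted=fitted,
        adj_r2=float(adj_r2),
        bic=float(best["bic"]),
    )


def _design_disc(times: np.ndarray, bps: tuple[float, ...]) -> np.ndarray:
    """Discontinuous variant: independent line per segment."""
    edges = [-np.inf, *bps, np.inf]
    cols = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = ((times > lo) & (times <= hi)).astype(float)
        cols += [mask, mask * times]
    return np.column_stack(cols)


def filter_fits(
    fits: list[TrajectoryFit], r2_min: float = 0.5
) -> list[TrajectoryFit]:
    """Keep accepted fits with adjusted R-squared >= ``r2_min``; exact
    boundary cases are retained and logged."""
    kept = []
    for f in fits:
        if not f.accepted:
            continue
        if f.adj_r2 >= r2_min:
            if f.adj_r2 == r2_min:
                logger.info(
                    "%s/%s at the R2 boundary %g; retained",
                    f.gene, f.structure, r2_min,
                )
            kept.append(f)
    return kept


def classify_shape(fit: TrajectoryFit) -> str:
    """Label the direction sequence: monotone-up, monotone-down, peak,
    V-shape, flat, or complex (after merging repeats and dropping flats)."""
    if not fit.accepted:
        raise ValueError("cannot classify a rejected fit")
    seq = [d for d in fit.directions if d != "flat"]
    collapsed = [d for d, _ in itertools.groupby(seq)]
    if not collapsed:
        return "flat"
    if collapsed == ["up"]:
        return "monotone-up"
    if collapsed == ["down"]:
        return "monotone-down"
    if collapsed == ["down", "up"]:
        return "V-shape"
    if collapsed == ["up", "down"]:
        return "peak"
    return "complex"
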