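"""Piecewise (segmented) regression estimation of the extinction threshold.

When the logistic response is among the best-supported models, the cover
value where diversity "starts to drop from the upper value" is estimated by
fitting the continuous two-segment linear model

    y = b0 + b1 * x + b2 * (x - psi) * 1[x > psi]

to the raw series.  The breakpoint psi is refined by the Muggeo
linearization: each iteration augments the design with the working
covariate V = -1[x > psi] and updates psi by gamma_hat / b2_hat, where
gamma is V's coefficient.  At convergence gamma vanishes and
se(psi) = se(gamma) / |b2| from the final linearized least-squares fit; the
95% confidence interval is the Wald interval psi +/- 1.96 se.  A seeded
grid search over interior breakpoints backs the iteration up when it
stalls or drifts to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .community import ResponseSeries
from .errors import InputError
from .selection import SelectionTable

Z975 = 1.959963984540054


@dataclass
class PiecewiseConfig:
    psi0: float | None = None  # starting breakpoint; default median(x)
    max_iter: int = 100
    tol: float = 1e-10  # convergence on the breakpoint update step
    n_grid: int = 201
    # constrain the high-cover segment (x > psi) to slope 0: the response
    # then sits at a flat upper plateau and declines only below the break
    flat_plateau: bool = False
    method: str = "auto"  # auto | iterative | grid


@dataclass
class ThresholdEstimate:
    """A single-breakpoint segmented-regression threshold."""

    breakpoint: float
    se: float
    ci_low: float
    ci_high: float
    left_slope: float
    right_slope: float
    converged: bool
    applicable: bool = True
    reason: str = ""
    method: str = "iterative"
    n_iter: int = 0

    def to_frame(self, series_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "series": series_id,
                    "breakpoint": self.breakpoint,
                    "se": self.se,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "left_slope": self.left_slope,
                    "right_slope": self.right_slope,
                    "converged": self.converged,
                    "applicable": self.applicable,
                    "reason": self.reason,
                }
            ]
        )


def _design(x: np.ndarray, psi: float, flat_plateau: bool, working: bool) -> np.ndarray:
    """Design matrix of the segmented model at a fixed breakpoint.

    Free variant: [1, x, (x - psi)_+] — two free slopes joined at psi.
    Flat-plateau variant: [1, (psi - x)_+] — flat above psi, sloped below.
    ``working`` appends the Muggeo covariate dU/dpsi whose coefficient,
    divided by the slope-change coefficient, is the breakpoint update.
    """
    cols = [np.ones_like(x)]
    if flat_plateau:
        cols.append(np.maximum(psi - x, 0.0))
        if working:
            cols.append((x < psi).astype(float))
    else:
        cols.append(x)
        cols.append(np.maximum(x - psi, 0.0))
        if working:
            cols.append(-(x > psi).astype(float))
    return np.column_stack(cols)


def _sse_at(x: np.ndarray, y: np.ndarray, psi: float, flat_plateau: bool) -> float:
    X = _design(x, psi, flat_plateau, working=False)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _grid_best(x: np.ndarray, y: np.ndarray, cfg: PiecewiseConfig, lo: float, hi: float) -> float:
    grid = np.linspace(lo, hi, cfg.n_grid)
    sses = [_sse_at(x, y, p, cfg.flat_plateau) for p in grid]
    return float(grid[int(np.argmin(sses))])


def _iterate(
    x: np.ndarray, y: np.ndarray, psi: float, cfg: PiecewiseConfig, lo: float, hi: float
) -> tuple[float, bool, int]:
    """Muggeo refinement from a starting breakpoint; returns (psi, ok, iters)."""
    scale = float(np.ptp(x)) or 1.0
    for it in range(1, cfg.max_iter + 1):
        X = _design(x, psi, cfg.flat_plateau, working=True)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        b2, gamma = beta[-2], beta[-1]
        if abs(b2) < 1e-12 * (abs(gamma) + 1e-12):
            return psi, False, it  # no slope change: breakpoint unidentifiable
        step = gamma / b2
        new = psi + step
        if not np.isfinite(new):
            return psi, False, it
        new = min(max(new, lo), hi)
        moved = abs(new - psi)
        psi = new
        if abs(step) < cfg.tol * scale or moved == 0.0 and abs(step) > cfg.tol * scale:
            # either converged, or pinned at a boundary while wanting out
            return psi, abs(step) < cfg.tol * scale, it
    return psi, False, cfg.max_iter


def fit_breakpoint(x, y, config: PiecewiseConfig | None = None) -> ThresholdEstimate:
    """Segmented-regression breakpoint on raw (x, y) arrays.

    The default ``auto`` method runs the Muggeo iteration from ``psi0``
    (median x if unset), falls back to a grid search over interior
    breakpoints when the iteration fails or finds a worse optimum, and
    flags the estimate non-converged if the breakpoint sits at the guard
    boundary (one x-step from either end of the gradient) — the signature
    of data with no identifiable break.
    """
    cfg = config or PiecewiseConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise InputError("piecewise regression needs n >= 5")
    xs = np.unique(x)
    if xs.size < 4:
        raise InputError("piecewise regression needs >= 4 distinct x values")
    delta = float(np.min(np.diff(xs)))  # guard: one x-step from each end
    lo, hi = float(xs.min()) + delta, float(xs.max()) - delta

    psi0 = cfg.psi0 if cfg.psi0 is not None else float(np.median(x))
    psi0 = min(max(psi0, lo), hi)

    candidates: list[tuple[float, bool, int, str]] = []
    if cfg.method in ("auto", "iterative"):
        psi, ok, it = _iterate(x, y, psi0, cfg, lo, hi)
        candidates.append((psi, ok, it, "iterative"))
    if cfg.method in ("auto", "grid") or not candidates or not candidates[0][1]:
        g = _grid_best(x, y, cfg, lo, hi)
        psi, ok, it = _iterate(x, y, g, cfg, lo, hi)
        candidates.append((psi, ok, it, "grid+iterative" if cfg.method != "grid" else "grid"))
        if cfg.method == "grid":
            candidates[-1] = (g, True, 0, "grid")

    # keep the candidate with the smallest SSE, preferring converged ones
    scored = [
        (not ok, _sse_at(x, y, psi, cfg.flat_plateau), psi, ok, it, meth)
        for psi, ok, it, meth in candidates
    ]
    scored.sort(key=lambda t: (t[0], t[1]))
    _, _, psi, ok, n_iter, method = scored[0]

    at_boundary = psi <= lo + 1e-9 or psi >= hi - 1e-9
    converged = bool(ok and not at_boundary)

    X = _design(x, psi, cfg.flat_plateau, working=True)
    ols = sm.OLS(y, X).fit()
    b2 = ols.params[-2]
    se_gamma = ols.bse[-1]
    se_psi = float(se_gamma / abs(b2)) if abs(b2) > 0 else float("nan")
    if cfg.flat_plateau:
        left, right = -float(b2), 0.0  # slope below the break; plateau above
    else:
        left = float(ols.params[1])
        right = left + float(b2)
    if at_boundary:
        reason = "breakpoint pinned at the gradient boundary"
    elif not ok:
        reason = "breakpoint iteration did not converge"
    else:
        reason = ""
    return ThresholdEstimate(
        breakpoint=float(psi),
        se=se_psi,
        ci_low=float(psi - Z975 * se_psi),
        ci_high=float(psi + Z975 * se_psi),
        left_slope=left,
        right_slope=right,
        converged=converged,
        reason=reason,
        method=method,
        n_iter=n_iter,
    )


def piecewise_fit(series: ResponseSeries, config: PiecewiseConfig | None = None) -> ThresholdEstimate:
    """Segmented-regression threshold estimate for one response series."""
    return fit_breakpoint(series.x, series.y, config)


def threshold_report(
    selection: SelectionTable,
    series: ResponseSeries,
    config: PiecewiseConfig | None = None,
    logistic_midpoint: float | None = None,
) -> ThresholdEstimate:
    """Threshold estimate gated on the logistic model being best-supported.

    Runs the piecewise regression only when ``LOG`` is in the AICc best
    set, seeding the breakpoint at the fitted logistic midpoint when one is
    supplied; otherwise returns an explicit not-applicable record.
    """
    if "LOG" not in selection.best_set:
        return ThresholdEstimate(
            breakpoint=float("nan"), se=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"),
            left_slope=float("nan"), right_slope=float("nan"),
            converged=False, applicable=False,
            reason="no threshold model selected", method="none",
        )
    cfg = config or PiecewiseConfig()
    if logistic_midpoint is not None and cfg.psi0 is None:
        cfg = PiecewiseConfig(
            psi0=float(logistic_midpoint), max_iter=cfg.max_iter, tol=cfg.tol,
            n_grid=cfg.n_grid, flat_plateau=cfg.flat_plateau, method=cfg.method,
        )
    return piecewise_fit(series, cfg)
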