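"""AICc multimodel selection, Akaike weights and fit diagnostics.

Candidate fits are ranked by the small-sample-corrected Akaike information
criterion; models within 2 AICc units of the best form the *best set* of
equally plausible response shapes.  Diagnostics cover the three checks a
small-n count/diversity analysis needs: model insufficiency (residuals
correlated with the predictor), overdispersion of Poisson fits, and
residual normality of normal fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import ResponseSeries
from .errors import InputError, NumericalError
from .models import FitResult, model_mean

DELTA_BEST_SET = 2.0


def aicc(loglik: float, K: int, n: int) -> float:
    """Corrected AIC: -2 loglik + 2K + 2K(K+1)/(n-K-1).

    Undefined when n <= K + 1; returns NaN there so callers can flag and
    exclude the fit from ranking.
    """
    if n <= K + 1:
        return float("nan")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1.0) / (n - K - 1.0)


@dataclass
class SelectionTable:
    """Ranked model comparison for one response series."""

    series_id: str
    table: pd.DataFrame  # model, loglik, K, n, aicc, delta_aicc, weight, converged
    best_set: list[str]

    @property
    def best_model(self) -> str:
        return self.table.iloc[0]["model"]


def select(
    fits: list[FitResult],
    delta_cutoff: float = DELTA_BEST_SET,
    series_id: str = "",
) -> SelectionTable:
    """Rank fits by AICc and compute Akaike weights and the best-model set.

    Non-converged fits (and fits whose AICc is undefined at this n) are kept
    in the output table for the record but excluded from delta/weight
    computation and from the best set.  Raises if nothing converged.
    """
    if not fits:
        raise InputError("select() needs at least one fit")
    rows = []
    for f in fits:
        a = aicc(f.loglik, f.K, f.n) if f.converged else float("nan")
        rows.append(
            {
                "model": f.model,
                "loglik": f.loglik,
                "K": f.K,
                "n": f.n,
                "aicc": a,
                "converged": f.converged,
            }
        )
    tab = pd.DataFrame(rows)
    usable = tab["converged"] & np.isfinite(tab["aicc"])
    if not usable.any():
        raise NumericalError(f"no converged, AICc-rankable fit for {series_id or 'series'}")
    best_aicc = tab.loc[usable, "aicc"].min()
    tab["delta_aicc"] = np.where(usable, tab["aicc"] - best_aicc, np.nan)
    rel = np.where(usable, np.exp(-0.5 * tab["delta_aicc"].fillna(np.inf)), 0.0)
    tab["weight"] = rel / rel.sum()
    tab = tab.sort_values(
        ["delta_aicc", "K", "model"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    in_best = tab["delta_aicc"] <= delta_cutoff
    return SelectionTable(
        series_id=series_id, table=tab, best_set=tab.loc[in_best, "model"].tolist()
    )


@dataclass
class DiagnosticsReport:
    """Residual diagnostics for one fitted model on one series."""

    series_id: str
    model: str
    residual_cover_correlation: float
    residual_correlation_p: float
    insufficient: bool
    correlation_undefined: bool
    overdispersion_ratio: float | None = None
    overdispersed: bool | None = None
    n_floored_terms: int = 0
    shapiro_p: float | None = None
    nonnormal: bool | None = None


def insufficiency_test(
    series: ResponseSeries, fit: FitResult, alpha: float = 0.05
) -> DiagnosticsReport:
    """Test a fitted model for insufficiency: residuals correlated with x.

    A significant Pearson correlation between the residuals and forest
    cover means the model leaves predictor-related structure unexplained.
    Zero-variance residuals (a perfect fit) make the correlation undefined
    and are flagged rather than propagated as NaN.
    """
    if not fit.converged or fit.params is None:
        raise InputError("insufficiency test requires a converged fit")
    if series.n < 4:
        raise InputError("insufficiency test needs n >= 4")
    resid = series.y - model_mean(series.x, fit.params)
    if np.std(resid) < 1e-12 or np.std(series.x) < 1e-12:
        return DiagnosticsReport(
            series.label, fit.model, float("nan"), float("nan"),
            insufficient=False, correlation_undefined=True,
        )
    r, p = stats.pearsonr(series.x, resid)
    return DiagnosticsReport(
        series.label, fit.model, float(r), float(p),
        insufficient=bool(p < alpha), correlation_undefined=False,
    )


def dispersion_check(
    series: ResponseSeries, fit: FitResult, floor: float = 1e-6
) -> tuple[float, int]:
    """Pearson chi-square / df overdispersion ratio for a Poisson fit.

    Returns ``(ratio, n_floored)`` where terms with a fitted mean at or
    below ``floor`` are excluded (and counted) rather than allowed to blow
    up the statistic.  Values near 1 indicate Poisson-consistent scatter.
    """
    if series.family != "poisson":
        raise InputError("dispersion check applies to poisson-family series")
    if not fit.converged or fit.params is None:
        raise InputError("dispersion check requires a converged fit")
    mu = model_mean(series.x, fit.params)
    keep = mu > floor
    n_floored = int((~keep).sum())
    df = series.n - fit.K
    if df <= 0:
        raise InputError("dispersion check needs n > K")
    chi2 = float(np.sum((series.y[keep] - mu[keep]) ** 2 / mu[keep]))
    return chi2 / df, n_floored


def diagnose(
    series: ResponseSeries,
    fit: FitResult,
    alpha: float = 0.05,
    dispersion_threshold: float = 1.5,
) -> DiagnosticsReport:
    """Full diagnostics bundle: insufficiency plus family-specific checks."""
    report = insufficiency_test(series, fit, alpha=alpha)
    if series.family == "poisson":
        ratio, n_floored = dispersion_check(series, fit)
        report.overdispersion_ratio = ratio
        report.overdispersed = bool(ratio > dispersion_threshold)
        report.n_floored_terms = n_floored
    else:
        resid = series.y - model_mean(series.x, fit.params)
        if np.std(resid) > 1e-12 and series.n >= 3:
            _, sp = stats.shapiro(resid)
            report.shapiro_p = float(sp)
            report.nonnormal = bool(sp < alpha)
    return report


def selection_to_frame(selection: SelectionTable) -> pd.DataFrame:
    """Serialize a selection table in the conventional published layout."""
    out = selection.table[["model", "delta_aicc", "K", "weight", "converged"]].copy()
    out.insert(0, "series", selection.series_id)
    out["in_best_set"] = out["model"].isin(selection.best_set)
    return out
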