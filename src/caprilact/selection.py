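"""Fit diagnostics, information criteria and model ranking.

Per-fit criteria follow the least-squares forms (no likelihood constant):

    MSPE   = RSS / n
    adjR2  = 1 - (1 - R2) (n - 1) / (n - k - 1)
    AIC    = n ln(RSS/n) + 2k
    AICc   = AIC + 2k(k+1)/(n - k - 1)
    BIC    = n ln(RSS/n) + k ln(n)

Residual diagnostics: the Durbin–Watson statistic (first-order residual
autocorrelation, computed on residuals averaged by day in milk across
lactations) and the Shapiro–Francia normality test with Royston's
p-value approximation.

Model ranking: candidates that did not fit 100% of lactations are excluded;
the rest are ranked by the sum of their ranks over mean MSPE (lower better),
mean adjusted R^2 (higher better) and mean AIC/AICc/BIC (lower better),
with ties broken by fewer parameters then lexical id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curves import FitResult
from .errors import DegenerateDataError, InsufficientDataError, ValidationError

#: Criteria columns used for ranking: (column, higher_is_better)
RANKING_CRITERIA = (
    ("mspe", False),
    ("adj_r2", True),
    ("aic", False),
    ("aicc", False),
    ("bic", False),
)


@dataclass(frozen=True)
class FitCriteria:
    """Selection criteria of one fitted lactation curve."""

    rss: float
    mspe: float
    adj_r2: float
    aic: float
    aicc: float
    bic: float
    fitted_ok: bool


def criteria(fit: FitResult) -> FitCriteria:
    """Selection criteria for one fit; requires n >= k + 2."""
    n, k = fit.n, fit.k
    if n < k + 2:
        raise InsufficientDataError(f"criteria need n >= k+2 (n={n}, k={k})")
    rss = float(fit.rss)
    tss = float(np.sum((fit.y - np.mean(fit.y)) ** 2))
    if rss <= 0.0:
        warnings.warn("perfect fit: AIC family returned as -inf", stacklevel=2)
        return FitCriteria(0.0, 0.0, 1.0, -np.inf, -np.inf, -np.inf, fit.converged)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    aic = n * np.log(rss / n) + 2 * k
    return FitCriteria(
        rss=rss,
        mspe=rss / n,
        adj_r2=adj_r2,
        aic=aic,
        aicc=aic + 2 * k * (k + 1) / (n - k - 1),
        bic=n * np.log(rss / n) + k * np.log(n),
        fitted_ok=fit.converged,
    )


def durbin_watson(residuals) -> float:
    """DW = sum((e_t - e_{t-1})^2) / sum(e_t^2), residuals in DIM order."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise InsufficientDataError("Durbin–Watson needs at least 2 residuals")
    den = float(np.sum(e**2))
    if den == 0.0:
        raise DegenerateDataError("Durbin–Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / den)


def dim_averaged_residuals(fits: list[FitResult]) -> np.ndarray:
    """Residuals averaged by day in milk across lactations, in DIM order."""
    acc: dict[float, list[float]] = {}
    for f in fits:
        for d, e in zip(f.t, f.residuals):
            acc.setdefault(float(d), []).append(float(e))
    return np.array([np.mean(acc[d]) for d in sorted(acc)])


def shapiro_francia(x) -> tuple[float, float]:
    """Shapiro–Francia normality test.

    W is the squared correlation between the ordered sample and Blom
    normal scores m_i = Phi^-1((i - 3/8)/(n + 1/4)); the p-value uses
    Royston's normal approximation for ln(1 - W).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 5:
        raise InsufficientDataError("Shapiro–Francia needs n >= 5")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("Shapiro–Francia undefined for constant sample")
    m = stats.norm.ppf((np.arange(1, n + 1) - 3.0 / 8.0) / (n + 0.25))
    w = float(np.corrcoef(x, m)[0, 1] ** 2)
    nu = np.log(n)
    mu = 1.0521 * (np.log(nu) - nu) - 1.2725
    sigma = -0.26758 * (np.log(nu) + 2.0 / nu) + 1.0308
    z = (np.log(1.0 - w) - mu) / sigma
    return w, float(stats.norm.sf(z))


def aggregate_criteria(
    fits_by_model: dict[str, list[FitResult]],
    model_k: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean criteria per model over lactations.

    ``pct_fitted`` is the percentage of converged fits; criteria means are
    taken over converged fits with enough points (n >= k + 2).
    """
    rows = []
    for model_id, fits in fits_by_model.items():
        if not fits:
            continue
        k = model_k[model_id] if model_k else fits[0].k
        pct = 100.0 * np.mean([f.converged for f in fits])
        crits = [criteria(f) for f in fits if f.converged and f.n >= f.k + 2]
        row = {"model_id": model_id, "k": k, "n_fits": len(fits), "pct_fitted": pct}
        for c in ("mspe", "adj_r2", "aic", "aicc", "bic"):
            row[c] = (
                float(np.mean([getattr(x, c) for x in crits])) if crits else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def select_best(table: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate models; the first row is the selected model.

    Input: one row per model with columns model_id, k, pct_fitted and the
    five criteria columns.  Models below 100% fit success (or with
    unevaluable criteria) are excluded; remaining models are ordered by
    rank-sum, then k, then model_id.
    """
    crit_cols = [c for c, _ in RANKING_CRITERIA]
    ok = table[
        (table["pct_fitted"] >= 100.0) & table[crit_cols].notna().all(axis=1)
    ].copy()
    if ok.empty:
        best = table.loc[table["pct_fitted"].idxmax()]
        raise ValidationError(
            "no candidate fitted 100% of lactations; best partial coverage: "
            f"{best['model_id']} at {best['pct_fitted']:.1f}%"
        )
    rank_sum = np.zeros(len(ok))
    for col, higher_better in RANKING_CRITERIA:
        vals = ok[col].to_numpy(dtype=float)
        r = stats.rankdata(-vals if higher_better else vals, method="average")
        ok[f"rank_{col}"] = r
        rank_sum += r
    ok["rank_sum"] = rank_sum
    ok = ok.sort_values(
        ["rank_sum", "k", "model_id"], kind="mergesort"
    ).reset_index(drop=True)
    ok.insert(0, "rank", np.arange(1, len(ok) + 1))
    return ok
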