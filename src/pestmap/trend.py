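"""Harmonic trend regression for monthly complaint series.

Seasonal count series are modeled as a harmonic function of time with a
linearly varying amplitude, linearized as an ordinary least-squares
problem with design columns

    [1, t, sin(2*pi*t/12), cos(2*pi*t/12), t*sin(2*pi*t/12), t*cos(2*pi*t/12)]

so the instantaneous seasonal amplitude at month t is
sqrt((b2 + b4*t)^2 + (b3 + b5*t)^2) and the secular trend is the t-test on
the linear coefficient b1.  Amplitude growth or decay is a derived
quantity, not a constraint, so rising and falling seasonal signals fit the
same model.  Also provides the per-area concordance regression between two
reporting streams (e.g. landlord infestation reports vs resident
complaints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import MonthlySeries

PERIOD = 12
N_COEF = 6
COEF_NAMES = ("intercept", "trend", "sin", "cos", "t_sin", "t_cos")


@dataclass
class HarmonicFit:
    """OLS fit of the amplitude-varying harmonic model."""

    beta: np.ndarray          # (6,) in COEF_NAMES order
    se: np.ndarray            # (6,)
    trend_t_stat: float
    trend_p: float
    amplitude_wald_stat: float   # joint Wald test on the t*sin, t*cos terms
    amplitude_wald_p: float
    r_squared: float
    residuals: np.ndarray
    n_obs: int
    sigma2_hat: float
    label: str = ""


def build_design(t: np.ndarray) -> np.ndarray:
    """Design matrix of the linearized harmonic model (period 12, t uncentered)."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise ValueError("t must be one-dimensional")
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate t values in design")
    w = 2.0 * np.pi * t / PERIOD
    s, c = np.sin(w), np.cos(w)
    return np.column_stack([np.ones_like(t), t, s, c, t * s, t * c])


def _standardized_response(series: MonthlySeries) -> np.ndarray:
    """Percent of the denominator when one is supplied, raw y otherwise."""
    if series.denominator is not None:
        return 100.0 * series.y / series.denominator
    return np.asarray(series.y, dtype=float)


def fit_harmonic_trend(series: MonthlySeries) -> HarmonicFit:
    """Fit the harmonic model by OLS via orthogonal (SVD) decomposition.

    When the series carries a denominator, the response is first
    standardized to 100*y/denominator.  The trend p-value is the two-sided
    t-test on the linear coefficient with n-6 degrees of freedom; the
    joint Wald test on the two amplitude-change terms is reported
    alongside.  For a zero-variance response, R^2 is defined as 0.
    """
    t = np.asarray(series.t, dtype=float)
    y = _standardized_response(series)
    n = len(y)
    if n < N_COEF + 1:
        raise ValueError(
            f"need at least {N_COEF + 1} months for the six-column design, got {n}"
        )
    if n < 24:
        warnings.warn(
            f"series of length {n} < 24 months: amplitude terms are weakly "
            "identified",
            stacklevel=2,
        )
    X = build_design(t)
    rank = np.linalg.matrix_rank(X)
    if rank < N_COEF:
        sv = np.linalg.svd(X, compute_uv=False)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {N_COEF}); singular values "
            f"{np.array2string(sv, precision=3)} — collinear harmonic columns, "
            "typically from too short or aliased sampling"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    dof = n - N_COEF
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = beta[1] / se[1] if se[1] > 0 else np.inf * np.sign(beta[1])
    trend_p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    # joint Wald test on (t*sin, t*cos): does the seasonal amplitude change?
    idx = [4, 5]
    V = sigma2 * XtX_inv[np.ix_(idx, idx)]
    b = beta[idx]
    if sigma2 > 0:
        wald = float(b @ np.linalg.solve(V, b)) / 2.0
        wald_p = float(stats.f.sf(wald, 2, dof))
    else:
        wald, wald_p = np.inf if np.any(b != 0) else 0.0, 0.0 if np.any(b != 0) else 1.0
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return HarmonicFit(
        beta=beta,
        se=se,
        trend_t_stat=float(t_stat),
        trend_p=trend_p,
        amplitude_wald_stat=wald,
        amplitude_wald_p=wald_p,
        r_squared=min(max(r2, 0.0), 1.0),
        residuals=resid,
        n_obs=n,
        sigma2_hat=sigma2,
        label=series.label,
    )


def amplitude_at(fit: HarmonicFit, t) -> np.ndarray | float:
    """Instantaneous seasonal amplitude sqrt((b2+b4 t)^2 + (b3+b5 t)^2)."""
    t = np.asarray(t, dtype=float)
    b = fit.beta
    amp = np.hypot(b[2] + b[4] * t, b[3] + b[5] * t)
    return float(amp) if amp.ndim == 0 else amp


def classify_trend(fit: HarmonicFit, alpha: float = 0.05) -> str:
    """'decreasing', 'increasing' or 'none' per the trend t-test at level alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if fit.trend_p >= alpha:
        return "none"
    return "decreasing" if fit.beta[1] < 0 else "increasing"


def concordance_regression(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, tuple[float, float], float, float]:
    """Simple OLS of y on x with intercept: per-area agreement of two streams.

    Returns (slope, 95% CI from t quantiles, R^2, two-sided p for slope=0).
    Used to compare, per area, counts from independent reporting channels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("zero-variance regressor: all x values identical")
    res = stats.linregress(x, y)
    tq = stats.t.ppf(0.975, n - 2)
    ci = (res.slope - tq * res.stderr, res.slope + tq * res.stderr)
    return float(res.slope), (float(ci[0]), float(ci[1])), float(res.rvalue**2), float(res.pvalue)


def fit_report_row(fit: HarmonicFit) -> dict:
    """Flat summary row for the fit-report CSV (one row per series)."""
    row = {"label": fit.label, "n_obs": fit.n_obs}
    for name, b, s in zip(COEF_NAMES, fit.beta, fit.se):
        row[f"beta_{name}"] = b
        row[f"se_{name}"] = s
    row.update(
        trend_t=fit.trend_t_stat,
        trend_p=fit.trend_p,
        amplitude_wald_p=fit.amplitude_wald_p,
        r_squared=fit.r_squared,
        amplitude_first=amplitude_at(fit, 0.0),
        amplitude_last=amplitude_at(fit, fit.n_obs - 1),
    )
    return row
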